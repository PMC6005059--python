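"""Synthetic data with planted ground truth for desk-scale verification.

Generates the four inputs the pipeline consumes — a 3-rank taxonomy, a fin
anatomy graph, an entity-quality annotation set, and a rooted species tree —
together with the ground truth used to check recovery: per-species true
presence/absence for each fin character and the list of planted loss/regain
transitions.

Everything is driven by a :class:`SyntheticScenario` and a seed; the same
scenario and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import dendropy
import yaml

from .inference import ABSENT, ASSERTED, PRESENT, PhenotypeAnnotation, write_annotations
from .ontology import (
    AnatomyGraph,
    DEPENDS_ON,
    DEVELOPS_FROM,
    IS_A,
    PART_OF,
)
from .taxonomy import TaxonRecord, Taxonomy

#: the two fin characters every synthetic dataset carries
CHARACTERS = ("pectoral_fin", "pelvic_fin")

#: per character: the part term whose qualities imply presence, and the
#: supporting girdle whose absence implies absence
PART_FOR = {"pectoral_fin": "pectoral_fin_ray", "pelvic_fin": "pelvic_fin_ray"}
GIRDLE_FOR = {"pectoral_fin": "pectoral_girdle", "pelvic_fin": "pelvic_girdle"}
BUD_FOR = {"pectoral_fin": "pectoral_fin_bud", "pelvic_fin": "pelvic_fin_bud"}


class ScenarioError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when the requested sparse event placement is impossible."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Counts are positive, fractions lie in [0, 1]; the same seed always yields
    byte-identical outputs.
    """

    seed: int = 0
    n_families: int = 8
    genera_per_family: tuple[int, int] = (2, 4)
    species_per_genus: tuple[int, int] = (2, 6)
    event_count_loss: int = 5
    event_count_regain: int = 1
    species_coverage: float = 1.0
    indirect_fraction: float = 0.3
    higher_level_fraction: float = 0.2
    conflict_rate: float = 0.0
    polytomy_fraction: float = 0.2
    mismatch_rate: float = 0.0
    extra_tip_rate: float = 0.0
    xref_fraction: float = 0.8
    sparse_placement: bool = True

    def __post_init__(self):
        for name in (
            "species_coverage", "indirect_fraction", "higher_level_fraction",
            "conflict_rate", "polytomy_fraction", "mismatch_rate",
            "extra_tip_rate", "xref_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1], got {v}")
        if self.n_families < 1:
            raise ScenarioError("need at least one family")
        for name in ("genera_per_family", "species_per_genus"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ScenarioError(f"bad count range for {name}")
        if self.event_count_loss < 0 or self.event_count_regain < 0:
            raise ScenarioError("event counts must be non-negative")
        if self.event_count_regain > self.event_count_loss:
            raise ScenarioError(
                "each regain must nest under a distinct loss; "
                "event_count_regain cannot exceed event_count_loss"
            )

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["genera_per_family"] = list(self.genera_per_family)
        data["species_per_genus"] = list(self.species_per_genus)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("genera_per_family", "species_per_genus"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _rng(seed: int, tag: str) -> random.Random:
    return random.Random(f"{seed}:{tag}")


def _letters(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ... (deterministic name suffixes)."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


# ---------------------------------------------------------------------------
# anatomy template


def generate_anatomy_template() -> AnatomyGraph:
    """Fixed fin-anatomy graph covering both paired fins.

    Per fin: the fin itself, its fin ray and radial (parts), the supporting
    girdle (a structural dependency: paired fins never occur without their
    girdle), and the larval fin bud (developmental precursor). A small
    ``is_a`` ladder (fin subtype -> paired fin -> fin) exercises subsumption.
    """
    labels = {
        "fin": "fin",
        "paired_fin": "paired fin",
        "girdle_skeleton": "girdle skeleton",
    }
    edges: list[tuple[str, str, str]] = [("paired_fin", IS_A, "fin")]
    for side in ("pectoral", "pelvic"):
        fin = f"{side}_fin"
        labels[fin] = f"{side} fin"
        labels[f"{side}_fin_ray"] = f"{side} fin ray"
        labels[f"{side}_radial"] = f"{side} radial element"
        labels[f"{side}_girdle"] = f"{side} girdle skeleton"
        labels[f"{side}_fin_bud"] = f"larval {side} fin bud"
        edges += [
            (fin, IS_A, "paired_fin"),
            (f"{side}_fin_ray", PART_OF, fin),
            (f"{side}_radial", PART_OF, fin),
            (f"{side}_girdle", IS_A, "girdle_skeleton"),
            (fin, DEPENDS_ON, f"{side}_girdle"),
            (fin, DEVELOPS_FROM, f"{side}_fin_bud"),
        ]
    return AnatomyGraph(labels, edges)


# ---------------------------------------------------------------------------
# taxonomy


def generate_taxonomy(scenario: SyntheticScenario) -> Taxonomy:
    """3-rank taxonomy (family -> genus -> species) under one supra-familial root.

    A ``xref_fraction`` of records carry a synthetic NCBI-like integer
    cross-reference.
    """
    rng = _rng(scenario.seed, "taxonomy")
    records = [TaxonRecord("TAX:00000", "Teleosteomorpha", "order", None)]
    counter = 1
    next_xref = 100000
    genus_counter = 0

    def new_id() -> str:
        nonlocal counter
        tid = f"TAX:{counter:05d}"
        counter += 1
        return tid

    def maybe_xref() -> Optional[int]:
        nonlocal next_xref
        if rng.random() < scenario.xref_fraction:
            next_xref += rng.randint(1, 50)
            return next_xref
        return None

    for fi in range(scenario.n_families):
        fam_id = new_id()
        fam_name = f"Fam{_letters(fi)}idae".capitalize()
        records.append(
            TaxonRecord(fam_id, fam_name, "family", "TAX:00000", maybe_xref())
        )
        n_genera = rng.randint(*scenario.genera_per_family)
        for _ in range(n_genera):
            gen_id = new_id()
            gen_name = f"Gen{_letters(genus_counter)}".capitalize()
            genus_counter += 1
            records.append(
                TaxonRecord(gen_id, gen_name, "genus", fam_id, maybe_xref())
            )
            n_species = rng.randint(*scenario.species_per_genus)
            for si in range(n_species):
                records.append(
                    TaxonRecord(
                        new_id(),
                        f"{gen_name} sp{_letters(si)}",
                        "species",
                        gen_id,
                        maybe_xref(),
                    )
                )
    return Taxonomy(records)


# ---------------------------------------------------------------------------
# tree


def generate_tree(taxonomy: Taxonomy, scenario: SyntheticScenario) -> dendropy.Tree:
    """Rooted species tree honouring taxonomy monophyly.

    Species are joined sequentially at random within each genus, genera within
    each family, and families at the root, so every genus and family is a
    clade. Then ``polytomy_fraction`` of the internal nodes are collapsed,
    ``mismatch_rate`` of tip names get a deterministic "_x" suffix (so
    unmatched tips are recognizable), and ``extra_tip_rate`` novel tips with no
    taxonomy counterpart are appended inside random clades.

    The returned tree carries ``tree.original_labels``: current tip label ->
    species name (None for the novel tips).
    """
    rng = _rng(scenario.seed, "tree")
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True

    def join(lineages: list[dendropy.Node]) -> dendropy.Node:
        lineages = list(lineages)
        while len(lineages) > 1:
            a = lineages.pop(rng.randrange(len(lineages)))
            b = lineages.pop(rng.randrange(len(lineages)))
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            lineages.append(parent)
        return lineages[0]

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(label.replace(" ", "_"))
        return node

    family_clades = []
    root = taxonomy.root_id
    for fam in sorted(taxonomy.children(root)):
        genus_clades = []
        for gen in sorted(taxonomy.children(fam)):
            tips = [leaf(taxonomy.name(sp)) for sp in taxonomy.species_under(gen)]
            if tips:
                genus_clades.append(join(tips))
        if genus_clades:
            family_clades.append(join(genus_clades))
    tree.seed_node = join(family_clades)

    # collapse a fraction of internal (non-root) nodes into polytomies
    internals = [
        n for n in tree.preorder_internal_node_iter() if n is not tree.seed_node
    ]
    n_collapse = round(scenario.polytomy_fraction * len(internals))
    for node in (rng.sample(internals, n_collapse) if internals else []):
        node.edge.collapse()

    original_labels: dict[str, Optional[str]] = {}
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    n_tips = len(leaves)
    n_mismatch = round(scenario.mismatch_rate * n_tips)
    perturbed = set(rng.sample(range(n_tips), n_mismatch))
    for i, node in enumerate(leaves):
        species_name = node.taxon.label.replace("_", " ")
        if i in perturbed:
            node.taxon.label = node.taxon.label + "_x"
        original_labels[node.taxon.label] = species_name

    n_extra = round(scenario.extra_tip_rate * n_tips)
    internal_pool = sorted(
        tree.preorder_internal_node_iter(), key=lambda n: min(
            l.taxon.label for l in n.leaf_iter()
        )
    )
    for i in range(n_extra):
        host = rng.choice(internal_pool)
        node = leaf(f"Novus inc{_letters(i)}")
        host.add_child(node)
        original_labels[node.taxon.label] = None

    tree.original_labels = original_labels
    return tree


# ---------------------------------------------------------------------------
# trait history


@dataclass(frozen=True)
class PlantedEvent:
    character: str
    kind: str  # "loss" or "regain"
    clade: frozenset[str]  # species names under the event branch


@dataclass
class GroundTruth:
    """True per-species states and the transitions that produced them."""

    states: dict[str, dict[str, bool]]  # character -> species name -> presence
    events: list[PlantedEvent]
    tip_name_map: dict[str, Optional[str]]  # tip label -> species name

    def loss_count(self, character: str) -> int:
        return sum(
            1 for e in self.events if e.character == character and e.kind == "loss"
        )

    def regain_count(self, character: str) -> int:
        return sum(
            1 for e in self.events if e.character == character and e.kind == "regain"
        )

    def write(self, states_path: str | Path, events_path: str | Path,
              tipmap_path: str | Path) -> None:
        with open(states_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["character", "species", "presence"])
            for char in sorted(self.states):
                for sp in sorted(self.states[char]):
                    w.writerow([char, sp, "1" if self.states[char][sp] else "0"])
        with open(events_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["character", "kind", "clade"])
            for e in self.events:
                w.writerow([e.character, e.kind, "|".join(sorted(e.clade))])
        with open(tipmap_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["tip_label", "species_name"])
            for tip in sorted(self.tip_name_map):
                w.writerow([tip, self.tip_name_map[tip] or ""])


def _real_tips_under(node, tree) -> list[str]:
    """Species names of data-bearing tips in a subtree."""
    out = []
    for leaf in node.leaf_iter():
        name = tree.original_labels.get(leaf.taxon.label)
        if name is not None:
            out.append(name)
    return out


def _regain_candidates(loss_node, tree) -> list:
    """Nodes strictly inside the loss clade usable as regain branches.

    A valid regain branch leaves at least three off-path lineages (each with
    at least one data-bearing tip) absent between the loss node and itself;
    this guarantees that a reconstruction with no gain inside the clade costs
    at least three changes, so every most parsimonious reconstruction spends
    exactly one gain here and the planted loss+regain pair is identifiable.
    """
    candidates = []
    # (node, off-path absent lineage count accumulated from loss_node down to
    # the node's parent); loss_node itself is never a candidate
    stack = [(loss_node, 0)]
    while stack:
        node, offpath = stack.pop()
        if node is not loss_node and offpath >= 3 and _real_tips_under(node, tree):
            candidates.append(node)
        if not node.is_leaf():
            kids = node.child_nodes()
            viable = [k for k in kids if _real_tips_under(k, tree)]
            for k in kids:
                others = [v for v in viable if v is not k]
                stack.append((k, offpath + len(others)))
    return candidates


def plant_trait_history(
    tree: dendropy.Tree, scenario: SyntheticScenario
) -> GroundTruth:
    """Assign presence at the root and plant loss/regain transitions.

    One independent history per character. In sparse mode (default) loss
    branches are mutually non-nested and never share a parent, and each regain
    sits inside a distinct loss clade behind at least three absent lineages;
    together these make the planted history the unique most parsimonious
    explanation (length = losses + regains, every MPR uses exactly
    ``event_count_regain`` gains). An impossible placement raises
    :class:`PlacementError` rather than being silently relaxed.
    """
    if not hasattr(tree, "original_labels"):
        tree.original_labels = {
            leaf.taxon.label: leaf.taxon.label.replace("_", " ")
            for leaf in tree.leaf_node_iter()
        }
    all_species = [v for v in tree.original_labels.values() if v is not None]
    states: dict[str, dict[str, bool]] = {}
    events: list[PlantedEvent] = []
    L, R = scenario.event_count_loss, scenario.event_count_regain
    for char in CHARACTERS:
        rng = _rng(scenario.seed, f"history:{char}")
        if L == 0:
            states[char] = {sp: True for sp in all_species}
            continue
        last_error: Optional[str] = None
        for _attempt in range(5):
            try:
                char_states, char_events = _place_events(
                    tree, char, L, R, rng, all_species
                )
            except PlacementError as exc:
                last_error = str(exc)
                continue
            if scenario.sparse_placement and not _placement_identifiable(
                tree, char_states, L, R
            ):
                last_error = "placement not uniquely identifiable by parsimony"
                continue
            states[char] = char_states
            events.extend(char_events)
            break
        else:
            raise PlacementError(
                f"sparse placement impossible for {char}: {last_error}"
            )
    return GroundTruth(
        states=states, events=events, tip_name_map=dict(tree.original_labels)
    )


def _place_events(tree, char, L, R, rng, all_species):
    char_states = {sp: True for sp in all_species}
    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    candidates = [n for n in nodes if _real_tips_under(n, tree)]
    rng.shuffle(candidates)

    def independent(node, chosen) -> bool:
        for other in chosen:
            if other is node or node.parent_node is other.parent_node:
                return False
            anc = node.parent_node
            while anc is not None:
                if anc is other:
                    return False
                anc = anc.parent_node
            anc = other.parent_node
            while anc is not None:
                if anc is node:
                    return False
                anc = anc.parent_node
        return True

    loss_nodes: list = []
    regain_for: dict[int, object] = {}
    for _ in range(R):  # losses that must host a regain come first
        found = False
        for node in candidates:
            if node in loss_nodes or not independent(node, loss_nodes):
                continue
            regains = _regain_candidates(node, tree)
            if not regains:
                continue
            loss_nodes.append(node)
            regain_for[id(node)] = regains[rng.randrange(len(regains))]
            found = True
            break
        if not found:
            raise PlacementError(
                f"cannot place regain {len(regain_for) + 1} for {char}: "
                "no loss clade deep enough for an identifiable regain"
            )
    for _ in range(L - R):  # plain losses
        found = False
        for node in candidates:
            if node in loss_nodes or not independent(node, loss_nodes):
                continue
            loss_nodes.append(node)
            found = True
            break
        if not found:
            raise PlacementError(f"cannot place {L} non-nested losses for {char}")

    char_events = []
    lost_total: set[str] = set()
    for node in loss_nodes:
        clade = set(_real_tips_under(node, tree))
        regain_node = regain_for.get(id(node))
        regained = (
            set(_real_tips_under(regain_node, tree))
            if regain_node is not None
            else set()
        )
        for sp in clade - regained:
            char_states[sp] = False
        lost_total |= clade - regained
        char_events.append(PlantedEvent(char, "loss", frozenset(clade)))
        if regain_node is not None:
            char_events.append(PlantedEvent(char, "regain", frozenset(regained)))
    if len(lost_total) >= len(all_species):
        raise PlacementError(
            "losses cover every data-bearing tip; root presence unrecoverable"
        )
    return char_states, char_events


def _placement_identifiable(tree, char_states, L, R) -> bool:
    """Planted history is the parsimony-unique explanation of the tip states."""
    from .parsimony import change_bounds, parsimony_length

    tip_states = {}
    for tip, species in tree.original_labels.items():
        if species is None:
            tip_states[tip] = frozenset()
        else:
            tip_states[tip] = frozenset({1 if char_states[species] else 0})
    if parsimony_length(tree, tip_states) != L + R:
        return False
    bounds = change_bounds(tree, tip_states)
    return bounds.gain_min == R and bounds.gain_max == R


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    truth: GroundTruth,
    taxonomy: Taxonomy,
    anatomy: AnatomyGraph,
    scenario: SyntheticScenario,
) -> tuple[list[PhenotypeAnnotation], dict[str, list[str]]]:
    """Emit the annotation set implied by the ground truth.

    Presence is stated directly ("fin present") or, for an
    ``indirect_fraction`` of statements, via a structural quality on a part
    (implying presence through inference); absence directly or via girdle
    absence (implying fin absence). For a ``higher_level_fraction`` of
    monomorphic families/genera a single higher-rank statement replaces the
    member species statements. A ``conflict_rate`` of covered species receive
    contradictory statements (an asserted absence alongside a part-level
    quality implying presence).

    Returns the annotations plus the planted conflict map
    (character -> species taxon ids).
    """
    rng = _rng(scenario.seed, "annotations")
    name_to_id = {}
    for rec in taxonomy:
        name_to_id[rec.name] = rec.id
    species_names = sorted(
        {sp for char in truth.states for sp in truth.states[char]}
    )
    n_cov = round(scenario.species_coverage * len(species_names))
    covered = set(rng.sample(species_names, n_cov))

    annotations: list[PhenotypeAnnotation] = []
    conflicts: dict[str, list[str]] = {c: [] for c in CHARACTERS}
    study_pool = [f"study{_letters(i)}" for i in range(6)]

    def study() -> str:
        return study_pool[rng.randrange(len(study_pool))]

    for char in CHARACTERS:
        char_truth = truth.states[char]
        part = PART_FOR[char]
        girdle = GIRDLE_FOR[char]

        n_conf = round(scenario.conflict_rate * len(covered))
        conflict_species = set(
            rng.sample(sorted(covered), n_conf)
        )
        conflicts[char] = sorted(
            name_to_id[sp] for sp in conflict_species
        )

        # higher-level replacement: monomorphic, fully-truth-known groups
        blocked_groups: set[str] = set()
        for sp in conflict_species:
            sid = name_to_id[sp]
            for anc in taxonomy.ancestors(sid):
                blocked_groups.add(anc)
        replaced_species: set[str] = set()
        higher_sources: list[tuple[str, bool]] = []  # (taxon_id, state)
        if scenario.higher_level_fraction > 0:
            for rank in ("family", "genus"):
                for taxon in sorted(
                    t.id for t in taxonomy if t.rank == rank
                ):
                    if taxon in blocked_groups:
                        continue
                    members = [
                        taxonomy.name(s) for s in taxonomy.species_under(taxon)
                    ]
                    if not members or any(m in replaced_species for m in members):
                        continue
                    member_states = {char_truth.get(m) for m in members}
                    if len(member_states) != 1 or None in member_states:
                        continue
                    if rng.random() < scenario.higher_level_fraction:
                        (state,) = member_states
                        higher_sources.append((taxon, state))
                        replaced_species.update(members)
        for taxon, state in higher_sources:
            annotations.append(
                PhenotypeAnnotation(
                    taxon=taxon,
                    entity=char,
                    quality=PRESENT if state else ABSENT,
                    provenance=ASSERTED,
                    study=study(),
                )
            )

        for sp in sorted(covered):
            sid = name_to_id[sp]
            state = char_truth[sp]
            if sp in conflict_species:
                # contradictory pair: part quality (implies presence via
                # inference) against an asserted absence of the fin itself
                annotations.append(
                    PhenotypeAnnotation(sid, part, "increased thickness",
                                        ASSERTED, study())
                )
                annotations.append(
                    PhenotypeAnnotation(sid, char, ABSENT, ASSERTED, study())
                )
                continue
            if sp in replaced_species:
                continue
            indirect = rng.random() < scenario.indirect_fraction
            if state:
                if indirect:
                    ann = PhenotypeAnnotation(sid, part, "unbranched",
                                              ASSERTED, study())
                else:
                    ann = PhenotypeAnnotation(sid, char, PRESENT,
                                              ASSERTED, study())
            else:
                if indirect:
                    ann = PhenotypeAnnotation(sid, girdle, ABSENT,
                                              ASSERTED, study())
                else:
                    ann = PhenotypeAnnotation(sid, char, ABSENT,
                                              ASSERTED, study())
            annotations.append(ann)
    return annotations, conflicts


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticDataset:
    scenario: SyntheticScenario
    taxonomy: Taxonomy
    anatomy: AnatomyGraph
    tree: dendropy.Tree
    truth: GroundTruth
    annotations: list[PhenotypeAnnotation]
    planted_conflicts: dict[str, list[str]]

    @property
    def characters(self) -> tuple[str, ...]:
        return CHARACTERS


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Full synthetic input set plus ground truth for one scenario."""
    taxonomy = generate_taxonomy(scenario)
    anatomy = generate_anatomy_template()
    tree = generate_tree(taxonomy, scenario)
    truth = plant_trait_history(tree, scenario)
    annotations, conflicts = generate_annotations(
        truth, taxonomy, anatomy, scenario
    )
    return SyntheticDataset(
        scenario, taxonomy, anatomy, tree, truth, annotations, conflicts
    )


def write_fixtures(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the ready-to-run input files plus the ground-truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "anatomy_edges": outdir / "anatomy_edges.tsv",
        "anatomy_labels": outdir / "anatomy_labels.tsv",
        "annotations": outdir / "annotations.tsv",
        "tree": outdir / "tree.nwk",
        "tip_xrefs": outdir / "tip_xrefs.tsv",
        "truth_states": outdir / "truth_states.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "tip_map": outdir / "tip_map.tsv",
        "scenario": outdir / "scenario.yaml",
    }
    dataset.taxonomy.to_tsv(paths["taxonomy"])
    dataset.anatomy.to_tsv(paths["anatomy_edges"], paths["anatomy_labels"])
    write_annotations(dataset.annotations, paths["annotations"])
    dataset.tree.write(
        path=str(paths["tree"]), schema="newick",
        suppress_rooting=True, unquoted_underscores=True,
    )
    # unperturbed tips inherit the species cross-reference
    name_to_xref = {
        rec.name: rec.ncbi_id for rec in dataset.taxonomy if rec.rank == "species"
    }
    with open(paths["tip_xrefs"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tip_label", "ncbi_id"])
        for tip, species in sorted(dataset.truth.tip_name_map.items()):
            if species is None or tip.replace("_", " ") != species:
                continue  # perturbed and novel tips carry no identifier
            xref = name_to_xref.get(species)
            if xref is not None:
                w.writerow([tip, xref])
    dataset.truth.write(
        paths["truth_states"], paths["truth_events"], paths["tip_map"]
    )
    dataset.scenario.to_yaml(paths["scenario"])
    return paths
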