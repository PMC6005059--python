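"""End-to-end orchestration: inference -> matrix -> propagation -> reconciliation
-> merge -> ancestral state reconstruction.

Each stage reads its inputs from disk and writes its artifacts to the output
directory, so any stage can be re-run in isolation from the on-disk state of
the previous one. A single master seed fans out to per-stage seeds by fixed
offsets, keeping replicate streams independent but reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import matrix as mx
from . import parsimony as pars
from .inference import close_annotations, detect_conflicts, read_annotations, write_annotations
from .ontology import read_anatomy_graph
from .propagation import propagate, propagation_summary
from .reconciliation import classify_unmatched, read_xref_table, reconcile
from .synth import SyntheticScenario, generate_dataset, write_fixtures
from .taxonomy import Taxonomy
from .trees import read_tree

# fixed offsets decouple the per-stage random streams from one master seed
SEED_OFFSET_ASR = 101
SEED_OFFSET_RESOLUTION = 202


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    annotations: str
    anatomy_edges: str
    taxonomy: str
    tree: str
    output_dir: str
    anatomy_labels: Optional[str] = None
    tip_xrefs: Optional[str] = None
    characters: list[str] = field(
        default_factory=lambda: ["pectoral_fin", "pelvic_fin"]
    )
    asr_sample_size: int = 1000
    n_resolutions: int = 100
    seed: int = 0

    def __post_init__(self):
        self.characters = list(self.characters)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def out(self, name: str) -> Path:
        return Path(self.output_dir) / name

    def validate_paths(self) -> None:
        for name in ("annotations", "anatomy_edges", "taxonomy", "tree"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


# ---------------------------------------------------------------------------
# stages


def stage_infer(config: PipelineConfig) -> dict:
    graph = read_anatomy_graph(config.anatomy_edges, config.anatomy_labels)
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    annotations = read_annotations(config.annotations)
    closed = close_annotations(annotations, graph)
    write_annotations(closed, config.out("annotations_closed.tsv"))
    conflicts = detect_conflicts(closed, taxonomy, config.characters, graph)
    conflicts.to_tsv(config.out("conflicts.tsv"))
    return {
        "annotations_in": len(annotations),
        "annotations_closed": len(closed),
        "conflicts": len(conflicts.conflicts),
    }


def stage_assemble(config: PipelineConfig) -> dict:
    graph = read_anatomy_graph(config.anatomy_edges, config.anatomy_labels)
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    closed = read_annotations(config.out("annotations_closed.tsv"))
    assembled = mx.assemble(closed, config.characters, taxonomy, graph)
    assembled.to_tsv(config.out("matrix_assembled.tsv"))
    scrubbed, scrub_log = mx.scrub_apparent_polymorphisms(assembled, taxonomy)
    scrubbed.to_tsv(config.out("matrix_preprocessed.tsv"))
    return {
        "taxa": len(assembled.taxa()),
        "populated_cells": assembled.populated_count(),
        "apparent_polymorphisms_removed": sum(
            scrub_log.replaced_by_rank.values()
        ),
        "species_polymorphisms": len(scrub_log.species_polymorphisms),
        "species_conflicts": len(scrub_log.species_conflicts),
    }


def stage_propagate(config: PipelineConfig) -> dict:
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    scrubbed = mx.Supermatrix.from_tsv(config.out("matrix_preprocessed.tsv"))
    propagated, log = propagate(scrubbed, taxonomy)
    propagated.to_tsv(config.out("matrix_propagated.tsv"))
    log.to_tsv(config.out("propagation_log.tsv"))
    summary = propagation_summary(log, config.characters)
    summary.to_tsv(config.out("propagation_summary.tsv"))
    return {
        "species_rows": len(propagated.taxa()),
        "species_added": summary.species_added,
        "cells_propagated": summary.cells_propagated,
        "contributing_families": summary.contributing_families,
        "contributing_genera": summary.contributing_genera,
        "conflicts_with_asserted": summary.conflicts_with_asserted,
        "conflicts_with_inferred": summary.conflicts_with_inferred,
    }


def stage_reconcile(config: PipelineConfig) -> dict:
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    propagated = mx.Supermatrix.from_tsv(config.out("matrix_propagated.tsv"))
    tree = read_tree(config.tree)
    matrix_taxa = {t: taxonomy.name(t) for t in propagated.taxa()}
    taxon_xrefs = taxonomy.xref_table()
    tip_xrefs = (
        read_xref_table(config.tip_xrefs)
        if config.tip_xrefs and Path(config.tip_xrefs).exists()
        else {}
    )
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    report = reconcile(matrix_taxa, tips, taxon_xrefs, tip_xrefs)
    categories = classify_unmatched(report, taxonomy)
    report.to_tsv(config.out("reconciliation.tsv"))

    final = mx.Supermatrix(propagated.characters)
    for taxon in report.matched_taxa():
        for char in propagated.characters:
            final.set_cell(taxon, char, propagated.cell(taxon, char))
    final.to_tsv(config.out("matrix_final.tsv"))

    # missing-data accounting under both denominator conventions
    preprocessed = mx.Supermatrix.from_tsv(config.out("matrix_preprocessed.tsv"))
    species_only = mx.Supermatrix(preprocessed.characters)
    for taxon in preprocessed.taxa():
        if taxonomy.is_species(taxon) and any(
            preprocessed.cell(taxon, c).populated for c in preprocessed.characters
        ):
            for c in preprocessed.characters:
                species_only.set_cell(taxon, c, preprocessed.cell(taxon, c))
    n_chars = len(config.characters)
    denom_final = max(len(final.taxa()) * n_chars, 1)
    denom_tree = max(len(tips) * n_chars, 1)
    rows = []
    for label, m in (("before_propagation", species_only), ("after_propagation", final)):
        s_final = mx.missing_stats(m, denom_final, "final_species_set")
        s_tree = mx.missing_stats(m, denom_tree, "tree_tip_set")
        rows.append(
            {
                "stage": label,
                **{f"populated_{c}": s_final.populated_per_character[c]
                   for c in m.characters},
                "total_populated": s_final.total_populated,
                "pct_missing_final_matrix": round(s_final.percent_missing, 1),
                "pct_missing_merged_tree": round(s_tree.percent_missing, 1),
            }
        )
    with open(config.out("missing_data.tsv"), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        w.writerows(rows)
    return {
        "matched": len(report.matches),
        "matched_by_id": sum(1 for m in report.matches if m.method == "id"),
        "matched_by_name": sum(
            1 for m in report.matches if m.method == "exact_name"
        ),
        "unmatched_taxa": len(report.unmatched_taxa),
        "unmatched_categories": categories,
        "missing_data": rows,
    }


def stage_merge(config: PipelineConfig) -> dict:
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    final = mx.Supermatrix.from_tsv(config.out("matrix_final.tsv"))
    tree = read_tree(config.tree)
    # rows keyed by name for the NEXUS export alongside the tree tip labels
    named = mx.Supermatrix(final.characters)
    for taxon in final.taxa():
        for char in final.characters:
            named.set_cell(taxonomy.name(taxon), char, final.cell(taxon, char))
    named.write_nexus(config.out("merged.nex"), tree=tree)
    return {"merged_taxa": len(final.taxa()), "tree_tips": sum(
        1 for _ in tree.leaf_node_iter()
    )}


def stage_asr(config: PipelineConfig) -> dict:
    final = mx.Supermatrix.from_tsv(config.out("matrix_final.tsv"))
    tree = read_tree(config.tree)
    taxonomy = Taxonomy.from_tsv(config.taxonomy)
    matrix_taxa = {t: taxonomy.name(t) for t in final.taxa()}
    tip_xrefs = (
        read_xref_table(config.tip_xrefs)
        if config.tip_xrefs and Path(config.tip_xrefs).exists()
        else {}
    )
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    recon = reconcile(matrix_taxa, tips, taxonomy.xref_table(), tip_xrefs)

    out: dict = {}
    summary_rows = []
    resolution_rows = []
    for char in config.characters:
        states = pars.merge(final, tree, recon, char)
        summary = pars.summarize_mprs(
            tree, states,
            n_samples=config.asr_sample_size,
            seed=config.seed + SEED_OFFSET_ASR,
        )
        min_regains, table, _ = pars.min_regains_over_resolutions(
            tree, states,
            n_resolutions=config.n_resolutions,
            seed=config.seed + SEED_OFFSET_RESOLUTION,
        )
        out[char] = {
            "length": summary.length,
            "mpr_count": summary.mpr_count,
            "gain_min": summary.gain_min,
            "gain_max": summary.gain_max,
            "loss_min": summary.loss_min,
            "loss_max": summary.loss_max,
            "sampled_gain_mean": summary.sampled_gain_mean,
            "sampled_loss_mean": summary.sampled_loss_mean,
            "min_regains_over_resolutions": min_regains,
        }
        summary_rows.append({"character": char, **{
            k: v for k, v in out[char].items()
        }})
        for row in table:
            resolution_rows.append({"character": char, **row})
    with open(config.out("asr_summary.tsv"), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(summary_rows[0]), delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        w.writerows(summary_rows)
    with open(config.out("polytomy_resolutions.tsv"), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(resolution_rows[0]),
                           delimiter="\t", lineterminator="\n")
        w.writeheader()
        w.writerows(resolution_rows)
    return out


STAGES = (
    ("infer", stage_infer),
    ("assemble", stage_assemble),
    ("propagate", stage_propagate),
    ("reconcile", stage_reconcile),
    ("merge", stage_merge),
    ("asr", stage_asr),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; write a machine-readable run report.

    Any stage failure halts the pipeline with the stage name and cause.
    """
    config.validate_paths()
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    for name, fn in STAGES:
        try:
            report["stages"][name] = fn(config)
        except Exception as exc:  # noqa: BLE001 - aggregated into StageError
            raise StageError(name, exc) from exc
    with open(config.out("run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def make_fixtures(
    scenario: SyntheticScenario, outdir: str | Path
) -> PipelineConfig:
    """Generate a ready-to-run synthetic input set and a matching config."""
    dataset = generate_dataset(scenario)
    paths = write_fixtures(dataset, outdir)
    outdir = Path(outdir)
    config = PipelineConfig(
        annotations=str(paths["annotations"]),
        anatomy_edges=str(paths["anatomy_edges"]),
        anatomy_labels=str(paths["anatomy_labels"]),
        taxonomy=str(paths["taxonomy"]),
        tree=str(paths["tree"]),
        tip_xrefs=str(paths["tip_xrefs"]),
        output_dir=str(outdir / "out"),
        seed=scenario.seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
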