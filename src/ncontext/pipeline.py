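"""End-to-end orchestration: simulate → DE → contextual associations → report.

`run_pipeline` ties the stages together on synthetic fixtures (or any inputs
with the same shapes) and is what both the recovery tests and the ``run`` CLI
subcommand call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import AnnotationSet
from .context import (
    TargetAssociation,
    assign_parental_genes,
    filter_de_targets,
    find_antisense_targets,
    find_lincrna_neighbors,
)
from .diffexpr import Thresholds, collapse_probes, de_gene_ids, run_de
from .synthetic import ExpressionData, SimulationConfig, TruthManifest, simulate

__all__ = ["PipelineResult", "run_pipeline", "run_on_inputs"]


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    annotation: AnnotationSet
    truth: TruthManifest | None
    sequences: dict[str, str]
    expression: ExpressionData
    probe_results: pd.DataFrame
    gene_results: pd.DataFrame
    neighbor_assocs: list[TargetAssociation] = field(default_factory=list)
    antisense_assocs: list[TargetAssociation] = field(default_factory=list)
    parental_assocs: list[TargetAssociation] = field(default_factory=list)
    parental_ambiguous: list[str] = field(default_factory=list)
    parental_unassigned: list[str] = field(default_factory=list)

    @property
    def associations(self) -> list[TargetAssociation]:
        return self.neighbor_assocs + self.antisense_assocs + self.parental_assocs

    def relation_triples(self) -> set[tuple[str, str, str]]:
        return {(a.relation, a.ncrna_id, a.target_id) for a in self.associations}


def run_on_inputs(
    annotation: AnnotationSet,
    expression: ExpressionData,
    sequences: dict[str, str],
    thr: Thresholds = Thresholds(),
    truth: TruthManifest | None = None,
) -> PipelineResult:
    """Run DE and all three contextual procedures on prepared inputs.

    DE ncRNAs of each class are associated with protein-coding genes:
    neighbours must already be DE (the candidate pool is the coding DEG set),
    antisense and parental candidates are all coding genes, filtered to DE
    targets afterwards — every retained association therefore has a DE target.
    """
    probe_results = run_de(expression.matrix, expression.design, thr)
    gene_results, _ = collapse_probes(probe_results, expression.probe_map)

    de_genes = de_gene_ids(gene_results)
    biotype = {f.feature_id: f.biotype for f in annotation}
    coding = {g for g, b in biotype.items() if b == "protein_coding"}
    de_coding = de_genes & coding
    de_linc = {g for g in de_genes if biotype.get(g) == "lincRNA"}
    de_as = {g for g in de_genes if biotype.get(g) == "antisense"}
    de_psg = {g for g in de_genes if biotype.get(g) == "pseudogene"}

    neighbors = find_lincrna_neighbors(
        annotation, de_linc, de_coding, window=thr.neighbor_window
    )
    neighbors = filter_de_targets(neighbors, gene_results)

    antis = find_antisense_targets(annotation, de_as, coding)
    antis = filter_de_targets(antis, gene_results)

    psg_seqs = {g: sequences[g] for g in sorted(de_psg) if g in sequences}
    coding_seqs = {g: sequences[g] for g in sorted(coding) if g in sequences}
    parental = assign_parental_genes(pseudo_seqs=psg_seqs, coding_seqs=coding_seqs)
    parental_de = filter_de_targets(parental.associations, gene_results)

    return PipelineResult(
        annotation=annotation,
        truth=truth,
        sequences=sequences,
        expression=expression,
        probe_results=probe_results,
        gene_results=gene_results,
        neighbor_assocs=neighbors,
        antisense_assocs=antis,
        parental_assocs=parental_de,
        parental_ambiguous=parental.ambiguous,
        parental_unassigned=parental.unassigned,
    )


def run_pipeline(
    cfg: SimulationConfig, thr: Thresholds = Thresholds()
) -> PipelineResult:
    """Simulate a study under ``cfg`` and run the full analysis on it."""
    ann, truth, seqs, expr = simulate(cfg)
    return run_on_inputs(ann, expr, seqs, thr, truth=truth)
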