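"""Synthetic fixtures with known ground truth for the whole pipeline.

Emulates a two-tissue (sciatic nerve and dorsal root ganglion), five-timepoint
(days 0/1/4/7/14), three-replicate microarray design together with a gene
annotation in which three kinds of ncRNA–target relations are planted at
exactly known positions:

* each lincRNA has one protein-coding neighbour at a requested boundary gap,
* each antisense RNA overlaps a coding gene on the opposite strand by a
  requested fraction of the shorter locus,
* each pseudogene's cDNA is a mutated (substitution + indel) copy of a
  dedicated parental coding gene.

Every planted ncRNA, target and parent also receives a planted differential
expression effect in one (tissue, interval) contrast.  A :class:`TruthManifest`
records all of it so recovery can be asserted downstream.

Log2 intensities are Gaussian around a per-gene baseline (the standard
log-normal microarray assumption); the matrix is emitted on the linear scale.
To keep planted neighbour relations the *only* neighbour relations, every
differentially expressed coding gene other than a planted lincRNA target is
placed more than ``guard_window`` away from every lincRNA locus (and lincRNA
blocks are mutually separated likewise), so a noiseless run of the full
pipeline recovers the manifest exactly rather than merely containing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GenomicFeature, write_gtf

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "ExpressionData",
    "PlacementError",
    "generate_annotation",
    "generate_sequences",
    "generate_expression",
    "simulate",
    "write_fixture_dir",
]

BASES = np.array(list("ACGT"))

#: planted neighbour gaps (bp, side) drawn from published rat nerve-injury
#: lincRNA–target distances, cycled over lincRNAs
DEFAULT_NEIGHBOR_OFFSETS: tuple[tuple[int, str], ...] = (
    (274577, "right"),
    (217956, "left"),
    (487168, "left"),
    (965615, "right"),
    (1620120, "right"),
    (2852122, "right"),
)


class PlacementError(RuntimeError):
    """Chromosomes too short / too crowded for the requested features."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_chromosomes: int = 6
    chrom_length: int = 25_000_000
    n_coding: int = 40
    n_lincrna: int = 6
    n_antisense: int = 6
    n_pseudogene: int = 8
    n_de_coding: int = 0  # extra plain coding genes given planted effects
    planted_neighbor_offsets: tuple[tuple[int, str], ...] = DEFAULT_NEIGHBOR_OFFSETS
    antisense_overlap_fraction: float = 0.5
    pseudogene_mutation_rate: float = 0.05
    pseudogene_indel_rate: float = 0.005
    tissues: tuple[str, ...] = ("SN", "DRG")
    timepoints: tuple[int, ...] = (0, 1, 4, 7, 14)
    replicates: int = 3
    de_effect_log2: float = 2.0
    de_span: str = "course"  # effect in every post-baseline interval | "single"
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    feature_length_range: tuple[int, int] = (2_000, 20_000)
    cdna_length_range: tuple[int, int] = (300, 900)
    probes_per_feature: int = 1
    guard_window: int = 3_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.n_coding,
            self.n_lincrna,
            self.n_antisense,
            self.n_pseudogene,
            self.n_de_coding,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        for rate in (self.pseudogene_mutation_rate, self.pseudogene_indel_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if not 0 < self.antisense_overlap_fraction <= 1:
            raise ValueError("antisense_overlap_fraction must lie in (0, 1]")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.planted_neighbor_offsets:
            max_off = max(d for d, _ in self.planted_neighbor_offsets)
            if self.chrom_length <= 2 * max_off:
                raise ValueError(
                    "chrom_length must exceed twice the largest planted offset"
                )
            if any(
                side not in ("left", "right") or d <= 0
                for d, side in self.planted_neighbor_offsets
            ):
                raise ValueError("offsets must be (positive bp, 'left'|'right')")
        n_special = self.n_lincrna + self.n_antisense + self.n_pseudogene
        if self.n_coding < n_special + self.n_de_coding:
            raise ValueError(
                "n_coding must cover lincRNA targets, antisense targets, "
                "pseudogene parents and extra DE coding genes"
            )
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include the day-0 baseline")
        if self.probes_per_feature < 1:
            raise ValueError("probes_per_feature must be >= 1")
        if self.de_span not in ("course", "single"):
            raise ValueError("de_span must be 'course' or 'single'")

    @property
    def intervals(self) -> tuple[str, ...]:
        """Contrast labels I1..Ik for the post-baseline days in order."""
        post = sorted(d for d in self.timepoints if d != 0)
        return tuple(f"I{i + 1}" for i in range(len(post)))

    def interval_of_day(self, day: int) -> str:
        post = sorted(d for d in self.timepoints if d != 0)
        return f"I{post.index(day) + 1}"


@dataclass
class TruthManifest:
    """Planted effects and relations; ground truth for recovery tests."""

    planted_de: dict[tuple[str, str, str], float] = field(default_factory=dict)
    planted_neighbors: list[tuple[str, str, int, str]] = field(default_factory=list)
    planted_antisense: list[tuple[str, str, int]] = field(default_factory=list)
    planted_parents: dict[str, str] = field(default_factory=dict)

    def de_features(self) -> set[str]:
        return {fid for fid, _, _ in self.planted_de}

    def to_dict(self) -> dict:
        return {
            "planted_de": [
                {"feature": f, "tissue": t, "interval": i, "log2_effect": e}
                for (f, t, i), e in sorted(self.planted_de.items())
            ],
            "planted_neighbors": [
                {"lincrna": a, "target": b, "distance": d, "side": s}
                for a, b, d, s in self.planted_neighbors
            ],
            "planted_antisense": [
                {"asrna": a, "target": b, "overlap": o}
                for a, b, o in self.planted_antisense
            ],
            "planted_parents": dict(sorted(self.planted_parents.items())),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthManifest":
        return cls(
            planted_de={
                (r["feature"], r["tissue"], r["interval"]): r["log2_effect"]
                for r in d.get("planted_de", ())
            },
            planted_neighbors=[
                (r["lincrna"], r["target"], r["distance"], r["side"])
                for r in d.get("planted_neighbors", ())
            ],
            planted_antisense=[
                (r["asrna"], r["target"], r["overlap"])
                for r in d.get("planted_antisense", ())
            ],
            planted_parents=dict(d.get("planted_parents", {})),
        )


@dataclass
class ExpressionData:
    """Linear-scale probe × sample matrix plus its design and probe map."""

    matrix: pd.DataFrame
    design: pd.DataFrame  # columns: sample, tissue, day, replicate
    probe_map: dict[str, list[str]]


# ---------------------------------------------------------------------------
# placement machinery


class _Placer:
    """Rejection-sampling placement of non-overlapping blocks with margins."""

    MARGIN = 1_000
    MAX_ATTEMPTS = 2_000

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}
        # lincRNA loci and DE-coding loci, for the guard-window constraint
        self.linc_loci: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}
        self.de_coding_loci: dict[str, list[tuple[int, int]]] = {
            c: [] for c in self.chroms
        }

    def _free(self, chrom: str, start: int, end: int) -> bool:
        m = self.MARGIN
        return all(
            end + m < s or e + m < start for s, e in self.occupied[chrom]
        )

    @staticmethod
    def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
        if a[0] <= b[1] and b[0] <= a[1]:
            return 0
        return b[0] - a[1] if a[1] < b[0] else a[0] - b[1]

    def _clear_of(
        self, loci: dict[str, list[tuple[int, int]]], chrom: str, span: tuple[int, int]
    ) -> bool:
        w = self.cfg.guard_window
        return all(self._gap(span, other) > w for other in loci[chrom])

    def place(
        self,
        length: int,
        *,
        avoid_linc: bool = False,
        avoid_de_coding: bool = False,
        chrom: str | None = None,
    ) -> tuple[str, int, int]:
        """Place one block; returns (chrom, start, end), 1-based inclusive."""
        if length > self.cfg.chrom_length:
            raise PlacementError(
                f"block of {length} bp exceeds chromosome length "
                f"{self.cfg.chrom_length}"
            )
        if not self.chroms:
            raise PlacementError("no chromosomes configured")
        for _ in range(self.MAX_ATTEMPTS):
            c = chrom if chrom is not None else self.chroms[
                int(self.rng.integers(len(self.chroms)))
            ]
            start = int(self.rng.integers(1, self.cfg.chrom_length - length + 2))
            end = start + length - 1
            if not self._free(c, start, end):
                continue
            span = (start, end)
            if avoid_linc and not self._clear_of(self.linc_loci, c, span):
                continue
            if avoid_de_coding and not self._clear_of(self.de_coding_loci, c, span):
                continue
            self.occupied[c].append(span)
            return c, start, end
        raise PlacementError(
            f"could not place a {length} bp block after {self.MAX_ATTEMPTS} "
            "attempts; chromosomes too short or too crowded for the request"
        )


# ---------------------------------------------------------------------------
# generators


def _flen(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.feature_length_range
    return int(rng.integers(lo, hi + 1))


def _plant_de(
    truth: TruthManifest,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    feature_id: str,
) -> None:
    """Plant a signed effect for one feature in one rng-chosen tissue.

    Under the default ``de_span="course"`` the effect persists across every
    post-baseline interval, emulating an injury response that lasts over the
    time course; ``"single"`` confines it to one random interval.
    """
    tissue = cfg.tissues[int(rng.integers(len(cfg.tissues)))]
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if cfg.de_span == "course":
        intervals = cfg.intervals
    else:
        intervals = (cfg.intervals[int(rng.integers(len(cfg.intervals)))],)
    for interval in intervals:
        truth.planted_de[(feature_id, tissue, interval)] = sign * cfg.de_effect_log2


def generate_annotation(
    cfg: SimulationConfig,
) -> tuple[AnnotationSet, TruthManifest]:
    """Build the synthetic gene annotation and its truth manifest.

    Raises :class:`PlacementError` (never silently truncates) when the
    configured chromosomes cannot host the requested features.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    placer = _Placer(cfg, rng)
    ann = AnnotationSet()
    truth = TruthManifest()

    coding_budget = cfg.n_coding
    gene_no = 0

    def next_gene_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"GENE{gene_no:04d}"

    # lincRNA + planted neighbour target, one block per lincRNA
    for i in range(cfg.n_lincrna):
        if not cfg.planted_neighbor_offsets:
            raise ValueError("n_lincrna > 0 requires planted_neighbor_offsets")
        dist, side = cfg.planted_neighbor_offsets[
            i % len(cfg.planted_neighbor_offsets)
        ]
        linc_len, tgt_len = _flen(cfg, rng), _flen(cfg, rng)
        # gap convention: downstream.start - upstream.end
        block_len = linc_len + dist + tgt_len
        chrom, bstart, bend = placer.place(
            block_len, avoid_linc=True, avoid_de_coding=True
        )
        if side == "right":
            linc = (bstart, bstart + linc_len - 1)
            tgt = (linc[1] + dist, linc[1] + dist + tgt_len - 1)
        else:
            tgt = (bstart, bstart + tgt_len - 1)
            linc = (tgt[1] + dist, tgt[1] + dist + linc_len - 1)
        linc_id = f"LINC{i + 1:03d}"
        tgt_id = next_gene_id()
        coding_budget -= 1
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(
            GenomicFeature(
                linc_id, linc_id, chrom, linc[0], linc[1], strand, "lincRNA"
            )
        )
        ann.add(
            GenomicFeature(
                tgt_id,
                tgt_id,
                chrom,
                tgt[0],
                tgt[1],
                "+" if rng.random() < 0.5 else "-",
                "protein_coding",
            )
        )
        placer.linc_loci[chrom].append((bstart, bend))
        truth.planted_neighbors.append((linc_id, tgt_id, dist, side))
        _plant_de(truth, rng, cfg, linc_id)
        _plant_de(truth, rng, cfg, tgt_id)

    # antisense pair: coding gene + opposite-strand overlapping asRNA
    for i in range(cfg.n_antisense):
        cod_len, as_len = _flen(cfg, rng), _flen(cfg, rng)
        frac = cfg.antisense_overlap_fraction
        overlap = max(1, int(round(frac * min(cod_len, as_len))))
        block_len = cod_len + as_len - overlap
        chrom, bstart, _ = placer.place(block_len, avoid_linc=True)
        cod = (bstart, bstart + cod_len - 1)
        as_iv = (cod[1] - overlap + 1, cod[1] - overlap + as_len)
        as_id = f"ASR{i + 1:03d}"
        cod_id = next_gene_id()
        coding_budget -= 1
        strand = "+" if rng.random() < 0.5 else "-"
        anti = "-" if strand == "+" else "+"
        ann.add(
            GenomicFeature(
                cod_id, cod_id, chrom, cod[0], cod[1], strand, "protein_coding"
            )
        )
        ann.add(
            GenomicFeature(as_id, as_id, chrom, as_iv[0], as_iv[1], anti, "antisense")
        )
        placer.de_coding_loci[chrom].append(cod)
        truth.planted_antisense.append((as_id, cod_id, overlap))
        _plant_de(truth, rng, cfg, as_id)
        _plant_de(truth, rng, cfg, cod_id)

    # pseudogene + dedicated parental coding gene
    for i in range(cfg.n_pseudogene):
        psg_id = f"PSG{i + 1:03d}"
        par_id = next_gene_id()
        coding_budget -= 1
        for fid, biotype, avoid in (
            (psg_id, "pseudogene", False),
            (par_id, "protein_coding", True),
        ):
            length = _flen(cfg, rng)
            chrom, s, e = placer.place(length, avoid_linc=avoid)
            strand = "+" if rng.random() < 0.5 else "-"
            ann.add(GenomicFeature(fid, fid, chrom, s, e, strand, biotype))
            if avoid:
                placer.de_coding_loci[chrom].append((s, e))
        truth.planted_parents[psg_id] = par_id
        _plant_de(truth, rng, cfg, psg_id)
        _plant_de(truth, rng, cfg, par_id)

    # extra coding genes with planted effects, kept away from lincRNA loci
    for _ in range(cfg.n_de_coding):
        gid = next_gene_id()
        coding_budget -= 1
        length = _flen(cfg, rng)
        chrom, s, e = placer.place(length, avoid_linc=True)
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(GenomicFeature(gid, gid, chrom, s, e, strand, "protein_coding"))
        placer.de_coding_loci[chrom].append((s, e))
        _plant_de(truth, rng, cfg, gid)

    # plain (null) coding genes anywhere free
    for _ in range(coding_budget):
        gid = next_gene_id()
        length = _flen(cfg, rng)
        chrom, s, e = placer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(GenomicFeature(gid, gid, chrom, s, e, strand, "protein_coding"))

    return ann, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> str:
    """Per-site i.i.d. substitutions (always to a different base) and indels."""
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(_random_seq(rng, 1))  # insertion before the site
        if rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(ch)
    return "".join(out)


def generate_sequences(
    ann: AnnotationSet, truth: TruthManifest, cfg: SimulationConfig
) -> dict[str, str]:
    """cDNA sequences for coding genes and pseudogenes.

    Coding sequences are i.i.d. uniform (expected pairwise identity ~0.25);
    each pseudogene is a mutated copy of its parent's sequence at the
    configured substitution and indel rates.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    seqs: dict[str, str] = {}
    coding = sorted(
        f.feature_id for f in ann if f.biotype == "protein_coding"
    )
    lo, hi = cfg.cdna_length_range
    for gid in coding:
        seqs[gid] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
    for psg, parent in sorted(truth.planted_parents.items()):
        if parent not in seqs:
            raise ValueError(f"parent {parent} of {psg} has no sequence")
        seqs[psg] = _mutate(
            rng, seqs[parent], cfg.pseudogene_mutation_rate, cfg.pseudogene_indel_rate
        )
    return seqs


def generate_expression(
    ann: AnnotationSet, truth: TruthManifest, cfg: SimulationConfig
) -> ExpressionData:
    """Linear-scale intensity matrix under the planted-effect model.

    log2 intensity = per-gene baseline + planted (tissue, interval) effect +
    Normal(0, noise_sd_log2).  Columns are labelled ``{tissue}_d{day}_r{rep}``
    and the design sheet carries the same decomposition.
    """
    if 0 not in cfg.timepoints:
        raise ValueError("design lacks a day-0 baseline group")
    rng = np.random.default_rng([cfg.seed, 3])
    features = sorted(f.feature_id for f in ann)
    baselines = {
        fid: cfg.baseline_log2_mean + cfg.baseline_log2_sd * rng.standard_normal()
        for fid in features
    }

    samples = []
    for tissue in cfg.tissues:
        for day in sorted(cfg.timepoints):
            for rep in range(1, cfg.replicates + 1):
                samples.append((f"{tissue}_d{day}_r{rep}", tissue, day, rep))
    design = pd.DataFrame(samples, columns=["sample", "tissue", "day", "replicate"])

    probe_map: dict[str, list[str]] = {}
    probe_rows = []
    for fid in features:
        for j in range(1, cfg.probes_per_feature + 1):
            pid = f"P_{fid}_{j}" if cfg.probes_per_feature > 1 else f"P_{fid}"
            probe_map[pid] = [fid]
            probe_rows.append((pid, fid))

    mat = np.empty((len(probe_rows), len(samples)))
    for col, (_, tissue, day, _) in enumerate(samples):
        interval = None if day == 0 else cfg.interval_of_day(day)
        for row, (_, fid) in enumerate(probe_rows):
            mu = baselines[fid]
            if interval is not None:
                mu += truth.planted_de.get((fid, tissue, interval), 0.0)
            mat[row, col] = mu
    if cfg.noise_sd_log2 > 0:
        mat += cfg.noise_sd_log2 * rng.standard_normal(mat.shape)

    matrix = pd.DataFrame(
        np.exp2(mat),
        index=pd.Index([p for p, _ in probe_rows], name="probe"),
        columns=[s[0] for s in samples],
    )
    return ExpressionData(matrix=matrix, design=design, probe_map=probe_map)


def simulate(
    cfg: SimulationConfig,
) -> tuple[AnnotationSet, TruthManifest, dict[str, str], ExpressionData]:
    """Run all three generators under one config."""
    ann, truth = generate_annotation(cfg)
    seqs = generate_sequences(ann, truth, cfg)
    expr = generate_expression(ann, truth, cfg)
    return ann, truth, seqs, expr


def write_fixture_dir(outdir: str | Path, cfg: SimulationConfig) -> Path:
    """Materialise a complete fixture directory (GTF/FASTA/TSV/JSON).

    Output is byte-deterministic for a given config (seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth, seqs, expr = simulate(cfg)

    write_gtf(ann, outdir / "annotation.gtf")
    with open(outdir / "cdna.fa", "w") as fh:
        for fid in sorted(seqs):
            fh.write(f">{fid}\n")
            s = seqs[fid]
            for k in range(0, len(s), 60):
                fh.write(s[k : k + 60] + "\n")
    expr.matrix.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    expr.design.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "probe_map.tsv", "w") as fh:
        fh.write("probe\tgene\n")
        for probe in sorted(expr.probe_map):
            for gene in expr.probe_map[probe]:
                fh.write(f"{probe}\t{gene}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.json", "w") as fh:
        cfg_d = asdict(cfg)
        json.dump(cfg_d, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return outdir
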