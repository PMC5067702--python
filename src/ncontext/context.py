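"""Contextual ncRNA → protein-coding target association.

Three procedures, each yielding :class:`TargetAssociation` records:

* **neighbour** — for each lincRNA, every differentially expressed coding
  gene on the same chromosome within a ±window (default 3 Mb) boundary gap,
  closest first, binned per megabase and side;
* **antisense** — coding genes overlapping an antisense RNA on the opposite
  strand of the same chromosome by at least ``min_overlap`` bp;
* **parental** — for each pseudogene, the unique best-scoring coding gene by
  local sequence alignment (Smith–Waterman, affine gaps, BLASTN-like
  scoring), with score/identity ties across distinct subjects treated as
  ambiguous and reported separately.

Distances use the boundary-gap convention ``downstream.start − upstream.end``
(1-based inclusive coordinates; adjacent features have gap 1; overlapping
features gap 0).  ``distance_mode="start_to_start"`` is available as the
alternative convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from .annotation import AnnotationSet, GenomicFeature

__all__ = [
    "TargetAssociation",
    "AlignmentHit",
    "AlignmentScoring",
    "ParentalAssignment",
    "find_lincrna_neighbors",
    "find_antisense_targets",
    "local_align",
    "read_blast_tab",
    "assign_parental_genes",
    "filter_de_targets",
    "associations_to_frame",
]

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TargetAssociation:
    """One (ncRNA, putative protein-coding target) link with its evidence."""

    ncrna_id: str
    target_id: str
    relation: str  # neighbor | antisense | parental
    distance: int | None = None  # neighbor: boundary gap, 0 if overlapping
    side: str | None = None  # neighbor: left | right | overlap
    mb_bin: str | None = None  # neighbor: <=1MB | <=2MB | <=3MB | overlap
    overlap_bp: int | None = None  # antisense
    score: float | None = None  # parental
    identity: float | None = None  # parental
    aln_length: int | None = None  # parental
    target_de: bool | None = None
    de_evidence: tuple[tuple[str, str], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    length: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must lie in (0, 1]")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring; a gap of length k costs gap_open + k*gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


def _mb_bin(distance: int) -> str:
    if distance == 0:
        return "overlap"
    return f"<={max(1, math.ceil(distance / 1_000_000))}MB"


def _gap_and_side(linc: GenomicFeature, target: GenomicFeature) -> tuple[int, str]:
    if target.end < linc.start:
        return linc.start - target.end, "left"
    if target.start > linc.end:
        return target.start - linc.end, "right"
    return 0, "overlap"


def find_lincrna_neighbors(
    ann: AnnotationSet,
    lincrna_ids: Iterable[str],
    coding_deg_ids: Iterable[str],
    window: int = 3_000_000,
    distance_mode: str = "gap",
) -> list[TargetAssociation]:
    """Putative cis targets of lincRNAs among nearby coding DEGs.

    Emits every coding DEG on the lincRNA's chromosome whose distance is
    <= ``window`` (inclusive at the boundary), sorted by (lincRNA, distance,
    target) so the closest candidate ranks first.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if distance_mode not in ("gap", "start_to_start"):
        raise ValueError("distance_mode must be 'gap' or 'start_to_start'")
    deg = set(coding_deg_ids)
    out: list[TargetAssociation] = []
    for linc_id in sorted(set(lincrna_ids)):
        linc = ann.get(linc_id)
        lo = max(1, linc.start - window)
        hi = linc.end + window
        for cand in ann.overlapping(linc.chrom, lo, hi):
            if cand.feature_id == linc_id or cand.feature_id not in deg:
                continue
            if cand.biotype != "protein_coding":
                continue
            gap, side = _gap_and_side(linc, cand)
            dist = (
                gap
                if distance_mode == "gap"
                else abs(cand.start - linc.start)
            )
            if dist > window:
                continue
            out.append(
                TargetAssociation(
                    ncrna_id=linc_id,
                    target_id=cand.feature_id,
                    relation="neighbor",
                    distance=dist,
                    side=side,
                    mb_bin=_mb_bin(dist),
                )
            )
    out.sort(key=lambda a: (a.ncrna_id, a.distance, a.target_id))
    return out


def find_antisense_targets(
    ann: AnnotationSet,
    asrna_ids: Iterable[str],
    coding_ids: Iterable[str],
    min_overlap: int = 1,
) -> list[TargetAssociation]:
    """Coding genes overlapped on the opposite strand by antisense RNAs.

    A pair qualifies iff same chromosome, opposite strands, and the loci
    overlap by at least ``min_overlap`` bp (1-based inclusive intersection).
    """
    coding = set(coding_ids)
    out: list[TargetAssociation] = []
    for as_id in sorted(set(asrna_ids)):
        asr = ann.get(as_id)
        for cand in ann.overlapping(asr.chrom, asr.start, asr.end):
            if cand.feature_id == as_id or cand.feature_id not in coding:
                continue
            if cand.strand == asr.strand:
                continue
            ov = min(asr.end, cand.end) - max(asr.start, cand.start) + 1
            if ov < min_overlap:
                continue
            out.append(
                TargetAssociation(
                    ncrna_id=as_id,
                    target_id=cand.feature_id,
                    relation="antisense",
                    overlap_bp=ov,
                )
            )
    out.sort(key=lambda a: (a.ncrna_id, a.target_id))
    return out


def _validate_seq(seq: str, label: str) -> str:
    s = seq.upper()
    if not s:
        raise ValueError(f"{label}: empty sequence")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"{label}: non-ACGTN symbol(s) {sorted(bad)}")
    return s


def _aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # first gap position costs open+extend, each further position extend
    a.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    a.extend_gap_score = -scoring.gap_extend
    return a


def local_align(
    query: str,
    subject: str,
    scoring: AlignmentScoring = AlignmentScoring(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Best local alignment (Smith–Waterman, affine gaps) or None if score 0.

    Identity is counted over aligned columns (gap columns included in the
    denominator, BLAST-style).
    """
    q = _validate_seq(query, query_id)
    s = _validate_seq(subject, subject_id)
    aligner = _aligner(scoring)
    score = aligner.score(q, s)
    if score <= 0:
        return None
    aln = aligner.align(q, s)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        identity=counts.identities / length,
        length=int(length),
    )


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into alignment hits.

    Percent identity is converted to a fraction; the bitscore is used as the
    hit score.  A line with the wrong column count raises with its number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        identity=float(fields[2]) / 100.0,
                        length=int(fields[3]),
                        score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


@dataclass
class ParentalAssignment:
    """Unique parental assignments plus the ambiguous/unassigned remainder."""

    associations: list[TargetAssociation]
    ambiguous: list[str]
    unassigned: list[str]


def assign_parental_genes(
    pseudo_seqs: Mapping[str, str] | None = None,
    coding_seqs: Mapping[str, str] | None = None,
    hits: Sequence[AlignmentHit] | None = None,
    min_score: float = 50.0,
    min_identity: float = 0.7,
    scoring: AlignmentScoring = AlignmentScoring(),
    tie_policy: str = "exclude",
) -> ParentalAssignment:
    """Assign each pseudogene to at most one parental coding gene.

    Candidates come either from all-pairs local alignment of the given
    sequences or from a pre-computed hit list (BLAST tabular).  Per query,
    hits are ranked by score (ties: identity, then lexicographic subject id)
    and only the top hit is kept.  If the two best hits across *different*
    subjects tie on both score and identity the query is ambiguous: excluded
    from the unique list under ``tie_policy="exclude"`` (default) or resolved
    to the lexicographically first subject under ``tie_policy="first"``.
    Queries with no hit passing ``min_score``/``min_identity`` are unassigned.
    """
    if tie_policy not in ("exclude", "first"):
        raise ValueError("tie_policy must be 'exclude' or 'first'")
    by_query: dict[str, list[AlignmentHit]] = {}
    if hits is not None:
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        queries = sorted(by_query)
    else:
        if pseudo_seqs is None or coding_seqs is None:
            raise ValueError("provide either sequences or a hit list")
        queries = sorted(pseudo_seqs)
        for qid in queries:
            for sid in sorted(coding_seqs):
                hit = local_align(
                    pseudo_seqs[qid], coding_seqs[sid], scoring, qid, sid
                )
                if hit is not None:
                    by_query.setdefault(qid, []).append(hit)

    result = ParentalAssignment(associations=[], ambiguous=[], unassigned=[])
    for qid in queries:
        cands = [
            h
            for h in by_query.get(qid, ())
            if h.score >= min_score and h.identity >= min_identity
        ]
        if not cands:
            result.unassigned.append(qid)
            continue
        cands.sort(key=lambda h: (-h.score, -h.identity, h.subject_id))
        best = cands[0]
        tied = (
            len(cands) > 1
            and cands[1].subject_id != best.subject_id
            and cands[1].score == best.score
            and cands[1].identity == best.identity
        )
        if tied and tie_policy == "exclude":
            result.ambiguous.append(qid)
            continue
        result.associations.append(
            TargetAssociation(
                ncrna_id=qid,
                target_id=best.subject_id,
                relation="parental",
                score=best.score,
                identity=best.identity,
                aln_length=best.length,
            )
        )
    return result


def filter_de_targets(
    assocs: Iterable[TargetAssociation],
    gene_deg_table: pd.DataFrame,
    keep_all: bool = False,
) -> list[TargetAssociation]:
    """Annotate associations with target DE status and evidence contrasts.

    ``gene_deg_table`` is a gene-level contrast table with columns feature/
    tissue/interval/de.  Each association gains ``target_de`` and the sorted
    (tissue, interval) list where its target is flagged.  By default only
    associations with a DE target are returned; ``keep_all=True`` returns all
    annotated records.
    """
    de_rows = gene_deg_table[gene_deg_table["de"]]
    evidence: dict[str, list[tuple[str, str]]] = {}
    for _, row in de_rows.iterrows():
        evidence.setdefault(row["feature"], []).append(
            (row["tissue"], row["interval"])
        )
    out: list[TargetAssociation] = []
    for a in assocs:
        ev = tuple(sorted(evidence.get(a.target_id, ())))
        annotated = replace(a, target_de=bool(ev), de_evidence=ev)
        if ev or keep_all:
            out.append(annotated)
    return out


def associations_to_frame(assocs: Iterable[TargetAssociation]) -> pd.DataFrame:
    """Flat table view (TSV-ready) of association records."""
    rows = []
    for a in assocs:
        rows.append(
            {
                "ncrna": a.ncrna_id,
                "target": a.target_id,
                "relation": a.relation,
                "distance": a.distance,
                "side": a.side,
                "bin": a.mb_bin,
                "overlap": a.overlap_bp,
                "score": a.score,
                "identity": a.identity,
                "target_de": a.target_de,
                "evidence": ";".join(f"{t}_{i}" for t, i in a.de_evidence),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "ncrna",
            "target",
            "relation",
            "distance",
            "side",
            "bin",
            "overlap",
            "score",
            "identity",
            "target_de",
            "evidence",
        ],
    )
    for col in ("distance", "overlap"):  # keep bp counts integral in TSVs
        df[col] = df[col].astype("Int64")
    return df
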