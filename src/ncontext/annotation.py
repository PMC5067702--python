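"""Gene-level genome annotation: GTF parsing, biotype grouping, source merging.

The pipeline works on gene loci only — transcript structure is deliberately
discarded, since every downstream procedure (neighbourhood search, antisense
overlap, parental assignment) operates on gene coordinates.  Raw Ensembl
biotypes are consolidated into four working groups: ``protein_coding``,
``lincRNA``, ``antisense`` and ``pseudogene`` (all ``*_pseudogene``
subcategories collapse into the latter); everything else is ``other``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "BIOTYPES",
    "GenomicFeature",
    "AnnotationSet",
    "GtfParseError",
    "classify_biotype",
    "read_gtf",
    "merge_sources",
    "write_gtf",
]

#: canonical biotype groups, in reporting order
BIOTYPES = ("protein_coding", "lincRNA", "antisense", "pseudogene", "other")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated gene locus (1-based, inclusive coordinates)."""

    feature_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.feature_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def classify_biotype(raw: str | None) -> str:
    """Map a raw annotation biotype onto the four working groups.

    Total and idempotent: any string containing ``pseudogene`` (processed,
    transcribed_unprocessed, unitary, ...) collapses to ``pseudogene``;
    lincRNA/intergenic lncRNA labels map to ``lincRNA``; antisense labels to
    ``antisense``; ``protein_coding`` passes through; anything else is
    ``other``.
    """
    if raw is None:
        return "other"
    low = raw.strip().lower()
    if "pseudogene" in low:
        return "pseudogene"
    if low == "lincrna" or ("lncrna" in low and "intergenic" in low):
        return "lincRNA"
    if low in ("antisense", "antisense_rna"):
        return "antisense"
    if low == "protein_coding":
        return "protein_coding"
    return "other"


class AnnotationSet:
    """Gene features indexed by id and by (chromosome, interval).

    Features are keyed by ``(source, feature_id)``; ids must be unique within
    a source.  Interval queries use a per-chromosome interval tree and return
    exactly the features overlapping the query window (1-based inclusive on
    both sides).
    """

    def __init__(self, features: Iterable[GenomicFeature] = ()) -> None:
        self._features: dict[tuple[str, str], GenomicFeature] = {}
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self.add(f)

    def add(self, feature: GenomicFeature) -> None:
        key = (feature.source, feature.feature_id)
        if key in self._features:
            raise ValueError(f"duplicate feature {key}")
        self._features[key] = feature
        # interval tree uses half-open coords; +1 converts inclusive end
        self._trees.setdefault(feature.chrom, IntervalTree()).addi(
            feature.start, feature.end + 1, key
        )

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        try:
            self.get(feature_id)
            return True
        except KeyError:
            return False

    def get(self, feature_id: str, source: str | None = None) -> GenomicFeature:
        """Look a feature up by id, optionally restricted to one source."""
        if source is not None:
            return self._features[(source, feature_id)]
        matches = [f for (src, fid), f in self._features.items() if fid == feature_id]
        if not matches:
            raise KeyError(feature_id)
        if len(matches) > 1:
            raise KeyError(f"{feature_id} is ambiguous across sources; pass source=")
        return matches[0]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicFeature]:
        """All features overlapping [start, end] (1-based inclusive) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self._features[iv.data] for iv in tree.overlap(start, end + 1)]
        hits.sort(key=lambda f: (f.start, f.end, f.source, f.feature_id))
        return hits

    def by_biotype(self, biotype: str) -> list[GenomicFeature]:
        out = [f for f in self if f.biotype == biotype]
        out.sort(key=lambda f: (f.chrom, f.start, f.feature_id))
        return out

    @property
    def sources(self) -> list[str]:
        return sorted({f.source for f in self})

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-source, per-biotype feature counts (Table-1 shaped)."""
        out: dict[str, dict[str, int]] = {}
        for src in self.sources:
            c = Counter(f.biotype for f in self if f.source == src)
            out[src] = {b: c.get(b, 0) for b in BIOTYPES}
        return out


def _parse_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    source: str = "rat",
    chrom_normalize: bool = False,
) -> AnnotationSet:
    """Read a GTF file into gene-level features.

    Explicit ``gene`` records are used directly; for genes described only by
    transcript/exon/CDS lines the locus span is the min start / max end over
    all their records.  Attributes ``gene_id`` (required), ``gene_name`` and
    ``gene_biotype`` (``gene_type`` accepted as a synonym) are parsed.

    Chromosome labels are compared as exact strings; ``chrom_normalize=True``
    strips a leading ``chr`` prefix (Ensembl GTFs are unprefixed).
    """
    path = Path(path)
    gene_lines: dict[str, GenomicFeature] = {}
    spans: dict[str, list] = {}  # gene_id -> [chrom,start,end,strand,name,biotype]
    n_records = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected >=9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = (
                fields[:9]
            )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if chrom_normalize and chrom.startswith("chr"):
                chrom = chrom[3:]
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            name = attrs.get("gene_name", gene_id)
            biotype = classify_biotype(
                attrs.get("gene_biotype", attrs.get("gene_type"))
            )
            n_records += 1
            if ftype == "gene":
                gene_lines[gene_id] = GenomicFeature(
                    gene_id, name, chrom, start, end, strand, biotype, source
                )
            else:
                rec = spans.get(gene_id)
                if rec is None:
                    spans[gene_id] = [chrom, start, end, strand, name, biotype]
                else:
                    rec[1] = min(rec[1], start)
                    rec[2] = max(rec[2], end)

    if n_records == 0:
        warnings.warn(f"{path}: empty GTF, no features read", stacklevel=2)

    ann = AnnotationSet()
    for gid, feat in gene_lines.items():
        ann.add(feat)
    for gid, (chrom, start, end, strand, name, biotype) in spans.items():
        if gid not in gene_lines:
            ann.add(
                GenomicFeature(gid, name, chrom, start, end, strand, biotype, source)
            )
    return ann


def merge_sources(primary: AnnotationSet, secondary: AnnotationSet) -> AnnotationSet:
    """Union of two annotation sources keyed by (source, id).

    Sources must carry distinct tags so that detections unique to the
    secondary reference stay countable via :meth:`AnnotationSet.counts`.
    """
    merged = AnnotationSet()
    for f in primary:
        merged.add(f)
    for f in secondary:
        merged.add(f)
    return merged


def write_gtf(ann: AnnotationSet, path: str | Path, raw_biotypes: dict | None = None) -> None:
    """Write gene-level records as GTF, sorted by (chrom, start, id).

    ``raw_biotypes`` optionally maps feature_id to the raw biotype string to
    emit (e.g. ``processed_pseudogene``); the canonical group is written
    otherwise.
    """
    feats = sorted(ann, key=lambda f: (f.chrom, f.start, f.end, f.feature_id))
    with open(path, "w") as fh:
        for f in feats:
            raw = (raw_biotypes or {}).get(f.feature_id, f.biotype)
            attrs = (
                f'gene_id "{f.feature_id}"; gene_name "{f.gene_name}"; '
                f'gene_biotype "{raw}";'
            )
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source,
                        "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def relabel_source(feature: GenomicFeature, source: str) -> GenomicFeature:
    """Copy of a feature under a different source tag."""
    return replace(feature, source=source)
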