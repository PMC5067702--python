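"""Result assembly: evidence tables, fold-change matrices, biotype counts.

The tested artifacts are numeric tables (TSV-ready DataFrames); figure
rendering is presentation and intentionally out of scope.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, BIOTYPES
from .context import TargetAssociation

__all__ = [
    "build_evidence_table",
    "fc_heatmap_matrix",
    "biotype_count_table",
    "unique_de_counts",
]

EVIDENCE_COLUMNS = [
    "tissue",
    "ncrna",
    "target",
    "distance",
    "side",
    "bin",
    "relation",
]


def build_evidence_table(
    assocs: Iterable[TargetAssociation],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-tissue evidence rows for retained associations, closest first.

    Each association contributes one row per tissue in which its target is
    differentially expressed (the association must have been annotated by
    ``filter_de_targets`` first).  Returns the table plus per-tissue counts
    of distinct targets.
    """
    rows = []
    for a in assocs:
        tissues = sorted({t for t, _ in a.de_evidence}) or [None]
        for tissue in tissues:
            rows.append(
                {
                    "tissue": tissue,
                    "ncrna": a.ncrna_id,
                    "target": a.target_id,
                    "distance": a.distance,
                    "side": a.side,
                    "bin": a.mb_bin,
                    "relation": a.relation,
                }
            )
    df = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["tissue", "ncrna", "distance", "target"],
            kind="stable",
            na_position="last",
        ).reset_index(drop=True)
    counts = (
        df.dropna(subset=["tissue"]).groupby("tissue")["target"].nunique().to_dict()
        if len(df)
        else {}
    )
    return df, counts


def fc_heatmap_matrix(
    pairs: Sequence[tuple[str, str]],
    deg_table: pd.DataFrame,
) -> pd.DataFrame:
    """Signed fold-change matrix for (ncRNA, target) pairs across contrasts.

    Rows interleave ncRNA and target (pair order preserved); columns are
    ``{tissue}_{interval}`` for every contrast in the table.  Contrasts
    missing for a gene are NaN.  A gene absent from the table raises.
    """
    known = set(deg_table["feature"])
    genes: list[str] = []
    for nc, tg in pairs:
        for g in (nc, tg):
            if g not in known:
                raise KeyError(f"gene {g!r} not present in the contrast table")
            if g not in genes:
                genes.append(g)
    contrasts = (
        deg_table[["tissue", "interval"]]
        .drop_duplicates()
        .sort_values(["tissue", "interval"])
    )
    columns = [f"{t}_{i}" for t, i in contrasts.itertuples(index=False)]
    mat = pd.DataFrame(np.nan, index=genes, columns=columns)
    indexed = deg_table.set_index(["feature", "tissue", "interval"])["fc"]
    for g in genes:
        for (t, i), col in zip(contrasts.itertuples(index=False), columns):
            try:
                mat.loc[g, col] = indexed.loc[(g, t, i)]
            except KeyError:
                pass
    return mat


def biotype_count_table(
    deg_table: pd.DataFrame,
    annotation: AnnotationSet,
) -> pd.DataFrame:
    """DE feature counts per (biotype, tissue, interval, source).

    Zero cells are present, not absent, for every biotype group × observed
    contrast × annotation source, so secondary-source-only detections remain
    countable in their own column.
    """
    meta = {
        (f.source, f.feature_id): (f.biotype, f.source) for f in annotation
    }
    by_id: dict[str, tuple[str, str]] = {}
    for (src, fid), v in meta.items():
        by_id.setdefault(fid, v)

    de = deg_table[deg_table["de"]]
    contrasts = (
        deg_table[["tissue", "interval"]]
        .drop_duplicates()
        .sort_values(["tissue", "interval"])
    )
    sources = annotation.sources or ["synthetic"]
    counts: dict[tuple[str, str, str, str], int] = {}
    for _, row in de.iterrows():
        info = by_id.get(row["feature"])
        if info is None:
            continue
        biotype, source = info
        key = (biotype, row["tissue"], row["interval"], source)
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for biotype in BIOTYPES:
        for t, i in contrasts.itertuples(index=False):
            for src in sources:
                rows.append(
                    {
                        "biotype": biotype,
                        "tissue": t,
                        "interval": i,
                        "source": src,
                        "n_de": counts.get((biotype, t, i, src), 0),
                    }
                )
    return pd.DataFrame(rows, columns=["biotype", "tissue", "interval", "source", "n_de"])


def unique_de_counts(
    deg_table: pd.DataFrame, annotation: AnnotationSet
) -> pd.DataFrame:
    """Distinct DE features per (biotype, tissue), deduplicated across intervals."""
    by_id = {f.feature_id: f.biotype for f in annotation}
    de = deg_table[deg_table["de"]].copy()
    de["biotype"] = de["feature"].map(by_id)
    de = de.dropna(subset=["biotype"])
    out = (
        de.groupby(["biotype", "tissue"])["feature"]
        .nunique()
        .reset_index(name="n_unique")
    )
    return out.sort_values(["biotype", "tissue"], kind="stable").reset_index(drop=True)
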