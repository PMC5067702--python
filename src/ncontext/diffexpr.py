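"""Time-course differential expression against a day-0 baseline.

Each post-injury day is contrasted against the day-0 group of the same
tissue (contrasts labelled I1..I4 for days 1/4/7/14 in the emulated design).
Significance requires the conjunction |FC| > fc_min, t-test p < p_max
(pooled-variance Student by default; Welch optional), and Benjamini–Hochberg
q < q_max, with BH applied across features within each
(tissue, interval) contrast.  Probe-level results are collapsed to gene level
by keeping, per gene and contrast, the probe with the smallest q.

Fold change is computed on linear-scale group means and reported signed:
``r = mean(interval)/mean(baseline)``, returned as ``r`` when ``r >= 1`` and
``-1/r`` otherwise, so the sign encodes direction and |FC| >= 1 always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Thresholds",
    "ProbeCollapseReport",
    "normalize_log2",
    "signed_fold_change",
    "welch_t_pvalue",
    "student_t_pvalue",
    "bh_adjust",
    "run_de",
    "collapse_probes",
    "de_gene_ids",
]

RESULT_COLUMNS = ["feature", "tissue", "interval", "fc", "p", "q", "de"]


@dataclass(frozen=True)
class Thresholds:
    """Significance and context thresholds used across the pipeline."""

    fc_min: float = 1.5
    p_max: float = 0.05
    q_max: float = 0.05
    neighbor_window: int = 3_000_000
    network_confidence_min: float = 0.7

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must be > 1 (linear fold change)")
        if not (0 < self.p_max < 1 and 0 < self.q_max < 1):
            raise ValueError("p_max and q_max must lie in (0, 1)")
        if self.neighbor_window <= 0:
            raise ValueError("neighbor_window must be positive")
        if not 0 <= self.network_confidence_min <= 1:
            raise ValueError("network_confidence_min must lie in [0, 1]")


def normalize_log2(
    matrix: pd.DataFrame, median_center: bool = False
) -> pd.DataFrame:
    """log2-transform a strictly positive intensity matrix.

    ``median_center=True`` additionally subtracts each sample's median so
    per-sample medians are exactly zero.  A non-positive entry raises with
    the offending (row, column) named.
    """
    values = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~(values > 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive intensity at ({matrix.index[r]!r}, "
            f"{matrix.columns[c]!r}): {values[r, c]}"
        )
    out = pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)
    if median_center:
        out = out - out.median(axis=0)
    return out


def signed_fold_change(
    group_baseline: Sequence[float], group_interval: Sequence[float]
) -> float:
    """Signed linear fold change of interval vs baseline group means."""
    b = np.asarray(group_baseline, dtype=float)
    i = np.asarray(group_interval, dtype=float)
    if b.size == 0 or i.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = b.mean()
    if mb == 0:
        raise ZeroDivisionError("baseline group mean is zero")
    r = i.mean() / mb
    return float(r) if r >= 1 else float(-1.0 / r)


def welch_t_pvalue(
    group_a: Sequence[float],
    group_b: Sequence[float],
    var_floor: float = 1e-8,
) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on log2 values.

    Sample variances are floored at ``var_floor`` so zero-variance groups
    (common on noiseless fixtures) yield a finite statistic instead of 0/0;
    identical groups still return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va = max(a.var(ddof=1), var_floor)
    vb = max(b.var(ddof=1), var_floor)
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def student_t_pvalue(
    group_a: Sequence[float],
    group_b: Sequence[float],
    var_floor: float = 1e-8,
) -> float:
    """Two-sided pooled-variance (classical Student) t-test p-value.

    The pooled variance is floored at ``var_floor``.  With tiny replicate
    groups (n = 3 per arm in the emulated design) the pooled test keeps the
    full 2n−2 degrees of freedom and hence far more power than Welch, whose
    estimated df collapses to ~2; it is the default test of :func:`run_de`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df = a.size + b.size - 2
    sp2 = max(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df,
        var_floor,
    )
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    return float(2.0 * stats.t.sf(abs(t), df))


def _t_vectorized(
    a: np.ndarray, b: np.ndarray, var_floor: float, test: str
) -> np.ndarray:
    """Row-wise two-sided t-test p-values for feature × replicate blocks."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    if test == "welch":
        va = np.maximum(va, var_floor)
        vb = np.maximum(vb, var_floor)
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    elif test == "student":
        df = na + nb - 2
        sp2 = np.maximum(((na - 1) * va + (nb - 1) * vb) / df, var_floor)
        se2 = sp2 * (1 / na + 1 / nb)
    else:
        raise ValueError("test must be 'student' or 'welch'")
    t = diff / np.sqrt(se2)
    return 2.0 * stats.t.sf(np.abs(t), df)


def run_de(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    thr: Thresholds = Thresholds(),
    var_floor: float = 1e-8,
    test: str = "student",
) -> pd.DataFrame:
    """Per-(feature, tissue, interval) contrast table against day 0.

    ``matrix`` holds strictly positive linear-scale intensities (features ×
    samples); ``design`` has columns sample/tissue/day/replicate covering all
    matrix columns.  t-tests (pooled-variance by default, ``test="welch"``
    for unequal variances) run on log2 values, fold changes on linear group
    means, BH within each contrast.  Output sorted by (tissue, interval,
    feature) so the result is invariant to input row/column order.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    missing = [c for c in matrix.columns if c not in design.index]
    if missing:
        raise ValueError(f"design does not cover matrix columns: {missing[:5]}")

    log2 = normalize_log2(matrix)
    linear = matrix.to_numpy(dtype=float)
    log2v = log2.to_numpy()
    features = matrix.index.to_numpy()

    rows = []
    for tissue in sorted(design.loc[matrix.columns, "tissue"].unique()):
        sub = design.loc[matrix.columns]
        tissue_samples = sub[sub["tissue"] == tissue]
        days = sorted(tissue_samples["day"].unique())
        if 0 not in days:
            raise ValueError(f"tissue {tissue}: no day-0 baseline group")
        base_cols = [
            matrix.columns.get_loc(s)
            for s in tissue_samples[tissue_samples["day"] == 0].index
        ]
        post = [d for d in days if d != 0]
        for k, day in enumerate(post, start=1):
            interval = f"I{k}"
            cols = [
                matrix.columns.get_loc(s)
                for s in tissue_samples[tissue_samples["day"] == day].index
            ]
            mb = linear[:, base_cols].mean(axis=1)
            mi = linear[:, cols].mean(axis=1)
            if np.any(mb == 0):
                raise ZeroDivisionError("baseline group mean is zero")
            ratio = mi / mb
            fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
            p = _t_vectorized(log2v[:, cols], log2v[:, base_cols], var_floor, test)
            q = bh_adjust(p)
            de = (np.abs(fc) > thr.fc_min) & (p < thr.p_max) & (q < thr.q_max)
            rows.append(
                pd.DataFrame(
                    {
                        "feature": features,
                        "tissue": tissue,
                        "interval": interval,
                        "fc": fc,
                        "p": p,
                        "q": q,
                        "de": de,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["tissue", "interval", "feature"], kind="stable").reset_index(
        drop=True
    )


@dataclass
class ProbeCollapseReport:
    """Bookkeeping from probe→gene collapse."""

    n_probes: int = 0
    unmapped_probes: list[str] = field(default_factory=list)
    multi_gene_probes: list[str] = field(default_factory=list)


def collapse_probes(
    results: pd.DataFrame,
    probe_map: Mapping[str, str | Sequence[str]],
) -> tuple[pd.DataFrame, ProbeCollapseReport]:
    """Collapse probe-level contrasts to gene level.

    Per (gene, tissue, interval) the probe with the smallest q is kept (ties:
    largest |FC|, then lexicographic probe id); the gene inherits that probe's
    row including its DE flag.  A probe mapping to several genes contributes
    to each of them (logged); unmapped probes are excluded with a warning and
    counted in the report.
    """
    report = ProbeCollapseReport(n_probes=results["feature"].nunique())
    expanded = []
    for probe in results["feature"].unique():
        genes = probe_map.get(probe)
        if genes is None:
            report.unmapped_probes.append(probe)
            continue
        if isinstance(genes, str):
            genes = [genes]
        if len(genes) > 1:
            report.multi_gene_probes.append(probe)
        for g in genes:
            expanded.append((probe, g))
    if report.unmapped_probes:
        warnings.warn(
            f"{len(report.unmapped_probes)} probe(s) not in probe_map, excluded",
            stacklevel=2,
        )
    if not expanded:
        empty = results.iloc[0:0].copy()
        empty["probe"] = pd.Series(dtype=str)
        return empty, report

    mapping = pd.DataFrame(expanded, columns=["probe", "gene"])
    merged = results.rename(columns={"feature": "probe"}).merge(
        mapping, on="probe", how="inner"
    )
    merged["_absfc"] = merged["fc"].abs()
    merged = merged.sort_values(
        ["gene", "tissue", "interval", "q", "_absfc", "probe"],
        ascending=[True, True, True, True, False, True],
        kind="stable",
    )
    best = merged.groupby(["gene", "tissue", "interval"], as_index=False).first()
    best = best.drop(columns=["_absfc"]).rename(columns={"gene": "feature"})
    best = best[["feature", "tissue", "interval", "fc", "p", "q", "de", "probe"]]
    best = best.sort_values(["tissue", "interval", "feature"], kind="stable")
    return best.reset_index(drop=True), report


def de_gene_ids(gene_results: pd.DataFrame, tissue: str | None = None) -> set[str]:
    """Genes flagged DE in at least one contrast (optionally one tissue)."""
    sub = gene_results[gene_results["de"]]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    return set(sub["feature"])
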