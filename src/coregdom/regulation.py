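"""Gene response categories for a two-timepoint stimulation time course.

Expressed genes are classified from three log2 fold-change comparisons —
treatment vs vehicle at an early timepoint (2 h), at a late timepoint (12 h),
and late vs early (12 h vs 2 h) — into six response categories (early-up,
early-down, late-up, late-down, transient-up, transient-down) or left
independent.  The printed rule set defines transient responses via the late
vs early rebound, but under a literal reading the transient-up region is a
subset of the early-up acceptance region; the default "partition" convention
instead defines transient as the rebound patterns that the early rules
explicitly exclude, which makes the seven labels mutually exclusive.  The
"verbatim" convention applies the printed transient rules unchanged and
relies on transient -> early -> late precedence for single labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = (
    "early-up",
    "early-down",
    "late-up",
    "late-down",
    "transient-up",
    "transient-down",
)
INDEPENDENT = "independent"
EARLY_LIKE = ("early-up", "early-down", "transient-up", "transient-down")
LATE_LIKE = ("late-up", "late-down")
UP_CATEGORIES = ("early-up", "late-up", "transient-up")
DOWN_CATEGORIES = ("early-down", "late-down", "transient-down")


def classify_frame(
    fc2,
    fc12,
    fc12v2,
    p,
    *,
    p_late=None,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    convention: str = "partition",
) -> pd.Series:
    """Assign one category per gene.

    Parameters
    ----------
    fc2, fc12, fc12v2 : array-like
        log2FC for 2h-vs-vehicle, 12h-vs-vehicle and 12h-vs-2h.
    p : array-like
        p-value gating early/transient categories (the 2h comparison where
        per-comparison p-values exist; otherwise the single per-gene p).
    p_late : array-like, optional
        p-value gating late categories (12h comparison); defaults to `p`.
    convention : {'partition', 'verbatim'}
        Transient-rule convention (see module docstring).
    """
    if convention not in ("partition", "verbatim"):
        raise ValueError(f"unknown convention: {convention!r}")
    fc2 = np.asarray(fc2, dtype=float)
    fc12 = np.asarray(fc12, dtype=float)
    fc12v2 = np.asarray(fc12v2, dtype=float)
    p = np.asarray(p, dtype=float)
    p_late_arr = p if p_late is None else np.asarray(p_late, dtype=float)
    t = fc_threshold

    ok_early = p < p_threshold
    ok_late = p_late_arr < p_threshold

    if convention == "partition":
        trans_up = (fc2 > t) & (fc12v2 < -t)
        trans_down = (fc2 < -t) & (fc12v2 > t)
    else:  # verbatim printed rules
        trans_up = (fc2 > t) & (fc12v2 > t)
        trans_down = (fc2 < -t) & (fc12v2 < -t)
    early_up = (fc2 > t) & ~(fc12v2 < -t)
    early_down = (fc2 < -t) & ~(fc12v2 > t)
    late_up = (fc12 > t) & ~(fc2 > t)
    late_down = (fc12 < -t) & ~(fc2 < -t)

    out = np.full(fc2.shape, INDEPENDENT, dtype=object)
    # precedence transient -> early -> late: assign in reverse order
    out[ok_late & late_down] = "late-down"
    out[ok_late & late_up] = "late-up"
    out[ok_early & early_down] = "early-down"
    out[ok_early & early_up] = "early-up"
    out[ok_early & trans_down] = "transient-down"
    out[ok_early & trans_up] = "transient-up"
    return pd.Series(out, name="category")


def classify(
    fc2: float,
    fc12: float,
    fc12v2: float,
    p: float,
    *,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    convention: str = "partition",
) -> str:
    """Scalar convenience wrapper around :func:`classify_frame`."""
    return classify_frame(
        [fc2], [fc12], [fc12v2], [p],
        p_threshold=p_threshold, fc_threshold=fc_threshold, convention=convention,
    ).iloc[0]


def classify_genes(
    genes: pd.DataFrame,
    *,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    convention: str = "partition",
    out_col: str = "category",
) -> pd.DataFrame:
    """Classify a gene table in place-style (returns a copy with `out_col`).

    Non-expressed genes are labelled independent regardless of their values.
    """
    out = genes.copy()
    cat = classify_frame(
        genes["log2fc_2h"], genes["log2fc_12h"], genes["log2fc_12v2"], genes["p"],
        p_threshold=p_threshold, fc_threshold=fc_threshold, convention=convention,
    )
    cat.index = out.index
    if "expressed" in out.columns:
        cat = cat.where(out["expressed"].astype(bool), INDEPENDENT)
    out[out_col] = cat
    return out


def transient_early_overlap(
    genes: pd.DataFrame, *, p_threshold: float = 0.05, fc_threshold: float = 1.0
) -> int:
    """Number of genes matching both the printed (verbatim) transient and
    early raw predicates — the rule overlap that motivates the partition
    convention."""
    t = fc_threshold
    fc2 = genes["log2fc_2h"].to_numpy(float)
    fc12v2 = genes["log2fc_12v2"].to_numpy(float)
    p = genes["p"].to_numpy(float)
    trans = ((fc2 > t) & (fc12v2 > t)) | ((fc2 < -t) & (fc12v2 < -t))
    early = ((fc2 > t) & ~(fc12v2 < -t)) | ((fc2 < -t) & ~(fc12v2 > t))
    return int(np.sum(trans & early & (p < p_threshold)))


def defining_log2fc(genes: pd.DataFrame, category_col: str = "category") -> pd.Series:
    """log2FC of the comparison that defines each gene's category
    (2h-vs-vehicle for early/transient, 12h-vs-vehicle for late)."""
    fc = genes["log2fc_2h"].copy()
    late = genes[category_col].isin(LATE_LIKE)
    fc[late] = genes.loc[late, "log2fc_12h"]
    fc[genes[category_col] == INDEPENDENT] = np.nan
    return fc


def robust_subset(
    genes: pd.DataFrame,
    *,
    category_col: str = "category",
    fc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Robustly regulated genes: |defining log2FC| > 1 (strict) with
    adjusted p < 0.05."""
    if "p_adj" not in genes.columns:
        raise KeyError("gene table lacks required column 'p_adj'")
    fc = defining_log2fc(genes, category_col)
    keep = (
        (genes[category_col] != INDEPENDENT)
        & (fc.abs() > fc_threshold)
        & (genes["p_adj"] < padj_threshold)
    )
    return genes[keep.fillna(False)]


def filter_expressed(
    counts: pd.DataFrame,
    library_sizes=None,
    *,
    cpm_threshold: float = 2.0,
    min_replicates: int = 2,
) -> pd.Index:
    """Expressed genes: CPM >= threshold in >= `min_replicates` replicate
    columns.  `counts` is genes x replicates; library sizes default to
    column sums."""
    if counts.shape[1] < 2:
        raise ValueError("expression filtering requires at least 2 replicate columns")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    cpm = counts.to_numpy(float) / library_sizes * 1e6
    kept = (cpm >= cpm_threshold).sum(axis=1) >= min_replicates
    return counts.index[kept]
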