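"""Footprint motif-enrichment statistics, Tn5 cut-site extraction and
per-bp footprint profiles.

Enrichment of a motif in real footprints over a background footprint set:

    Enr = (footprints[motif] / footprints[total])
        / (footprints_bg[motif] / footprints_bg[total])

with a two-sided Fisher exact test on the corresponding 2x2 table.  The
background is either a 5x shuffled-sequence set per category or, for
differential enrichment, the footprints of all peaks outside the focal
category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MotifEnrichment:
    motif: str
    m: int
    total: int
    m_bg: int
    total_bg: int
    enr: float
    fisher_p: float
    infinite: bool = False


def footprint_enrichment(
    m: int,
    total: int,
    m_bg: int,
    total_bg: int,
    motif: str = "",
    continuity: bool = False,
) -> MotifEnrichment:
    """Ratio-of-proportions enrichment and two-sided Fisher exact p.

    A zero background count yields Enr = inf with infinite=True unless
    `continuity` adds +0.5 to every cell for the ratio (the Fisher test is
    always on the raw counts).
    """
    if total <= 0 or total_bg <= 0:
        raise ValueError("footprint totals must be positive")
    if m > total or m_bg > total_bg:
        raise ValueError("motif count exceeds footprint total")
    infinite = False
    if continuity:
        enr = ((m + 0.5) / (total + 0.5)) / ((m_bg + 0.5) / (total_bg + 0.5))
    elif m_bg == 0:
        enr = float("inf")
        infinite = True
    else:
        enr = (m / total) / (m_bg / total_bg)
    table = [[m, total - m], [m_bg, total_bg - m_bg]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return MotifEnrichment(motif, m, total, m_bg, total_bg, float(enr), p, infinite)


def _split_motifs(col: pd.Series) -> list[list[str]]:
    out = []
    for v in col:
        if v in (".", "", None) or (isinstance(v, float) and np.isnan(v)):
            out.append([])
        else:
            out.append(str(v).split(","))
    return out


def count_motif_footprints(footprints: pd.DataFrame, motifs=None):
    """Per-motif footprint counts and the footprint total from a table with
    one row per footprint and a comma-separated `motif` column ('.' for
    none)."""
    total = len(footprints)
    counts: dict[str, int] = {}
    for hits in _split_motifs(footprints["motif"]):
        for mot in set(hits):
            counts[mot] = counts.get(mot, 0) + 1
    if motifs is not None:
        counts = {m: counts.get(m, 0) for m in motifs}
    return counts, total


def enrichment_table(
    real: pd.DataFrame,
    background: pd.DataFrame,
    motifs=None,
    continuity: bool = False,
) -> pd.DataFrame:
    """Eq.-style enrichment of every motif in `real` footprints against the
    `background` footprint set, ranked by -log10 Fisher p."""
    counts, total = count_motif_footprints(real, motifs)
    counts_bg, total_bg = count_motif_footprints(background, motifs)
    rows = []
    for mot in sorted(set(counts) | set(counts_bg)):
        r = footprint_enrichment(
            counts.get(mot, 0), total, counts_bg.get(mot, 0), total_bg,
            motif=mot, continuity=continuity,
        )
        rows.append(vars(r))
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("fisher_p", kind="stable").reset_index(drop=True)
    return out


def differential_enrichment(
    footprints: pd.DataFrame,
    peak_categories: pd.Series,
    category: str,
    motifs=None,
    continuity: bool = False,
) -> pd.DataFrame:
    """Motif enrichment of the focal peak category's footprints against the
    footprints of all peaks in the complement categories."""
    cat_of = peak_categories.astype(str)
    fg_peaks = set(cat_of[cat_of == category].index)
    bg_peaks = set(cat_of[cat_of != category].index)
    fg = footprints[footprints["peak_id"].isin(fg_peaks)]
    bg = footprints[footprints["peak_id"].isin(bg_peaks)]
    if fg.empty:
        warnings.warn(f"no footprints in category {category!r}")
        return pd.DataFrame(
            columns=["motif", "m", "total", "m_bg", "total_bg",
                     "enr", "fisher_p", "infinite"]
        )
    if bg.empty:
        raise ValueError("empty background: focal category covers the full peak set")
    return enrichment_table(fg, bg, motifs, continuity=continuity)


def extract_cut_sites(
    fragments: pd.DataFrame,
    max_fragment: int = 100,
    shifts: tuple[int, int] = (4, -5),
) -> pd.DataFrame:
    """Transposase cut sites from sub-`max_fragment` stranded fragments.

    Each record's 5' base (start for +, end-1 for -) is shifted by +4 on
    the plus strand and -5 on the minus strand.  Negative results are
    clipped to 0 and flagged.
    """
    plus_shift, minus_shift = shifts
    length = fragments["end"] - fragments["start"]
    sub = fragments[length < max_fragment]
    plus = sub["strand"] == "+"
    pos = np.where(
        plus,
        sub["start"].to_numpy() + plus_shift,
        sub["end"].to_numpy() - 1 + minus_shift,
    )
    clipped = pos < 0
    pos = np.clip(pos, 0, None)
    return pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "position": pos.astype(int),
            "strand": sub["strand"].to_numpy(),
            "clipped": clipped,
        }
    )


def footprint_profile(
    cut_sites: pd.DataFrame,
    centers: pd.DataFrame,
    half_window: int = 50,
) -> pd.DataFrame:
    """Aggregated cut-site counts at each offset in [-half_window,
    +half_window] around motif centers (columns chrom, pos)."""
    n_off = 2 * half_window + 1
    counts = np.zeros(n_off, dtype=int)
    by_chrom = {
        c: np.sort(g["position"].to_numpy()) for c, g in cut_sites.groupby("chrom")
    }
    for chrom, center in zip(centers["chrom"], centers["pos"]):
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, center - half_window, side="left")
        hi = np.searchsorted(arr, center + half_window, side="right")
        off = arr[lo:hi] - center + half_window
        counts += np.bincount(off, minlength=n_off)[:n_off]
    return pd.DataFrame(
        {"offset": np.arange(-half_window, half_window + 1), "count": counts}
    )
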