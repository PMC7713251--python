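"""Accessibility-peak catalog: refinement, TSS partition, accessibility bins,
chromatin states, enhancer regulation categories and intergenic selection.

All intervals are 0-based half-open.  Peak summits are absolute coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import regulation
from .stats import nearest_rank_percentile

ACCESSIBILITY_BINS = ("FC<1.5", "1.5<=FC<2", "2<=FC<4", "FC>=4")
CHROMATIN_STATES = ("latent", "primed", "active", "undefined")
REGULATION_LABELS = (
    "early-activated",
    "early-repressed",
    "late-activated",
    "late-repressed",
    "transient-activated",
    "transient-repressed",
    "independent",
)

_GENE_TO_ENHANCER = {
    "early-up": "early-activated",
    "early-down": "early-repressed",
    "late-up": "late-activated",
    "late-down": "late-repressed",
    "transient-up": "transient-activated",
    "transient-down": "transient-repressed",
    "independent": "independent",
}
ACTIVATED = ("early-activated", "late-activated", "transient-activated")
REPRESSED = ("early-repressed", "late-repressed", "transient-repressed")


def _require_columns(df: pd.DataFrame, cols, what: str = "peak table") -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{what} lacks required column(s): {missing}")


def refine_peaks(
    peaks: pd.DataFrame,
    min_length: int = 150,
    merge_distance: int = 1000,
    signal_col: str = "signal",
) -> pd.DataFrame:
    """Discard peaks shorter than `min_length`, then transitively merge peaks
    whose summits lie closer than `merge_distance` on the same chromosome.

    The merged interval is the union span; the merged summit (and other
    attributes) come from the component with the highest accessibility
    signal.  Input must be sorted by (chrom, start) with summits set.
    """
    _require_columns(peaks, ["chrom", "start", "end", "summit"])
    if peaks["summit"].isna().any():
        raise ValueError("refine_peaks: missing summit in input")
    sort_key = peaks[["chrom", "start"]]
    if not sort_key.equals(sort_key.sort_values(["chrom", "start"])):
        raise ValueError("refine_peaks: input must be sorted by (chrom, start)")

    kept = peaks[(peaks["end"] - peaks["start"]) >= min_length]
    merged_rows = []
    for _, grp in kept.groupby("chrom", sort=False):
        grp = grp.sort_values("summit", kind="stable")
        summits = grp["summit"].to_numpy()
        # chain grouping on sorted summits == transitive closure of the
        # pairwise closer-than relation
        breaks = np.flatnonzero(np.diff(summits) >= merge_distance) + 1
        for block in np.split(np.arange(len(grp)), breaks):
            comp = grp.iloc[block]
            if signal_col in comp.columns and comp[signal_col].notna().all():
                best = comp.loc[comp[signal_col].idxmax()]
            else:
                best = comp.iloc[0]
            row = best.copy()
            row["start"] = comp["start"].min()
            row["end"] = comp["end"].max()
            merged_rows.append(row)
    if not merged_rows:
        return kept.iloc[0:0].copy()
    out = pd.DataFrame(merged_rows).sort_values(["chrom", "start"], kind="stable")
    return out.reset_index(drop=True)


def partition_by_tss(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 1000,
    chromosomes=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split peaks into TSS-proximal and putative enhancers.

    A peak is TSS-proximal when it overlaps any closed window
    [tss - window, tss + window] (half-open peak vs closed window).
    `tss` needs columns chrom and tss.  When `chromosomes` is given, TSS
    rows on chromosomes outside it raise a cross-reference error.
    """
    _require_columns(peaks, ["chrom", "start", "end"])
    _require_columns(tss, ["chrom", "tss"], "TSS table")
    if chromosomes is not None:
        unknown = set(tss["chrom"]) - set(chromosomes)
        if unknown:
            raise ValueError(f"TSS list names unknown chromosome(s): {sorted(unknown)}")

    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss.groupby("chrom")}
    is_prox = np.zeros(len(peaks), dtype=bool)
    for i, (chrom, start, end) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"])
    ):
        arr = tss_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        # any tss in [start - window, (end - 1) + window]
        lo = np.searchsorted(arr, start - window, side="left")
        hi = np.searchsorted(arr, end - 1 + window, side="right")
        is_prox[i] = hi > lo
    out = peaks.copy()
    out["is_tss_proximal"] = is_prox
    return out[is_prox].copy(), out[~is_prox].copy()


def assign_accessibility_category(log2fc) -> pd.Series:
    """Bin peaks by linear accessibility fold change FC = 2**log2FC into the
    four printed categories; decreases fall in the lowest bin."""
    fc_log = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(fc_log)):
        raise ValueError("accessibility log2FC must be finite")
    fc = 2.0 ** fc_log
    cat = np.select(
        [fc >= 4.0, fc >= 2.0, fc >= 1.5],
        ["FC>=4", "2<=FC<4", "1.5<=FC<2"],
        default="FC<1.5",
    )
    return pd.Series(cat, name="accessibility_category")


def mark_thresholds(
    peaks: pd.DataFrame,
    *,
    h3k27ac_percentile: float = 25.0,
    h3k4me1_percentile: float = 10.0,
    conditions=("veh", "2h", "12h"),
) -> dict[str, float]:
    """Nearest-rank RPKM thresholds per mark, pooled over all peaks and
    conditions."""
    if len(peaks) < 2:
        raise ValueError("mark thresholds undefined for fewer than 2 peaks")
    out = {}
    for mark, q in (("h3k27ac", h3k27ac_percentile), ("h3k4me1", h3k4me1_percentile)):
        cols = [f"{mark}_{c}" for c in conditions]
        _require_columns(peaks, cols)
        pooled = peaks[cols].to_numpy(float).ravel()
        out[mark] = nearest_rank_percentile(pooled, q)
    return out


def call_chromatin_state(
    peaks: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    *,
    vehicle: str = "veh",
    treatments=("2h", "12h"),
    h3k27ac_percentile: float = 25.0,
    h3k4me1_percentile: float = 10.0,
) -> pd.Series:
    """Chromatin state per peak from H3K27ac/H3K4me1 RPKM.

    A mark is present iff RPKM is strictly greater than its nearest-rank
    percentile threshold.  In vehicle: both marks -> active, H3K4me1 only ->
    primed; peaks with neither vehicle mark that acquire >=1 mark after
    treatment -> latent; neither anywhere (or H3K27ac without H3K4me1) ->
    undefined.
    """
    if thresholds is None:
        thresholds = mark_thresholds(
            peaks,
            h3k27ac_percentile=h3k27ac_percentile,
            h3k4me1_percentile=h3k4me1_percentile,
            conditions=(vehicle, *treatments),
        )

    def present(mark: str, cond: str) -> np.ndarray:
        return peaks[f"{mark}_{cond}"].to_numpy(float) > thresholds[mark]

    k27_veh = present("h3k27ac", vehicle)
    k4_veh = present("h3k4me1", vehicle)
    any_treated = np.zeros(len(peaks), dtype=bool)
    for cond in treatments:
        any_treated |= present("h3k27ac", cond) | present("h3k4me1", cond)

    state = np.full(len(peaks), "undefined", dtype=object)
    state[~k27_veh & ~k4_veh & any_treated] = "latent"
    state[k4_veh & ~k27_veh] = "primed"
    state[k4_veh & k27_veh] = "active"
    return pd.Series(state, index=peaks.index, name="chromatin_state")


def call_enhancer_regulation(
    peaks: pd.DataFrame,
    *,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    logcpm_threshold: float = 0.0,
    convention: str = "partition",
) -> pd.Series:
    """Enhancer regulation categories from H3K27ac differential binding.

    Applies the gene rule table to the H3K27ac log2FCs, additionally
    requiring p < 0.05 and mean log2CPM > 0 in the defining comparison
    (2h-vs-vehicle for early/transient, 12h-vs-vehicle for late).
    """
    needed = [
        "k27ac_log2fc_2h", "k27ac_log2fc_12h", "k27ac_log2fc_12v2",
        "k27ac_p_2h", "k27ac_p_12h", "k27ac_logcpm_2h", "k27ac_logcpm_12h",
    ]
    _require_columns(peaks, needed)
    # fold the log2CPM gate into the comparison p: a failing expression gate
    # behaves like a non-significant comparison
    p_early = np.where(
        peaks["k27ac_logcpm_2h"].to_numpy(float) > logcpm_threshold,
        peaks["k27ac_p_2h"].to_numpy(float), 1.0,
    )
    p_late = np.where(
        peaks["k27ac_logcpm_12h"].to_numpy(float) > logcpm_threshold,
        peaks["k27ac_p_12h"].to_numpy(float), 1.0,
    )
    cat = regulation.classify_frame(
        peaks["k27ac_log2fc_2h"], peaks["k27ac_log2fc_12h"],
        peaks["k27ac_log2fc_12v2"], p_early, p_late=p_late,
        p_threshold=p_threshold, fc_threshold=fc_threshold,
        convention=convention,
    )
    out = cat.map(_GENE_TO_ENHANCER)
    out.index = peaks.index
    out.name = "regulation"
    return out


def select_intergenic_enhancers(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    tts_extension: int = 5000,
    erna_halfwidth: int = 200,
) -> pd.DataFrame:
    """Keep peaks not overlapping any gene body extended `tts_extension`
    past the TTS (strand-aware); survivors carry an eRNA quantification
    window of summit +/- `erna_halfwidth`."""
    _require_columns(peaks, ["chrom", "start", "end", "summit"])
    _require_columns(genes, ["chrom", "start", "end", "strand"], "gene table")

    ext = genes.copy()
    plus = ext["strand"] == "+"
    ext.loc[plus, "end"] = ext.loc[plus, "end"] + tts_extension
    ext.loc[~plus, "start"] = (ext.loc[~plus, "start"] - tts_extension).clip(lower=0)

    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in ext.groupby("chrom"):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))

    keep = np.ones(len(peaks), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(peaks["chrom"], peaks["start"], peaks["end"])):
        iv = merged.get(chrom)
        if iv is None:
            continue
        starts, ends = iv
        j = np.searchsorted(starts, e, side="left") - 1
        # overlaps interval j (the last one starting before the peak end)?
        keep[i] = not (j >= 0 and ends[j] > s)
    out = peaks[keep].copy()
    out["erna_start"] = out["summit"] - erna_halfwidth
    out["erna_end"] = out["summit"] + erna_halfwidth
    return out


def normalize_counts(counts, library_sizes, feature_lengths):
    """CPM and RPKM.  For enhancer-mark quantification the library size is
    the total of reads counted in peaks."""
    counts = np.asarray(counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    feature_lengths = np.asarray(feature_lengths, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    if np.any(feature_lengths <= 0):
        raise ValueError("feature lengths must be positive")
    cpm = counts / library_sizes * 1e6
    rpkm = cpm / (feature_lengths / 1000.0)
    return cpm, rpkm
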