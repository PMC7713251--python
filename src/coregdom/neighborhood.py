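"""Genome-order neighborhood statistics around enhancers and genes.

Expressed genes are numbered 1..n per chromosome by ascending TSS.  For an
enhancer anchor, Eg+-n denotes the n-th expressed gene downstream (+) or
upstream (-) of the summit in pure chromosome-coordinate order (never
strand-relative).  Gene anchors use the same ordinals directly (n +- k).
Randomization is by circular shift of the per-chromosome anchor list
(default, 50 positions) or by uniform sampling without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RandomizationScheme:
    method: str = "circular_shift"  # or 'sample'
    shift_k: int = 50
    iterations: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("circular_shift", "sample"):
            raise ValueError(f"unknown randomization method: {self.method!r}")


def order_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome ordinals (1..n) over expressed genes by ascending TSS.

    Non-expressed genes are dropped.  Duplicate TSS are broken stably by
    gene_id.
    """
    sub = genes[genes["expressed"].astype(bool)].copy()
    sub = sub.sort_values(["chrom", "tss", "gene_id"], kind="stable")
    sub["ordinal"] = sub.groupby("chrom", sort=False).cumcount() + 1
    return sub.reset_index(drop=True)


def assign_enhancer_neighbors(
    enhancers: pd.DataFrame,
    ordered_genes: pd.DataFrame,
    max_n: int = 4,
    anchor_id_col: str = "peak_id",
) -> pd.DataFrame:
    """Up-to-`max_n` nearest expressed genes on each side of every enhancer
    summit.  Positions are signed (-max_n..-1, +1..+max_n); distances are
    TSS - summit.  A TSS exactly at the summit counts as downstream (+1)."""
    by_chrom = {
        c: g.sort_values("ordinal")
        for c, g in ordered_genes.groupby("chrom", sort=False)
    }
    known = set(by_chrom)
    rows = []
    for aid, chrom, summit in zip(
        enhancers[anchor_id_col], enhancers["chrom"], enhancers["summit"]
    ):
        if chrom not in known:
            raise ValueError(f"enhancer {aid!r} on unknown chromosome {chrom!r}")
        grp = by_chrom[chrom]
        tss = grp["tss"].to_numpy()
        gid = grp["gene_id"].to_numpy()
        idx = np.searchsorted(tss, summit, side="left")  # first tss >= summit
        for n in range(1, max_n + 1):
            j = idx - n
            if j >= 0:
                rows.append((aid, gid[j], -n, int(tss[j] - summit)))
            j = idx + n - 1
            if j < len(tss):
                rows.append((aid, gid[j], n, int(tss[j] - summit)))
    return pd.DataFrame(rows, columns=["anchor_id", "gene_id", "position", "distance"])


def assign_gene_neighbors(
    anchor_gene_ids,
    ordered_genes: pd.DataFrame,
    max_n: int = 4,
) -> pd.DataFrame:
    """Neighbors n+-k of anchor genes in expressed-gene ordinal space."""
    anchor_set = set(anchor_gene_ids)
    rows = []
    for chrom, grp in ordered_genes.groupby("chrom", sort=False):
        grp = grp.sort_values("ordinal")
        gid = grp["gene_id"].to_numpy()
        tss = grp["tss"].to_numpy()
        anchor_idx = np.flatnonzero(np.isin(gid, list(anchor_set)))
        for i in anchor_idx:
            for n in range(1, max_n + 1):
                for sign, j in ((-1, i - n), (1, i + n)):
                    if 0 <= j < len(gid):
                        rows.append(
                            (gid[i], gid[j], sign * n, int(tss[j] - tss[i]))
                        )
    return pd.DataFrame(rows, columns=["anchor_id", "gene_id", "position", "distance"])


def randomize_anchors(
    universe: pd.DataFrame,
    anchor_ids,
    scheme: RandomizationScheme,
    *,
    id_col: str = "peak_id",
    pos_col: str = "summit",
    rng: np.random.Generator | None = None,
) -> dict:
    """Map each anchor id to a randomized id drawn from the per-chromosome
    universe, by circular shift of the ordered list or by sampling without
    replacement."""
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    anchor_set = set(anchor_ids)
    mapping: dict = {}
    for chrom, grp in universe.groupby("chrom", sort=False):
        grp = grp.sort_values([pos_col, id_col], kind="stable")
        ids = grp[id_col].to_numpy()
        L = len(ids)
        if L == 0:
            warnings.warn(f"empty anchor universe on chromosome {chrom!r}; skipped")
            continue
        sel = [i for i, x in enumerate(ids) if x in anchor_set]
        if not sel:
            continue
        if scheme.method == "circular_shift":
            for i in sel:
                mapping[ids[i]] = ids[(i + scheme.shift_k) % L]
        else:
            drawn = rng.choice(L, size=len(sel), replace=False)
            for i, j in zip(sel, drawn):
                mapping[ids[i]] = ids[j]
    return mapping


def assign_distance_bins(
    distances,
    bin_size: int = 50_000,
    max_distance: int = 250_000,
) -> pd.DataFrame:
    """Signed distance -> (side, bin) with half-open bins [k*50k,(k+1)*50k).

    d = 0 belongs to the first downstream bin; |d| >= max_distance is out of
    range (in_range False, bin <NA>).
    """
    d = np.asarray(distances, dtype=float)
    side = np.where(d < 0, "-", "+")
    absd = np.abs(d)
    in_range = absd < max_distance
    bins = np.floor_divide(absd, bin_size).astype(int)
    out = pd.DataFrame({"side": side, "bin": bins, "in_range": in_range})
    out.loc[~in_range, "bin"] = pd.NA
    return out


def group_by_distance(
    assignments: pd.DataFrame,
    bin_size: int = 50_000,
    max_distance: int = 250_000,
) -> pd.DataFrame:
    """Attach distance-interval bins to a neighborhood assignment table and
    drop out-of-range rows."""
    bins = assign_distance_bins(assignments["distance"], bin_size, max_distance)
    bins.index = assignments.index
    out = pd.concat([assignments, bins], axis=1)
    return out[out["in_range"]].drop(columns="in_range")


def _fc_lookup(ordered_genes: pd.DataFrame, fc_col: str) -> pd.Series:
    return ordered_genes.set_index("gene_id")[fc_col]


def _position_summary(
    real: pd.DataFrame, random: pd.DataFrame, fc: pd.Series, max_n: int
) -> pd.DataFrame:
    rows = []
    for pos in [*range(-max_n, 0), *range(1, max_n + 1)]:
        rf = fc.reindex(real.loc[real["position"] == pos, "gene_id"]).dropna().to_numpy()
        qf = fc.reindex(random.loc[random["position"] == pos, "gene_id"]).dropna().to_numpy()
        if len(rf) and len(qf):
            p = float(sps.mannwhitneyu(rf, qf, alternative="two-sided").pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "position": pos,
                "n_real": len(rf),
                "n_random": len(qf),
                "median_real": float(np.median(rf)) if len(rf) else np.nan,
                "median_random": float(np.median(qf)) if len(qf) else np.nan,
                "mannwhitney_p": p,
            }
        )
    return pd.DataFrame(rows)


def enhancer_neighborhood_summary(
    enhancers: pd.DataFrame,
    category: str,
    ordered_genes: pd.DataFrame,
    fc_col: str = "log2fc_2h",
    scheme: RandomizationScheme | None = None,
    max_n: int = 4,
    regulation_col: str = "regulation",
) -> pd.DataFrame:
    """Per-position (Eg-4..Eg+4) neighbor log2FC summary for anchors of one
    enhancer regulation category, against the randomization null."""
    if scheme is None:
        scheme = RandomizationScheme()
    anchors = enhancers[enhancers[regulation_col] == category]
    if anchors.empty:
        warnings.warn(f"no enhancers in category {category!r}")
        return pd.DataFrame(
            columns=["position", "n_real", "n_random",
                     "median_real", "median_random", "mannwhitney_p"]
        )
    real = assign_enhancer_neighbors(anchors, ordered_genes, max_n)
    rng = np.random.default_rng(scheme.seed)
    rand_parts = []
    for _ in range(scheme.iterations):
        mapping = randomize_anchors(enhancers, anchors["peak_id"], scheme, rng=rng)
        rand_ids = [mapping[a] for a in anchors["peak_id"] if a in mapping]
        rand_anchors = enhancers[enhancers["peak_id"].isin(rand_ids)]
        rand_parts.append(assign_enhancer_neighbors(rand_anchors, ordered_genes, max_n))
    random = pd.concat(rand_parts, ignore_index=True)
    return _position_summary(real, random, _fc_lookup(ordered_genes, fc_col), max_n)


def gene_neighborhood_summary(
    anchor_gene_ids,
    ordered_genes: pd.DataFrame,
    fc_col: str = "log2fc_2h",
    scheme: RandomizationScheme | None = None,
    max_n: int = 4,
) -> pd.DataFrame:
    """Per-position (n-4..n+4) neighbor log2FC summary for gene anchors
    against the randomization null."""
    if scheme is None:
        scheme = RandomizationScheme()
    anchor_gene_ids = list(anchor_gene_ids)
    if not anchor_gene_ids:
        warnings.warn("no anchor genes supplied")
        return pd.DataFrame(
            columns=["position", "n_real", "n_random",
                     "median_real", "median_random", "mannwhitney_p"]
        )
    real = assign_gene_neighbors(anchor_gene_ids, ordered_genes, max_n)
    rng = np.random.default_rng(scheme.seed)
    rand_parts = []
    for _ in range(scheme.iterations):
        mapping = randomize_anchors(
            ordered_genes, anchor_gene_ids, scheme,
            id_col="gene_id", pos_col="tss", rng=rng,
        )
        rand_ids = [mapping[a] for a in anchor_gene_ids if a in mapping]
        rand_parts.append(assign_gene_neighbors(rand_ids, ordered_genes, max_n))
    random = pd.concat(rand_parts, ignore_index=True)
    return _position_summary(real, random, _fc_lookup(ordered_genes, fc_col), max_n)


def continuity_test(
    enhancers: pd.DataFrame,
    category: str,
    ordered_genes: pd.DataFrame,
    robust_gene_ids,
    target_position: int,
    fc_col: str = "log2fc_2h",
    scheme: RandomizationScheme | None = None,
    regulation_col: str = "regulation",
) -> dict:
    """Continuity of enhancer influence: restrict to anchors whose Eg+2 (or
    Eg-2) gene is robustly regulated in the enhancer's direction, then
    report log2FC distributions of the interposed and flanking positions
    together with the random-anchor baseline.

    Only target positions -2 and +2 are supported.
    """
    if target_position not in (-2, 2):
        raise ValueError("continuity target position must be -2 or +2")
    if scheme is None:
        scheme = RandomizationScheme()
    robust_set = set(robust_gene_ids)
    anchors = enhancers[enhancers[regulation_col] == category]
    assign = assign_enhancer_neighbors(anchors, ordered_genes)
    at_target = assign[
        (assign["position"] == target_position)
        & assign["gene_id"].isin(robust_set)
    ]
    qualifying = set(at_target["anchor_id"])
    sign = 1 if target_position > 0 else -1
    inner = [-2 * sign, -1 * sign, 1 * sign]
    if not qualifying:
        warnings.warn("no qualifying enhancers for continuity test")
        return {"n_anchors": 0, "positions": {}, "baseline": {}}

    fc = _fc_lookup(ordered_genes, fc_col)
    sub = assign[assign["anchor_id"].isin(qualifying)]
    positions = {
        pos: fc.reindex(sub.loc[sub["position"] == pos, "gene_id"]).dropna().to_numpy()
        for pos in inner
    }
    rng = np.random.default_rng(scheme.seed)
    mapping = randomize_anchors(enhancers, qualifying, scheme, rng=rng)
    rand_anchors = enhancers[enhancers["peak_id"].isin(list(mapping.values()))]
    rand_assign = assign_enhancer_neighbors(rand_anchors, ordered_genes)
    baseline = {
        pos: fc.reindex(
            rand_assign.loc[rand_assign["position"] == pos, "gene_id"]
        ).dropna().to_numpy()
        for pos in inner
    }
    return {"n_anchors": len(qualifying), "positions": positions, "baseline": baseline}


def binned_fc_correlation(x, y, n_bins: int = 20):
    """Sort pairs by x, split into `n_bins` near-equal groups, and compute
    Spearman rho and the least-squares slope on the binned means.

    Returns (rho, slope, DataFrame of binned means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 3:
        raise ValueError("binned correlation requires at least 3 bins")
    if len(x) < n_bins:
        raise ValueError(f"need at least {n_bins} pairs, got {len(x)}")
    if np.all(x == x[0]):
        raise ValueError("degenerate binning: all x values identical")
    order = np.argsort(x, kind="stable")
    groups = np.array_split(order, n_bins)
    bx = np.array([x[g].mean() for g in groups])
    by = np.array([y[g].mean() for g in groups])
    rho = float(sps.spearmanr(bx, by).statistic)
    slope = float(sps.linregress(bx, by).slope)
    bins = pd.DataFrame({"x_mean": bx, "y_mean": by, "n": [len(g) for g in groups]})
    return rho, slope, bins


def exclusion_intervals(genes: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Regions masked from signal metaplots: whole gene bodies +-2 kb
    ('gene_bodies'), TSS +-5 kb ('tss'), or nothing ('none')."""
    if mode == "none":
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if mode == "gene_bodies":
        out = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": (genes["start"] - 2000).clip(lower=0),
                "end": genes["end"] + 2000,
            }
        )
    elif mode == "tss":
        out = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": (genes["tss"] - 5000).clip(lower=0),
                "end": genes["tss"] + 5000,
            }
        )
    else:
        raise ValueError(f"unknown exclusion mode: {mode!r}")
    return out.reset_index(drop=True)


def _mask_points(signal: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    if exclusions.empty:
        return signal
    keep = np.ones(len(signal), dtype=bool)
    for chrom, grp in exclusions.groupby("chrom"):
        ivs = grp.sort_values("start")
        starts, ends = [], []
        for s, e in zip(ivs["start"], ivs["end"]):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        m = signal["chrom"] == chrom
        pos = signal.loc[m, "pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        keep[np.flatnonzero(m.to_numpy())[inside]] = False
    return signal[keep]


def _profile(
    anchors: pd.DataFrame, signal: pd.DataFrame,
    window: int, bin_size: int, t_lib: float, c_lib: float,
) -> np.ndarray:
    n_bins = 2 * window // bin_size
    t_sum = np.zeros(n_bins)
    c_sum = np.zeros(n_bins)
    by_chrom = {c: g.sort_values("pos") for c, g in signal.groupby("chrom")}
    for chrom, tss in zip(anchors["chrom"], anchors["tss"]):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, tss - window, side="left")
        hi = np.searchsorted(pos, tss + window, side="left")
        off = pos[lo:hi] - tss + window
        idx = off // bin_size
        np.add.at(t_sum, idx, grp["treat"].to_numpy()[lo:hi])
        np.add.at(c_sum, idx, grp["ctrl"].to_numpy()[lo:hi])
    return np.log2((t_sum + 0.5) / (c_sum + 0.5) * (c_lib / t_lib))


def signal_metaplot_around_genes(
    anchor_genes: pd.DataFrame,
    random_genes: pd.DataFrame,
    signal: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    window: int = 250_000,
    bin_size: int = 10_000,
    exclusion: str = "none",
) -> pd.DataFrame:
    """Per-bin log2FC-over-random profile of a treatment/control signal
    around anchor gene TSSs.

    `signal` holds point-mass counts (chrom, pos, treat, ctrl).  Excluded
    regions (gene bodies +-2 kb or TSS +-5 kb) contribute no counts.  The
    profile of the random anchors is subtracted bin-to-bin.
    """
    if window % bin_size != 0:
        raise ValueError("bin size must divide the window")
    if exclusion != "none":
        if genes is None:
            raise ValueError("exclusion modes need the gene table")
        signal = _mask_points(signal, exclusion_intervals(genes, exclusion))
    t_lib = float(signal["treat"].sum()) or 1.0
    c_lib = float(signal["ctrl"].sum()) or 1.0
    real = _profile(anchor_genes, signal, window, bin_size, t_lib, c_lib)
    rand = _profile(random_genes, signal, window, bin_size, t_lib, c_lib)
    n_bins = 2 * window // bin_size
    offsets = (np.arange(n_bins) - n_bins // 2) * bin_size
    return pd.DataFrame(
        {"offset": offsets, "log2fc_real": real, "log2fc_random": rand,
         "log2fc_over_random": real - rand}
    )
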