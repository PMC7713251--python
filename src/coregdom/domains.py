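"""Regulatory-domain calling and its randomization nulls.

A regulatory domain (TRD) is a maximal run of >= 2 contiguous expressed
genes sharing a response category under relaxed thresholds (|log2FC| > 0.5,
p < 0.05).  Contiguity is in expressed-gene order; non-expressed genes are
skipped.  Nulls are built by sampling gene positions (pair counts), by
permuting gene-to-TAD assignment (TAD co-regulation), or by circular shifts
of positions/borders.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import regulation
from .neighborhood import binned_fc_correlation, order_genes
from .peaks import ACTIVATED, REPRESSED
from .stats import NullDistribution

TRD_CATEGORIES = ("early-up", "early-down", "late-up", "late-down")


def _global_order(ordered_genes: pd.DataFrame):
    """Concatenated per-chromosome orderings with chromosome-break mask.

    Returns (gene_ids, valid_adjacency) where valid_adjacency[i] is True
    when positions i and i+1 are on the same chromosome.
    """
    ordered = ordered_genes.sort_values(["chrom", "ordinal"], kind="stable")
    gid = ordered["gene_id"].to_numpy()
    chrom = ordered["chrom"].to_numpy()
    valid = chrom[:-1] == chrom[1:]
    return gid, valid, ordered


def count_contiguous_pairs(ordered_genes: pd.DataFrame, member_ids) -> int:
    """Adjacent expressed-gene pairs (ordinals i, i+1) with both members in
    the set, summed over chromosomes."""
    gid, valid, _ = _global_order(ordered_genes)
    member = np.isin(gid, list(set(member_ids)))
    return int(np.sum(member[:-1] & member[1:] & valid))


def pair_count_null(
    ordered_genes: pd.DataFrame,
    m: int,
    iterations: int = 5000,
    seed: int | None = None,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the contiguous-pair count: each iteration
    samples m expressed-gene positions genome-wide without replacement and
    counts adjacent same-chromosome pairs."""
    gid, valid, _ = _global_order(ordered_genes)
    N = len(gid)
    if m > N:
        raise ValueError(f"cannot sample {m} genes from {N} expressed genes")
    rng = np.random.default_rng(seed)
    counts = np.empty(iterations, dtype=float)
    member = np.zeros(N, dtype=bool)
    for i in range(iterations):
        sel = rng.choice(N, size=m, replace=False)
        member[:] = False
        member[sel] = True
        counts[i] = np.sum(member[:-1] & member[1:] & valid)
    return NullDistribution(
        statistic="contiguous_pairs", observed=observed,
        iterations=iterations, values=counts, seed=seed, tail="upper",
    )


def expected_pair_count(n_per_chrom, m: int) -> float:
    """Closed-form expected contiguous-pair count when m genes are sampled
    genome-wide without replacement: sum_c (N_c - 1) * C(m,2) / C(N,2)."""
    n_per_chrom = np.asarray(n_per_chrom)
    N = int(n_per_chrom.sum())
    if m < 2:
        return 0.0
    pair_prob = (m * (m - 1)) / (N * (N - 1))
    return float(np.sum(n_per_chrom - 1) * pair_prob)


def count_runs(labels: np.ndarray, valid: np.ndarray) -> int:
    """Number of maximal runs (length >= 2) of equal non-'none' labels over
    positions whose adjacency is valid (same chromosome)."""
    if len(labels) < 2:
        return 0
    same = (labels[:-1] == labels[1:]) & (labels[:-1] != "none") & valid
    starts = same & ~np.r_[False, same[:-1]]
    return int(starts.sum())


def trd_count_null(
    genes: pd.DataFrame,
    iterations: int = 5000,
    seed: int | None = None,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    categories=TRD_CATEGORIES,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the domain count: permute the relaxed category
    labels across expressed-gene positions genome-wide and count maximal
    same-category runs of length >= 2."""
    ordered = order_genes(genes)
    cats = regulation.classify_frame(
        ordered["log2fc_2h"], ordered["log2fc_12h"], ordered["log2fc_12v2"],
        ordered["p"], p_threshold=p_threshold, fc_threshold=fc_threshold,
    ).to_numpy()
    labels = np.where(np.isin(cats, list(categories)), cats, "none")
    _, valid, _ = _global_order(ordered)
    if observed is None:
        observed = count_runs(labels, valid)
    rng = np.random.default_rng(seed)
    # vectorized label permutations: integer codes, -1 for 'none'
    codes = np.full(len(labels), -1, dtype=np.int8)
    for k, cat in enumerate(categories):
        codes[labels == cat] = k
    perm = np.argsort(rng.random((iterations, len(codes))), axis=1)
    L = codes[perm]
    same = (L[:, :-1] == L[:, 1:]) & (L[:, :-1] >= 0) & valid[None, :]
    starts = same & ~np.concatenate(
        [np.zeros((iterations, 1), dtype=bool), same[:, :-1]], axis=1
    )
    counts = starts.sum(axis=1).astype(float)
    return NullDistribution(
        statistic="trd_count", observed=float(observed),
        iterations=iterations, values=counts, seed=seed, tail="upper",
    )


def call_trds(
    genes: pd.DataFrame,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    min_genes: int = 2,
    categories=TRD_CATEGORIES,
    span: str = "gene_bodies",
    category_col: str | None = None,
) -> pd.DataFrame:
    """Call regulatory domains as maximal same-category runs of contiguous
    expressed genes under relaxed thresholds.

    The domain span is the union of member gene bodies by default
    (`span='tss'` uses the TSS extent).  Categories are re-derived with the
    relaxed thresholds unless `category_col` names an existing column.
    """
    ordered = order_genes(genes)
    if category_col is None:
        cats = regulation.classify_frame(
            ordered["log2fc_2h"], ordered["log2fc_12h"], ordered["log2fc_12v2"],
            ordered["p"], p_threshold=p_threshold, fc_threshold=fc_threshold,
        ).to_numpy()
    else:
        cats = ordered[category_col].to_numpy()
    eligible = np.isin(cats, list(categories))
    labels = np.where(eligible, cats, "none")

    rows = []
    did = 0
    for chrom, grp_idx in ordered.groupby("chrom", sort=False).indices.items():
        lab = labels[grp_idx]
        sub = ordered.iloc[grp_idx]
        i = 0
        while i < len(lab):
            if lab[i] == "none":
                i += 1
                continue
            j = i
            while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                j += 1
            if j - i + 1 >= min_genes:
                members = sub.iloc[i : j + 1]
                if span == "tss":
                    start = int(members["tss"].min())
                    end = int(members["tss"].max()) + 1
                else:
                    start = int(members["start"].min())
                    end = int(members["end"].max())
                did += 1
                rows.append(
                    {
                        "domain_id": f"trd_{did}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "category": lab[i],
                        "gene_ids": list(members["gene_id"]),
                        "n_genes": j - i + 1,
                        "size_kb": (end - start) / 1000.0,
                        "first_ordinal": int(members["ordinal"].iloc[0]),
                        "last_ordinal": int(members["ordinal"].iloc[-1]),
                    }
                )
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "domain_id", "chrom", "start", "end", "category", "gene_ids",
            "n_genes", "size_kb", "first_ordinal", "last_ordinal",
        ],
    )


def _concordant(trd_category: str, enh_regulation: np.ndarray) -> np.ndarray:
    if trd_category.endswith("-up"):
        return np.isin(enh_regulation, list(ACTIVATED))
    return np.isin(enh_regulation, list(REPRESSED))


def _associated_mask(
    trds: pd.DataFrame, enh_chrom, enh_summit, enh_reg, vicinity: int
) -> np.ndarray:
    out = np.zeros(len(trds), dtype=bool)
    for k, (chrom, start, end, cat) in enumerate(
        zip(trds["chrom"], trds["start"], trds["end"], trds["category"])
    ):
        m = (enh_chrom == chrom) & _concordant(cat, enh_reg)
        s = enh_summit[m]
        out[k] = np.any((s >= start - vicinity) & (s <= end + vicinity))
    return out


def associate_enhancers(
    trds: pd.DataFrame,
    enhancers: pd.DataFrame,
    vicinity: int = 50_000,
    iterations: int = 1000,
    seed: int | None = None,
    method: str = "shift",
    regulation_col: str = "regulation",
) -> tuple[pd.DataFrame, NullDistribution | float]:
    """Associate each domain with concordantly regulated enhancers within
    its span +- `vicinity`, and test genome-wide enrichment.

    method='shift' (default): circular shift of summit assignments within
    the per-chromosome enhancer list, `iterations` random shifts; returns
    the fraction-associated NullDistribution.  method='hypergeometric':
    overlap probability of concordant enhancers among vicinity enhancers;
    returns a p-value.
    """
    enh_chrom = enhancers["chrom"].to_numpy()
    enh_summit = enhancers["summit"].to_numpy()
    enh_reg = enhancers[regulation_col].to_numpy()

    assoc = _associated_mask(trds, enh_chrom, enh_summit, enh_reg, vicinity)
    out = trds.copy()
    out["associated"] = assoc
    observed = float(assoc.mean()) if len(trds) else float("nan")

    if method == "hypergeometric":
        in_vicinity = np.zeros(len(enhancers), dtype=bool)
        concordant_any = np.zeros(len(enhancers), dtype=bool)
        for chrom, start, end, cat in zip(
            trds["chrom"], trds["start"], trds["end"], trds["category"]
        ):
            m = enh_chrom == chrom
            near = m & (enh_summit >= start - vicinity) & (enh_summit <= end + vicinity)
            in_vicinity |= near
            concordant_any |= _concordant(cat, enh_reg)
        N = len(enhancers)
        K = int(concordant_any.sum())
        n = int(in_vicinity.sum())
        k = int((in_vicinity & concordant_any).sum())
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        return out, p

    rng = np.random.default_rng(seed)
    fractions = np.empty(iterations, dtype=float)
    order = np.lexsort((enh_summit, enh_chrom))
    chrom_sorted = enh_chrom[order]
    summit_sorted = enh_summit[order]
    reg_sorted = enh_reg[order]
    starts = np.flatnonzero(np.r_[True, chrom_sorted[1:] != chrom_sorted[:-1]])
    bounds = np.r_[starts, len(chrom_sorted)]
    for it in range(iterations):
        shifted = reg_sorted.copy()
        for a, b in zip(bounds[:-1], bounds[1:]):
            L = b - a
            if L > 1:
                k = int(rng.integers(1, L))
                shifted[a:b] = np.roll(reg_sorted[a:b], k)
        fractions[it] = _associated_mask(
            trds, chrom_sorted, summit_sorted, shifted, vicinity
        ).mean()
    null = NullDistribution(
        statistic="fraction_trds_with_enhancer", observed=observed,
        iterations=iterations, values=fractions, seed=seed, tail="upper",
    )
    return out, null


def trd_descriptives(
    trds: pd.DataFrame,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    regulation_col: str = "regulation",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-domain summaries (size, gene count, local expressed-gene density)
    and per-member-gene distances to the closest co- and anti-regulated
    enhancer summit."""
    expressed = genes[genes["expressed"].astype(bool)]
    enh_reg = enhancers[regulation_col].to_numpy()

    per_trd = []
    per_gene = []
    for _, trd in trds.iterrows():
        span = max(trd["end"] - trd["start"], 1)
        n_local = int(
            (
                (expressed["chrom"] == trd["chrom"])
                & (expressed["tss"] >= trd["start"])
                & (expressed["tss"] < trd["end"])
            ).sum()
        )
        per_trd.append(
            {
                "domain_id": trd["domain_id"],
                "size_kb": trd["size_kb"],
                "n_genes": trd["n_genes"],
                "gene_density_per_mb": n_local / (span / 1e6),
            }
        )
        co_mask = _concordant(trd["category"], enh_reg) & (
            enhancers["chrom"].to_numpy() == trd["chrom"]
        )
        anti_cat = (
            trd["category"].replace("-up", "-down")
            if trd["category"].endswith("-up")
            else trd["category"].replace("-down", "-up")
        )
        anti_mask = _concordant(anti_cat, enh_reg) & (
            enhancers["chrom"].to_numpy() == trd["chrom"]
        )
        co = enhancers.loc[co_mask, "summit"].to_numpy()
        anti = enhancers.loc[anti_mask, "summit"].to_numpy()
        members = expressed[expressed["gene_id"].isin(trd["gene_ids"])]
        for gid, tss in zip(members["gene_id"], members["tss"]):
            per_gene.append(
                {
                    "domain_id": trd["domain_id"],
                    "gene_id": gid,
                    "dist_coregulated": float(np.min(np.abs(co - tss))) if len(co) else np.nan,
                    "dist_antiregulated": float(np.min(np.abs(anti - tss))) if len(anti) else np.nan,
                }
            )
    return pd.DataFrame(per_trd), pd.DataFrame(per_gene)


def assign_genes_to_tads(tads: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """TAD id per expressed gene by TSS (tiling domains, half-open)."""
    expressed = genes[genes["expressed"].astype(bool)]
    out = pd.Series(pd.NA, index=expressed.index, dtype=object)
    for chrom, grp in tads.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["domain_id"].to_numpy()
        m = expressed["chrom"] == chrom
        tss = expressed.loc[m, "tss"].to_numpy()
        j = np.searchsorted(starts, tss, side="right") - 1
        inside = (j >= 0) & (tss < ends[np.clip(j, 0, len(ends) - 1)])
        idx = expressed.index[m]
        out.loc[idx[inside]] = ids[j[inside]]
    return out


def tad_coregulation(
    tads: pd.DataFrame,
    genes: pd.DataFrame,
    fc_col: str = "log2fc_2h",
    min_expressed: int = 3,
    n_bins: int = 10,
    iterations: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Distribution of per-TAD upregulated-gene fractions against a
    permutation null.

    TADs with fewer than `min_expressed` expressed genes are removed.  Each
    TAD is scored by its fraction of genes with log2FC > 0 and TADs are
    histogrammed into `n_bins` fraction bins.  The null permutes the
    gene-to-TAD assignment genome-wide, conserving per-TAD gene counts
    (`iterations` permutations).  Per bin: observed count, null mean, their
    ratio, and normal-tail p for each tail.
    """
    expressed = genes[genes["expressed"].astype(bool)].copy()
    tad_of = assign_genes_to_tads(tads, genes)
    expressed["tad"] = tad_of
    expressed = expressed[expressed["tad"].notna()]
    counts = expressed.groupby("tad").size()
    keep = counts[counts >= min_expressed].index
    expressed = expressed[expressed["tad"].isin(keep)]
    if expressed.empty:
        raise ValueError(
            f"no TAD has at least {min_expressed} expressed genes"
        )

    expressed = expressed.sort_values("tad", kind="stable")
    up = (expressed[fc_col].to_numpy(float) > 0).astype(float)
    tad_codes = pd.factorize(expressed["tad"].to_numpy())[0]
    starts = np.flatnonzero(np.r_[True, tad_codes[1:] != tad_codes[:-1]])
    sizes = np.diff(np.r_[starts, len(tad_codes)])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    frac = np.add.reduceat(up, starts) / sizes
    observed, _ = np.histogram(frac, bins=edges)

    rng = np.random.default_rng(seed)
    null_counts = np.empty((iterations, n_bins), dtype=float)
    for it in range(iterations):
        perm = up[rng.permutation(len(up))]
        f = np.add.reduceat(perm, starts) / sizes
        null_counts[it], _ = np.histogram(f, bins=edges)

    mean_null = null_counts.mean(axis=0)
    sd_null = null_counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_null > 0, observed / mean_null, np.nan)
        z = np.where(sd_null > 0, (observed - mean_null) / sd_null, 0.0)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "observed": observed,
            "expected": mean_null,
            "ratio": ratio,
            "p_upper": sps.norm.sf(z),
            "p_lower": sps.norm.cdf(z),
        }
    )


def border_pair_analysis(
    genes: pd.DataFrame,
    borders: pd.DataFrame,
    pairing: str = "gene_gene",
    enhancers: pd.DataFrame | None = None,
    n_bins: int = 20,
    fc_col: str = "log2fc_2h",
    enhancer_fc_col: str = "k27ac_log2fc_2h",
) -> dict:
    """Binned FC correlation for pairs split by whether a TAD border lies
    strictly between the two anchor points.

    pairing='gene_gene': strictly contiguous expressed-gene pairs
    (log2FC(x), log2FC(y)).  pairing='enhancer_closest_gene': each
    enhancer's H3K27ac log2FC paired with its closest expressed gene's
    log2FC.  Borders need columns chrom and pos.
    """
    border_by_chrom = {
        c: np.sort(g["pos"].to_numpy()) for c, g in borders.groupby("chrom")
    }

    def crosses(chrom, a, b) -> bool:
        arr = border_by_chrom.get(chrom)
        if arr is None:
            return False
        lo, hi = (a, b) if a <= b else (b, a)
        i = np.searchsorted(arr, lo, side="right")
        j = np.searchsorted(arr, hi, side="left")
        return j > i

    xs, ys, cross = [], [], []
    if pairing == "gene_gene":
        ordered = order_genes(genes)
        for _, grp in ordered.groupby("chrom", sort=False):
            grp = grp.sort_values("ordinal")
            tss = grp["tss"].to_numpy()
            fc = grp[fc_col].to_numpy(float)
            chrom = grp["chrom"].iloc[0]
            for i in range(len(grp) - 1):
                xs.append(fc[i])
                ys.append(fc[i + 1])
                cross.append(crosses(chrom, tss[i], tss[i + 1]))
    elif pairing == "enhancer_closest_gene":
        if enhancers is None:
            raise ValueError("enhancer_closest_gene pairing needs enhancers")
        ordered = order_genes(genes)
        by_chrom = {c: g for c, g in ordered.groupby("chrom", sort=False)}
        for _, enh in enhancers.iterrows():
            grp = by_chrom.get(enh["chrom"])
            if grp is None or grp.empty:
                continue
            tss = grp["tss"].to_numpy()
            j = int(np.argmin(np.abs(tss - enh["summit"])))
            xs.append(float(enh[enhancer_fc_col]))
            ys.append(float(grp[fc_col].to_numpy()[j]))
            cross.append(crosses(enh["chrom"], enh["summit"], tss[j]))
    else:
        raise ValueError(f"unknown pairing: {pairing!r}")

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    cross = np.asarray(cross, dtype=bool)
    result: dict = {"n_within": int((~cross).sum()), "n_cross": int(cross.sum())}
    for name, mask in (("within", ~cross), ("cross", cross)):
        if mask.sum() >= n_bins:
            rho, slope, bins = binned_fc_correlation(xs[mask], ys[mask], n_bins)
            # raw (pairwise) Spearman alongside the binned one: with few bins
            # the binned rank correlation has large sampling variance even
            # under perfect decoupling, while the pairwise one concentrates
            rho_raw = float(sps.spearmanr(xs[mask], ys[mask]).statistic)
            result[name] = {
                "rho": rho, "slope": slope, "bins": bins, "rho_raw": rho_raw,
            }
        else:
            warnings.warn(f"too few {name}-border pairs for binned correlation")
            result[name] = None
    return result


def shift_domain_null(
    domains: pd.DataFrame,
    chrom_lengths: dict,
    shift: int = 10_000_000,
) -> pd.DataFrame:
    """Randomize a tiling domain set by recircularizing each chromosome and
    shifting every border by `shift` bp; the wrapped domain is split at the
    chromosome ends, all other domain sizes are preserved."""
    if shift <= 0:
        raise ValueError("shift must be positive")
    rows = []
    for chrom, grp in domains.groupby("chrom"):
        L = chrom_lengths[chrom]
        grp = grp.sort_values("start")
        starts = np.sort(np.unique(grp["start"].to_numpy() + shift) % L)
        if len(starts) == 1:
            rows.append({"chrom": chrom, "start": 0, "end": L})
            continue
        for a, b in zip(starts[:-1], starts[1:]):
            rows.append({"chrom": chrom, "start": int(a), "end": int(b)})
        # wrap-around piece, split at the chromosome end
        if starts[-1] < L:
            rows.append({"chrom": chrom, "start": int(starts[-1]), "end": int(L)})
        if starts[0] > 0:
            rows.append({"chrom": chrom, "start": 0, "end": int(starts[0])})
    out = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    out["domain_id"] = [f"rand_{i+1}" for i in range(len(out))]
    return out
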