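"""Contact-matrix analytics: directionality index, proportional and
boundary metaplots, enhancer-promoter interaction grouping, and the
mirrored-coordinate domain randomization.

The directionality index of a bin contrasts its total contacts to the 25
upstream 10-kb bins (A) with those to the 25 downstream bins (B) against
their mean E = (A+B)/2:

    DI = sign(B - A) * ((A-E)^2/E + (B-E)^2/E),   DI = 0 when A = B.

Negative DI marks bins interacting preferentially upstream; at a domain
border the mean DI changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    matrix: np.ndarray = field(repr=False)
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def directionality_index(cm: ContactMatrix, window: int = 250_000) -> pd.DataFrame:
    """Per-bin directionality index over a +-`window` contact window.

    Bins whose window is truncated by a chromosome end use the truncated
    sums and carry truncated=True.
    """
    if cm.n_bins == 0:
        raise ValueError("empty contact matrix")
    if window % cm.bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    w = window // cm.bin_size
    n = cm.n_bins
    M = cm.matrix
    A = np.empty(n)
    B = np.empty(n)
    for i in range(n):
        A[i] = M[i, max(0, i - w) : i].sum()
        B[i] = M[i, i + 1 : min(n, i + 1 + w)].sum()
    E = (A + B) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (A - E) ** 2 / E + (B - E) ** 2 / E
    di = np.where(A == B, 0.0, np.sign(B - A) * stat)
    truncated = (np.arange(n) < w) | (np.arange(n) + w >= n)
    return pd.DataFrame(
        {"bin": np.arange(n), "A": A, "B": B, "E": E, "di": di,
         "truncated": truncated}
    )


def _cumulative_step(values: np.ndarray, bin_size: int):
    """Integral of the per-bin step function: F(x) for x in bp."""
    cum = np.concatenate([[0.0], np.cumsum(values) * bin_size])

    def F(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0, len(values) * bin_size)
        k = np.minimum((x // bin_size).astype(int), len(values) - 1)
        return cum[k] + values[k] * (x - k * bin_size)

    return F


def proportional_metaplot(
    domains: pd.DataFrame,
    values: dict[str, np.ndarray],
    n_bins: int = 100,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Rescale every domain to `n_bins` equal-length slots and average the
    per-genomic-bin values into them (length-weighted), then average across
    domains.

    `values` maps chromosome -> per-bin array at `bin_size` resolution.
    Domains shorter than `n_bins` genomic bins are still averaged with
    weights and flagged in the 'n_short' attribute column of the result.
    """
    if domains.empty:
        raise ValueError("no domains supplied")
    profiles = np.full((len(domains), n_bins), np.nan)
    n_short = 0
    for row_i, (_, d) in enumerate(domains.iterrows()):
        vals = np.asarray(values[d["chrom"]], dtype=float)
        F = _cumulative_step(vals, bin_size)
        edges = d["start"] + (d["end"] - d["start"]) * np.arange(n_bins + 1) / n_bins
        mass = F(edges[1:]) - F(edges[:-1])
        widths = np.diff(edges)
        profiles[row_i] = mass / widths
        if (d["end"] - d["start"]) < n_bins * bin_size:
            n_short += 1
    out = pd.DataFrame(
        {"slot": np.arange(n_bins), "mean": np.nanmean(profiles, axis=0)}
    )
    out.attrs["n_short"] = n_short
    out.attrs["per_domain"] = profiles
    return out


def boundary_metaplot(
    borders: pd.DataFrame,
    values: dict[str, np.ndarray],
    flank_bins: tuple[int, int] = (50, 50),
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Across-border mean of per-bin values in fixed-width genomic bins
    around each border (columns chrom, pos).  Borders too close to a
    chromosome end contribute truncated (NaN-padded) rows."""
    up, down = flank_bins
    n_off = up + down
    rows = np.full((len(borders), n_off), np.nan)
    truncated = 0
    for i, (chrom, pos) in enumerate(zip(borders["chrom"], borders["pos"])):
        vals = np.asarray(values[chrom], dtype=float)
        c = int(pos // bin_size)
        for k, off in enumerate(range(-up, down)):
            j = c + off
            if 0 <= j < len(vals):
                rows[i, k] = vals[j]
        if c - up < 0 or c + down > len(vals):
            truncated += 1
    offsets = np.arange(-up, down)
    out = pd.DataFrame(
        {
            "offset": offsets,
            "mean": np.nanmean(rows, axis=0),
            "n": np.sum(~np.isnan(rows), axis=0),
        }
    )
    out.attrs["n_truncated"] = truncated
    return out


def ep_interaction_groups(
    cm: ContactMatrix,
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    trds: pd.DataFrame,
    windows=((0, 100_000), (100_000, 250_000), (250_000, 500_000)),
) -> dict:
    """Contact values between in-TRD enhancers and candidate promoters,
    grouped by promoter location relative to the TRD.

    Groups: 'within-TRD' plus one per distance window from the nearest TRD
    boundary.  Features falling outside the matrix are skipped and counted.
    """
    n = cm.n_bins
    trd_sub = trds[trds["chrom"] == cm.chrom]
    gene_sub = genes[(genes["chrom"] == cm.chrom) & genes["expressed"].astype(bool)]
    enh_sub = enhancers[enhancers["chrom"] == cm.chrom]

    labels = ["within-TRD"] + [f"{a//1000}-{b//1000}kb" for a, b in windows]
    groups: dict = {lab: [] for lab in labels}
    skipped = 0
    for _, trd in trd_sub.iterrows():
        in_trd = enh_sub[
            (enh_sub["summit"] >= trd["start"]) & (enh_sub["summit"] < trd["end"])
        ]
        for summit in in_trd["summit"]:
            e_bin = int(summit // cm.bin_size)
            if not 0 <= e_bin < n:
                skipped += 1
                continue
            for tss in gene_sub["tss"]:
                p_bin = int(tss // cm.bin_size)
                if not 0 <= p_bin < n:
                    skipped += 1
                    continue
                if trd["start"] <= tss < trd["end"]:
                    groups["within-TRD"].append(cm.matrix[e_bin, p_bin])
                    continue
                d = trd["start"] - tss if tss < trd["start"] else tss - trd["end"]
                for (a, b), lab in zip(windows, labels[1:]):
                    if a <= d < b:
                        groups[lab].append(cm.matrix[e_bin, p_bin])
                        break
    return {
        "groups": {k: np.asarray(v) for k, v in groups.items()},
        "sizes": {k: len(v) for k, v in groups.items()},
        "skipped": skipped,
    }


def random_trd_coordinates(
    trds: pd.DataFrame, chrom_lengths: dict
) -> pd.DataFrame:
    """Mirror every domain's start coordinate within its chromosome,
    keeping the length; clipped intervals are flagged.  Applying the
    transform twice restores the original (unclipped) starts."""
    out = trds.copy()
    starts, ends, clipped = [], [], []
    for chrom, s, e in zip(trds["chrom"], trds["start"], trds["end"]):
        L = chrom_lengths[chrom]
        length = e - s
        ns = L - s
        ne = ns + length
        clip = ne > L or ns < 0
        ns = max(0, min(ns, L))
        ne = max(0, min(ne, L))
        starts.append(int(ns))
        ends.append(int(ne))
        clipped.append(bool(clip))
    out["start"] = starts
    out["end"] = ends
    out["clipped"] = clipped
    return out
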