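"""Synthetic genomes with planted co-regulation structure.

The generator emulates the tabular derivatives consumed by the analysis
stages: an ordered gene annotation with expression and differential-
expression columns, accessibility peaks with per-condition histone-mark
signals, a TAD tiling, distance-decay contact matrices with within-TAD
enrichment, footprint/motif call tables and stranded fragment records.
Structure is planted with known labels (contiguous co-regulated gene runs,
linked concordant enhancers, per-category motif odds) so that every
downstream statistic can be checked against ground truth.

All coordinates are 0-based half-open.  A fixed seed makes every generator
byte-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .neighborhood import order_genes
from .peaks import assign_accessibility_category


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class PlantedDomain:
    """A contiguous run of co-regulated genes to plant.

    Effects are log2 fold changes drawn from Normal(effect_mean * sign,
    effect_sd) at the category's defining timepoint.
    """

    category: str
    n_genes: int
    effect_mean: float = 1.5
    effect_sd: float = 0.3


def default_planted_domains(n_domains: int = 12) -> list[PlantedDomain]:
    """Domains cycling the four response categories with sizes averaging
    ~2.2 genes (range 2-7), echoing observed regulatory-domain geometry."""
    cats = ("early-up", "late-up", "early-down", "late-down")
    sizes = (2, 2, 3, 2, 2, 2, 3, 2, 2, 4, 2, 2)
    return [
        PlantedDomain(cats[i % 4], sizes[i % len(sizes)]) for i in range(n_domains)
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 250
    intergene_spacing_median: int = 50_000  # bp between consecutive TSSs
    intergene_spacing_sigma: float = 0.6    # lognormal dispersion
    gene_length_median: int = 15_000
    gene_length_sigma: float = 0.8
    frac_expressed: float = 0.52
    planted_domains: list[PlantedDomain] = field(default_factory=default_planted_domains)
    background_fc_sd: float = 0.25
    secondary_fc_sd: float = 0.1  # jitter of the non-defining timepoint
    n_enhancers: int = 1000
    frac_enhancers_opening: float = 0.75
    domain_enhancer_linkage: float = 0.8
    tad_mean_size: int = 1_000_000
    contact_decay_exponent: float = 1.0
    within_tad_multiplier: float = 3.0
    contact_base: float = 100.0
    motif_baseline_prob: float = 0.02
    motif_enrichment_spec: dict = field(default_factory=dict)  # motif -> {category: odds}
    footprints_per_region: int = 3
    fragments_per_peak: float = 20.0
    frac_sub100: float = 0.6

    def validate(self) -> None:
        for name in ("n_chromosomes", "genes_per_chromosome", "n_enhancers"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("intergene_spacing_median", "gene_length_median", "tad_mean_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "frac_expressed", "frac_enhancers_opening",
            "domain_enhancer_linkage", "frac_sub100",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.contact_decay_exponent <= 0:
            raise ConfigurationError("contact_decay_exponent must be positive")
        for d in self.planted_domains:
            if d.n_genes < 2:
                raise ConfigurationError("planted_domains: n_genes must be >= 2")
        for motif, by_cat in self.motif_enrichment_spec.items():
            for cat, odds in by_cat.items():
                if odds <= 0:
                    raise ConfigurationError(
                        f"motif_enrichment_spec[{motif!r}][{cat!r}]: odds must be > 0"
                    )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthLabels:
    """Ground truth of planted structure."""

    gene_category: pd.Series                 # gene_id -> category or 'none'
    domains: pd.DataFrame                    # planted domain extents
    enhancer_regulation: pd.Series | None = None  # peak_id -> category
    motif_odds: dict | None = None


def chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def chrom_lengths_from_genes(genes: pd.DataFrame, margin: int = 100_000) -> dict:
    return {
        c: int(g["end"].max()) + margin for c, g in genes.groupby("chrom")
    }


def generate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Ordered, non-overlapping gene annotation with expression flags.

    Consecutive TSS spacings are lognormal with the configured median and
    dispersion; gene bodies are capped at half the distance to either
    neighboring TSS so that genes never overlap.  Strand is random and does
    not influence any genome-order statistic.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for chrom in chrom_names(config):
        n = config.genes_per_chromosome
        gaps = np.exp(
            rng.normal(np.log(config.intergene_spacing_median),
                       config.intergene_spacing_sigma, size=n)
        ).astype(np.int64)
        gaps = np.maximum(gaps, 2000)
        tss = np.cumsum(gaps) + 10_000
        lengths = np.exp(
            rng.normal(np.log(config.gene_length_median),
                       config.gene_length_sigma, size=n)
        ).astype(np.int64)
        lengths = np.maximum(lengths, 500)
        gap_next = np.diff(tss, append=tss[-1] + config.intergene_spacing_median)
        gap_prev = np.diff(tss, prepend=tss[0] - config.intergene_spacing_median)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        expressed = rng.random(n) < config.frac_expressed
        for j in range(n):
            if strand[j] == "+":
                ln = int(min(lengths[j], max(gap_next[j] // 2, 400)))
                start, end = int(tss[j]), int(tss[j]) + ln
            else:
                ln = int(min(lengths[j], max(gap_prev[j] // 2, 400)))
                start, end = int(tss[j]) - ln + 1, int(tss[j]) + 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand[j],
                    "gene_id": f"{chrom}_g{j + 1}",
                    "tss": int(tss[j]),
                    "expressed": bool(expressed[j]),
                }
            )
    genes = pd.DataFrame(rows)
    genes.attrs["chrom_lengths"] = chrom_lengths_from_genes(genes)
    return genes


def _place_domains(
    ordered: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    """Choose non-overlapping expressed-gene runs for the planted domains,
    keeping >= 1 background expressed gene between domains."""
    placements = []
    occupied: dict[str, np.ndarray] = {}
    chroms = list(ordered["chrom"].unique())
    per_chrom = {c: ordered[ordered["chrom"] == c] for c in chroms}
    for c in chroms:
        occupied[c] = np.zeros(len(per_chrom[c]), dtype=bool)
    need = sum(d.n_genes + 1 for d in config.planted_domains)
    avail = len(ordered)
    if need > avail:
        raise ConfigurationError(
            f"planted domains need ~{need} expressed genes, only {avail} available"
        )
    for dom in config.planted_domains:
        placed = False
        for _ in range(2000):
            c = chroms[int(rng.integers(len(chroms)))]
            n_c = len(per_chrom[c])
            if n_c < dom.n_genes + 2:
                continue
            i = int(rng.integers(1, n_c - dom.n_genes))
            lo, hi = i - 1, i + dom.n_genes + 1  # one-gene buffer both sides
            if occupied[c][max(lo, 0) : min(hi, n_c)].any():
                continue
            occupied[c][i : i + dom.n_genes] = True
            grp = per_chrom[c].iloc[i : i + dom.n_genes]
            placements.append(
                {
                    "chrom": c,
                    "category": dom.category,
                    "effect_mean": dom.effect_mean,
                    "effect_sd": dom.effect_sd,
                    "gene_ids": list(grp["gene_id"]),
                    "first_ordinal": int(grp["ordinal"].iloc[0]),
                    "last_ordinal": int(grp["ordinal"].iloc[-1]),
                }
            )
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                "could not place planted domains without overlap; "
                "reduce planted_domains or increase genes_per_chromosome"
            )
    return placements


def plant_regulation(
    genes: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Add differential-expression columns with planted contiguous
    co-regulated runs over a null background.

    Background genes draw both timepoints from Normal(0, background_fc_sd)
    with p ~ U(0, 1) (and p_adj = p; adjusted p is treated as an input
    column throughout).  Planted genes draw the defining timepoint from
    Normal(effect_mean * sign, effect_sd) with p = p_adj ~ U(0, 0.01);
    log2fc_12v2 = log2fc_12h - log2fc_2h by construction.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = genes.copy()
    n = len(out)
    fc2 = rng.normal(0.0, config.background_fc_sd, size=n)
    fc12 = rng.normal(0.0, config.background_fc_sd, size=n)
    p = rng.uniform(0.0, 1.0, size=n)
    p_adj = p.copy()
    category = np.full(n, "none", dtype=object)

    ordered = order_genes(out)
    placements = _place_domains(ordered, config, rng) if config.planted_domains else []
    idx_of = {g: i for i, g in enumerate(out["gene_id"])}
    for dom in placements:
        sign = 1.0 if dom["category"].endswith("-up") else -1.0
        for gid in dom["gene_ids"]:
            i = idx_of[gid]
            effect = rng.normal(sign * dom["effect_mean"], dom["effect_sd"])
            if dom["category"].startswith("early"):
                fc2[i] = effect
                fc12[i] = effect + rng.normal(0.0, config.secondary_fc_sd)
            elif dom["category"].startswith("late"):
                fc12[i] = effect
            else:  # transient: defined at 2h, rebound to baseline by 12h
                fc2[i] = effect
                fc12[i] = rng.normal(0.0, config.secondary_fc_sd)
            p[i] = rng.uniform(0.0, 0.01)
            p_adj[i] = p[i]
            category[i] = dom["category"]

    out["log2fc_2h"] = fc2
    out["log2fc_12h"] = fc12
    out["log2fc_12v2"] = fc12 - fc2
    out["p"] = p
    out["p_adj"] = p_adj
    out.attrs["chrom_lengths"] = genes.attrs.get(
        "chrom_lengths", chrom_lengths_from_genes(genes)
    )
    labels = TruthLabels(
        gene_category=pd.Series(category, index=out["gene_id"], name="category"),
        domains=pd.DataFrame(
            placements,
            columns=["chrom", "category", "effect_mean", "effect_sd",
                     "gene_ids", "first_ordinal", "last_ordinal"],
        ),
    )
    if not labels.domains.empty:
        labels.domains.insert(
            0, "domain_id", [f"planted_{i + 1}" for i in range(len(labels.domains))]
        )
    return out, labels


def _lognormal(rng, median, sigma, size):
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def generate_enhancers(
    genes: pd.DataFrame, labels: TruthLabels, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Accessibility peaks with summits, per-condition mark signals, H3K27ac
    differential-binding columns, and planted regulation.

    `frac_enhancers_opening` of peaks get linear accessibility FC >= 1.5;
    for `domain_enhancer_linkage` of planted domains one concordantly
    regulated enhancer is placed inside the domain span.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lengths = genes.attrs.get("chrom_lengths", chrom_lengths_from_genes(genes))
    if not lengths:
        raise ConfigurationError("no chromosomes available for enhancer placement")
    chroms = sorted(lengths)
    total = sum(lengths.values())

    n = config.n_enhancers
    rows = []
    for chrom in chroms:
        n_c = max(1, round(n * lengths[chrom] / total))
        width = np.clip(
            _lognormal(rng, 400, 0.4, n_c).astype(np.int64), 150, 3000
        )
        start = rng.integers(1000, lengths[chrom] - 4000, size=n_c)
        summit = start + (width * rng.uniform(0.2, 0.8, n_c)).astype(np.int64)
        for s, w, sm in zip(start, width, summit):
            rows.append({"chrom": chrom, "start": int(s), "end": int(s + w),
                         "summit": int(sm), "planted_regulation": "independent"})

    # linked enhancers inside planted domains
    if not labels.domains.empty:
        gene_span = genes.set_index("gene_id")
        n_dom = len(labels.domains)
        linked = rng.random(n_dom) < config.domain_enhancer_linkage
        for (_, dom), is_linked in zip(labels.domains.iterrows(), linked):
            if not is_linked:
                continue
            members = gene_span.loc[dom["gene_ids"]]
            lo = int(members["start"].min())
            hi = int(members["end"].max())
            sm = int(rng.integers(lo, max(hi, lo + 1)))
            reg = dom["category"].replace("-up", "-activated").replace(
                "-down", "-repressed"
            )
            rows.append({"chrom": dom["chrom"], "start": sm - 200,
                         "end": sm + 200, "summit": sm,
                         "planted_regulation": reg})

    peaks = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    peaks = peaks.reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"p{i + 1}" for i in range(len(peaks))])
    m = len(peaks)

    # accessibility
    peaks["signal"] = _lognormal(rng, 50, 0.8, m)
    log2_15 = np.log2(1.5)
    opening = rng.random(m) < config.frac_enhancers_opening
    fc = np.empty(m)
    fc[opening] = log2_15 + rng.exponential(0.7, size=int(opening.sum()))
    closed = np.flatnonzero(~opening)
    draws = rng.normal(0.0, 0.35, size=len(closed))
    bad = draws >= log2_15
    while bad.any():
        draws[bad] = rng.normal(0.0, 0.35, size=int(bad.sum()))
        bad = draws >= log2_15
    fc[closed] = draws
    peaks["atac_log2fc_2h"] = fc
    # same opening set at 12 h, fresh magnitudes, so the configured opening
    # fraction holds per condition
    fc12 = np.empty(m)
    fc12[opening] = log2_15 + rng.exponential(0.7, size=int(opening.sum()))
    draws12 = rng.normal(0.0, 0.35, size=len(closed))
    bad = draws12 >= log2_15
    while bad.any():
        draws12[bad] = rng.normal(0.0, 0.35, size=int(bad.sum()))
        bad = draws12 >= log2_15
    fc12[closed] = draws12
    peaks["atac_log2fc_12h"] = fc12

    # chromatin-state mark signals (vehicle mixture; latent acquire on treatment)
    state = rng.choice(
        ["active", "primed", "latent", "undefined"], size=m,
        p=[0.72, 0.15, 0.05, 0.08],
    )
    planted = peaks["planted_regulation"].to_numpy()
    state[planted != "independent"] = "active"

    def hi_lo(mask_hi):
        v = _lognormal(rng, 0.5, 0.5, m)
        v[mask_hi] = _lognormal(rng, 20, 0.5, int(mask_hi.sum()))
        return v

    k27_hi_veh = state == "active"
    k4_hi_veh = (state == "active") | (state == "primed")
    peaks["h3k27ac_veh"] = hi_lo(k27_hi_veh)
    peaks["h3k4me1_veh"] = hi_lo(k4_hi_veh)
    peaks["h3k4me3_veh"] = _lognormal(rng, 1.0, 0.5, m)
    acquired = k27_hi_veh | (state == "latent")
    peaks["h3k27ac_2h"] = hi_lo(acquired)
    peaks["h3k4me1_2h"] = hi_lo(k4_hi_veh | (state == "latent"))
    peaks["h3k4me3_2h"] = _lognormal(rng, 1.0, 0.5, m)
    peaks["h3k27ac_12h"] = hi_lo(acquired)
    peaks["h3k4me1_12h"] = hi_lo(k4_hi_veh | (state == "latent"))
    peaks["h3k4me3_12h"] = _lognormal(rng, 1.0, 0.5, m)

    # H3K27ac differential binding (the enhancer-regulation substrate)
    k27_fc2 = rng.normal(0.0, 0.3, size=m)
    k27_fc12 = rng.normal(0.0, 0.3, size=m)
    k27_p2 = rng.uniform(0.0, 1.0, size=m)
    k27_p12 = rng.uniform(0.0, 1.0, size=m)
    logcpm2 = rng.normal(2.0, 1.0, size=m)
    logcpm12 = rng.normal(2.0, 1.0, size=m)
    for i, reg in enumerate(planted):
        if reg == "independent":
            continue
        sign = 1.0 if reg.endswith("activated") else -1.0
        effect = rng.normal(sign * 1.5, 0.3)
        if reg.startswith("early"):
            k27_fc2[i] = effect
            k27_fc12[i] = effect + rng.normal(0.0, config.secondary_fc_sd)
            k27_p2[i] = rng.uniform(0.0, 0.01)
        else:
            k27_fc12[i] = effect
            k27_p12[i] = rng.uniform(0.0, 0.01)
        logcpm2[i] = abs(logcpm2[i]) + 0.5
        logcpm12[i] = abs(logcpm12[i]) + 0.5
    peaks["k27ac_log2fc_2h"] = k27_fc2
    peaks["k27ac_log2fc_12h"] = k27_fc12
    peaks["k27ac_log2fc_12v2"] = k27_fc12 - k27_fc2
    peaks["k27ac_p_2h"] = k27_p2
    peaks["k27ac_p_12h"] = k27_p12
    peaks["k27ac_logcpm_2h"] = logcpm2
    peaks["k27ac_logcpm_12h"] = logcpm12

    enh_truth = pd.Series(
        peaks["planted_regulation"].to_numpy(),
        index=peaks["peak_id"], name="regulation",
    )
    peaks = peaks.drop(columns="planted_regulation")
    labels = TruthLabels(
        gene_category=labels.gene_category,
        domains=labels.domains,
        enhancer_regulation=enh_truth,
        motif_odds=labels.motif_odds,
    )
    return peaks, labels


def generate_tads(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """TADs tiling each chromosome without gaps or overlaps, sizes centered
    on `tad_mean_size`."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lengths = genes.attrs.get("chrom_lengths", chrom_lengths_from_genes(genes))
    if config.tad_mean_size > min(lengths.values()):
        raise ConfigurationError("tad_mean_size exceeds chromosome length")
    rows = []
    k = 0
    for chrom in sorted(lengths):
        L = lengths[chrom]
        pos = 0
        while pos < L:
            size = int(
                np.clip(rng.normal(config.tad_mean_size, 0.2 * config.tad_mean_size),
                        0.3 * config.tad_mean_size, 2.0 * config.tad_mean_size)
            )
            end = min(pos + size, L)
            k += 1
            rows.append({"domain_id": f"tad_{k}", "chrom": chrom,
                         "start": pos, "end": end})
            pos = end
    return pd.DataFrame(rows)


def generate_contact_matrix(
    tads: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    bin_size: int,
    config: SimulationConfig,
) -> ContactMatrix:
    """Symmetric Poisson contact matrix with power-law distance decay and a
    within-TAD contact multiplier."""
    config.validate()
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n = chrom_length // bin_size
    i = np.arange(n)
    dist = np.abs(i[:, None] - i[None, :])
    expected = config.contact_base * (dist + 1.0) ** (-config.contact_decay_exponent)

    sub = tads[tads["chrom"] == chrom].sort_values("start")
    tad_of_bin = np.full(n, -1)
    for t, (s, e) in enumerate(zip(sub["start"], sub["end"])):
        b0 = int(np.ceil(s / bin_size))
        b1 = int(e // bin_size)
        tad_of_bin[b0:b1] = t
    same_tad = (tad_of_bin[:, None] == tad_of_bin[None, :]) & (tad_of_bin[:, None] >= 0)
    expected = np.where(same_tad, expected * config.within_tad_multiplier, expected)

    upper = np.triu(rng.poisson(expected).astype(float))
    mat = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=mat,
                         normalization="raw")


def _motif_hits(rng, motifs, probs, n):
    """Comma-joined motif labels per footprint ('.' when none)."""
    out = []
    draws = {mot: rng.random(n) < p for mot, p in zip(motifs, probs)}
    for j in range(n):
        hits = [mot for mot in motifs if draws[mot][j]]
        out.append(",".join(hits) if hits else ".")
    return out


def generate_footprints(
    peaks: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Footprint call tables: per real peak, `footprints_per_region`
    records with motif labels at per-category enriched probability; a
    background table over 5x as many regions at baseline probability."""
    config.validate()
    if not config.motif_enrichment_spec:
        raise ConfigurationError("motif_enrichment_spec must define at least one motif")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    motifs = sorted(config.motif_enrichment_spec)
    p0 = config.motif_baseline_prob
    cats = assign_accessibility_category(peaks["atac_log2fc_2h"]).to_numpy()

    real_rows = []
    for (pid, chrom, start, end), cat in zip(
        peaks[["peak_id", "chrom", "start", "end"]].itertuples(index=False), cats
    ):
        k = config.footprints_per_region
        probs = [
            min(config.motif_enrichment_spec[mot].get(cat, 1.0) * p0, 0.95)
            for mot in motifs
        ]
        pos = rng.integers(start, max(end - 20, start + 1), size=k)
        hits = _motif_hits(rng, motifs, probs, k)
        for x, h in zip(pos, hits):
            real_rows.append({"chrom": chrom, "start": int(x), "end": int(x) + 20,
                              "peak_id": pid, "motif": h, "set": "real"})
    real = pd.DataFrame(real_rows)

    bg_rows = []
    probs0 = [min(p0, 0.95)] * len(motifs)
    for (pid, chrom, start, end) in peaks[
        ["peak_id", "chrom", "start", "end"]
    ].itertuples(index=False):
        for rep in range(5):
            k = config.footprints_per_region
            pos = rng.integers(start, max(end - 20, start + 1), size=k)
            hits = _motif_hits(rng, motifs, probs0, k)
            for x, h in zip(pos, hits):
                bg_rows.append(
                    {"chrom": chrom, "start": int(x), "end": int(x) + 20,
                     "peak_id": f"{pid}_bg{rep + 1}", "motif": h, "set": "background"}
                )
    background = pd.DataFrame(bg_rows)
    return real, background


def generate_fragments(
    peaks: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Stranded fragment records around peak summits with a bimodal length
    mixture (`frac_sub100` sub-100 bp, the rest mono-nucleosome sized)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    rows = []
    for chrom, summit in zip(peaks["chrom"], peaks["summit"]):
        k = rng.poisson(config.fragments_per_peak)
        if k == 0:
            continue
        centers = rng.normal(summit, 100, size=k).astype(np.int64)
        sub = rng.random(k) < config.frac_sub100
        lens = np.where(
            sub,
            rng.integers(30, 100, size=k),
            np.clip(rng.normal(190, 25, size=k), 150, 400).astype(np.int64),
        )
        strands = np.where(rng.random(k) < 0.5, "+", "-")
        for c, ln, st in zip(centers, lens, strands):
            start = max(0, int(c) - int(ln) // 2)
            rows.append({"chrom": chrom, "start": start, "end": start + int(ln),
                         "name": ".", "score": 0, "strand": st})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
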