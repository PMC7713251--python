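"""Study-condition benchmarks on synthetic genomes with planted structure.

Each function regenerates its inputs from a seed, runs the relevant
analysis stages, and returns the summary quantities: domain recovery under
planted regulation, false-structure rates on null genomes, TAD
co-regulation calibration, and border insulation.  They are used both by
the validation test suite and by the reproduction script.

Problem sizes are fixed here as part of the benchmark definitions: domain
recovery uses 2 x 1000 genes with 30 planted domains; null calibration uses
200 independent 1000-gene genomes; the TAD co-regulation calibration uses a
~4800-TAD genome because the per-bin observed/expected ratio has sampling
sd ~ 1/sqrt(p_b * n_TADs) and smaller genomes cannot resolve a +-20% band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import domains, neighborhood as nb, regulation
from .simulate import (
    SimulationConfig,
    default_planted_domains,
    generate_enhancers,
    generate_genome,
    generate_tads,
    plant_regulation,
)


def _matches(planted_row, trds: pd.DataFrame, tol: int = 1) -> bool:
    cand = trds[
        (trds["chrom"] == planted_row["chrom"])
        & (trds["category"] == planted_row["category"])
        & ((trds["first_ordinal"] - planted_row["first_ordinal"]).abs() <= tol)
        & ((trds["last_ordinal"] - planted_row["last_ordinal"]).abs() <= tol)
    ]
    return len(cand) > 0


def trd_recovery_benchmark(seed: int = 0, n_domains: int = 30) -> dict:
    """Recovery of planted co-regulated domains on a 2 x 1000-gene genome
    (effect 1.5 +- 0.3 log2 units over background sd 0.25), plus domain
    descriptives and concordant-enhancer association."""
    cfg = SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        genes_per_chromosome=1000,
        planted_domains=default_planted_domains(n_domains),
        motif_enrichment_spec={"AP1": {"FC>=4": 10.0}},
        n_enhancers=2000,
    )
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    enh = enh.copy()
    from .peaks import call_enhancer_regulation

    enh["regulation"] = call_enhancer_regulation(enh).to_numpy()

    trds = domains.call_trds(genes)
    recovered = sum(
        _matches(row, trds) for _, row in labels.domains.iterrows()
    )
    trds_assoc, null = domains.associate_enhancers(
        trds, enh, iterations=200, seed=seed + 1
    )
    up = trds_assoc["category"].str.endswith("-up")
    return {
        "n_planted": len(labels.domains),
        "n_called": len(trds),
        "recovery": recovered / len(labels.domains),
        "mean_size_kb": float(trds["size_kb"].mean()),
        "mean_genes": float(trds["n_genes"].mean()),
        "frac_up_associated": float(trds_assoc.loc[up, "associated"].mean()),
        "frac_down_associated": float(trds_assoc.loc[~up, "associated"].mean()),
        "association_p": null.p,
    }


def null_calibration_benchmark(
    seed: int = 0,
    n_genomes: int = 200,
    iterations: int = 5000,
    n_anchors: int = 25,
) -> dict:
    """False-structure rates on genomes with no planted regulation.

    Per genome: the called domain count is compared with the central 99%
    interval of its label-permutation null, and per-position neighborhood
    Mann-Whitney p-values (random anchors vs circular-shift null) are
    pooled; the pooled p-values are tested for uniformity (KS).

    The anchor density is kept low (25 anchors over ~780 expressed genes)
    because the real and shifted-anchor neighbor sets draw from the same
    finite gene list: observations shared between the two Mann-Whitney
    samples (expected ~ n_anchors^2 / n_genes per comparison) bias the test
    conservative and distort the null p-value distribution.
    """
    rng = np.random.default_rng(seed)
    inside = 0
    counts = []
    pvals: list[float] = []
    for g in range(n_genomes):
        cfg = SimulationConfig(
            seed=seed + 5000 + g, n_chromosomes=2, genes_per_chromosome=750,
            planted_domains=[],
        )
        genes, _ = plant_regulation(generate_genome(cfg), cfg)
        null = domains.trd_count_null(
            genes, iterations=iterations, seed=seed + 6000 + g
        )
        lo, hi = null.central_interval(0.99)
        inside += lo <= null.observed <= hi
        counts.append(null.observed)
        ordered = nb.order_genes(genes)
        anchors = rng.choice(
            ordered["gene_id"].to_numpy(), size=n_anchors, replace=False
        )
        summary = nb.gene_neighborhood_summary(
            anchors, ordered,
            scheme=nb.RandomizationScheme(seed=seed + 7000 + g),
        )
        pvals.extend(summary["mannwhitney_p"].dropna().tolist())
    ks = sps.kstest(pvals, "uniform")
    return {
        "n_genomes": n_genomes,
        "frac_inside_99": inside / n_genomes,
        "mean_trd_count": float(np.mean(counts)),
        "n_pvalues": len(pvals),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def tad_calibration_null(seed: int = 0) -> pd.DataFrame:
    """TAD co-regulation observed/expected ratios on a null genome large
    enough (~4800 TADs of ~5 expressed genes) for the 10-bin ratios to be
    informative."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=2, genes_per_chromosome=10_000,
        intergene_spacing_median=20_000, frac_expressed=1.0,
        planted_domains=[], tad_mean_size=100_000,
    )
    genes, _ = plant_regulation(generate_genome(cfg), cfg)
    tads = generate_tads(genes, cfg)
    return domains.tad_coregulation(tads, genes, iterations=500, seed=seed + 1)


def tad_planted_benchmark(seed: int = 0, frac_coherent: float = 0.3) -> dict:
    """TAD co-regulation on a genome whose TADs tile coherently regulated
    blocks: a fraction of TADs get all-gene same-sign log2FC, the rest
    background.  Extreme fraction bins should exceed the null, the bin
    containing 50% should fall below it."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=2, genes_per_chromosome=2000,
        intergene_spacing_median=25_000, frac_expressed=1.0,
        planted_domains=[], tad_mean_size=250_000,
    )
    genes, _ = plant_regulation(generate_genome(cfg), cfg)
    tads = generate_tads(genes, cfg)
    rng = np.random.default_rng(seed + 9)
    tad_of = domains.assign_genes_to_tads(tads, genes)
    genes = genes.copy()
    fc = rng.normal(0.0, 0.5, size=len(genes))
    coherent = {
        t: s
        for t, s in zip(
            tads["domain_id"],
            np.where(rng.random(len(tads)) < frac_coherent,
                     np.where(rng.random(len(tads)) < 0.5, 1.0, -1.0), 0.0),
        )
        if s != 0.0
    }
    for i, t in tad_of.items():
        s = coherent.get(t, 0.0)
        if s != 0.0:
            fc[genes.index.get_loc(i)] = s * abs(rng.normal(1.0, 0.5))
    genes["log2fc_2h"] = fc
    table = domains.tad_coregulation(tads, genes, iterations=500, seed=seed + 2)
    mid = table[(table["bin_low"] <= 0.5) & (table["bin_high"] > 0.5)]
    return {
        "ratio_low": float(table["ratio"].iloc[0]),
        "ratio_high": float(table["ratio"].iloc[-1]),
        "ratio_mid": float(mid["ratio"].iloc[0]),
        "table": table,
    }


def border_insulation_benchmark(seed: int = 0) -> dict:
    """Binned FC correlation of contiguous gene pairs split by TAD borders
    on a genome with TAD-confined expression effects (per-TAD random
    effect sd 1.0, per-gene noise sd 0.3)."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=2, genes_per_chromosome=1001,
        intergene_spacing_median=50_000, frac_expressed=1.0,
        planted_domains=[], tad_mean_size=200_000,
    )
    genes, _ = plant_regulation(generate_genome(cfg), cfg)
    tads = generate_tads(genes, cfg)
    rng = np.random.default_rng(seed + 3)
    effects = dict(
        zip(tads["domain_id"], rng.normal(0.0, 1.0, size=len(tads)))
    )
    tad_of = domains.assign_genes_to_tads(tads, genes)
    genes = genes.copy()
    genes["log2fc_2h"] = [
        effects.get(tad_of.get(i), 0.0) + rng.normal(0.0, 0.3)
        for i in genes.index
    ]
    borders = pd.DataFrame(
        [
            {"chrom": chrom, "pos": p}
            for chrom, grp in tads.groupby("chrom")
            for p in sorted(grp["start"])[1:]
        ]
    )
    res = domains.border_pair_analysis(genes, borders)
    return {
        "n_pairs": res["n_within"] + res["n_cross"],
        "n_cross": res["n_cross"],
        "within_rho": res["within"]["rho"],
        "cross_rho_raw": res["cross"]["rho_raw"],
        "cross_rho_binned": res["cross"]["rho"],
    }
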