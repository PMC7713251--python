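"""Synthetic-genome generator: determinism, planted structure and the
statistical properties promised by construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coregdom import neighborhood as nb, regulation
from coregdom.simulate import (
    ConfigurationError,
    PlantedDomain,
    SimulationConfig,
    default_planted_domains,
    generate_contact_matrix,
    generate_enhancers,
    generate_footprints,
    generate_fragments,
    generate_genome,
    generate_tads,
    plant_regulation,
)


def test_genome_counts_and_ordinals():
    cfg = SimulationConfig(seed=0, n_chromosomes=2, genes_per_chromosome=100,
                           planted_domains=[])
    genes = generate_genome(cfg)
    assert len(genes) == 200
    for _, grp in genes.groupby("chrom"):
        assert list(grp["tss"]) == sorted(grp["tss"])
        # non-overlap in annotation order
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()


def test_genome_deterministic():
    cfg = SimulationConfig(seed=5)
    pd.testing.assert_frame_equal(generate_genome(cfg), generate_genome(cfg))


def test_genome_median_tss_spacing():
    cfg = SimulationConfig(seed=2, n_chromosomes=1, genes_per_chromosome=1000,
                           intergene_spacing_median=50_000, planted_domains=[])
    genes = generate_genome(cfg)
    gaps = np.diff(genes["tss"].to_numpy())
    assert 40_000 <= np.median(gaps) <= 60_000


def test_invalid_config_names_field():
    with pytest.raises(ConfigurationError, match="n_chromosomes"):
        generate_genome(SimulationConfig(n_chromosomes=0))
    with pytest.raises(ConfigurationError, match="frac_expressed"):
        SimulationConfig(frac_expressed=1.5).validate()
    with pytest.raises(ConfigurationError, match="n_genes"):
        SimulationConfig(
            planted_domains=[PlantedDomain("early-up", 1)]
        ).validate()


def test_null_genome_background_false_positive_rate():
    cfg = SimulationConfig(seed=3, n_chromosomes=2, genes_per_chromosome=1000,
                           planted_domains=[])
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    assert (labels.gene_category == "none").all()
    robust = (
        (genes["log2fc_2h"].abs() > 1) & (genes["p_adj"] < 0.05)
    ).mean()
    # closed form: 2*Phi(-1/sd) * 0.05 with sd = 0.25 is ~3e-6
    closed = 2 * sps.norm.sf(1 / cfg.background_fc_sd) * 0.05
    assert robust <= closed + 3 / len(genes)


def test_planted_domain_signs_and_truth_extent():
    cfg = SimulationConfig(
        seed=4, planted_domains=[PlantedDomain("early-up", 3)]
    )
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    dom = labels.domains.iloc[0]
    members = genes.set_index("gene_id").loc[dom["gene_ids"]]
    assert (members["log2fc_2h"] > 0).all()
    assert (members["p_adj"] < 0.05).all()
    # truth extent matches the expressed-gene ordinals of the members
    ordered = nb.order_genes(genes).set_index("gene_id")
    ords = ordered.loc[dom["gene_ids"], "ordinal"]
    assert dom["first_ordinal"] == ords.min()
    assert dom["last_ordinal"] == ords.max()
    assert dom["last_ordinal"] - dom["first_ordinal"] == 2  # contiguous


def test_planted_recovery_at_relaxed_threshold():
    """Early planted genes are recovered at >= 99% (defining-timepoint tail
    P(fc < 0.5) ~ 4e-4); late genes additionally require the unregulated
    early timepoint to stay within +-0.5, so their ceiling is
    1 - P(|N(0, 0.25)| > 0.5) ~ 95.4%."""
    cfg = SimulationConfig(seed=6, n_chromosomes=4, genes_per_chromosome=500,
                           planted_domains=default_planted_domains(60))
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    called = regulation.classify_genes(genes, fc_threshold=0.5)
    truth = labels.gene_category[labels.gene_category != "none"]
    got = called.set_index("gene_id").loc[truth.index, "category"]
    correct = got == truth
    early = truth.str.startswith("early")
    assert correct[early].mean() >= 0.99
    assert correct[~early].mean() >= 0.90


def test_capacity_error_when_domains_do_not_fit():
    cfg = SimulationConfig(
        seed=1, n_chromosomes=1, genes_per_chromosome=10,
        planted_domains=default_planted_domains(10),
    )
    with pytest.raises(ConfigurationError):
        plant_regulation(generate_genome(cfg), cfg)


def test_log2fc_12v2_identity():
    cfg = SimulationConfig(seed=7)
    genes, _ = plant_regulation(generate_genome(cfg), cfg)
    assert np.allclose(
        genes["log2fc_12v2"], genes["log2fc_12h"] - genes["log2fc_2h"]
    )


def _planted_genome(seed, linkage=1.0, opening=0.75, n_enh=2000):
    cfg = SimulationConfig(
        seed=seed, domain_enhancer_linkage=linkage,
        frac_enhancers_opening=opening, n_enhancers=n_enh,
        motif_enrichment_spec={"AP1": {"FC>=4": 10.0}},
    )
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    return cfg, genes, labels, enh


def test_enhancer_opening_fraction_binomial():
    cfg, genes, labels, enh = _planted_genome(seed=8, opening=0.8)
    frac = (2.0 ** enh["atac_log2fc_2h"] >= 1.5).mean()
    se = np.sqrt(0.8 * 0.2 / len(enh))
    assert abs(frac - 0.8) <= 4 * se + 0.01  # planted extras perturb slightly


def test_enhancer_opening_zero_boundary():
    cfg, genes, labels, enh = _planted_genome(seed=9, opening=0.0, linkage=0.0)
    assert (2.0 ** enh["atac_log2fc_2h"] < 1.5).all()


def test_full_linkage_places_concordant_enhancer_in_every_domain():
    cfg, genes, labels, enh = _planted_genome(seed=10, linkage=1.0)
    truth = labels.enhancer_regulation
    span = genes.set_index("gene_id")
    for _, dom in labels.domains.iterrows():
        members = span.loc[dom["gene_ids"]]
        lo = members["start"].min() - 50_000
        hi = members["end"].max() + 50_000
        want = dom["category"].replace("-up", "-activated").replace(
            "-down", "-repressed"
        )
        near = enh[
            (enh["chrom"] == dom["chrom"])
            & (enh["summit"] >= lo) & (enh["summit"] <= hi)
        ]
        assert (truth.loc[near["peak_id"]] == want).any()


def test_tads_tile_chromosomes():
    cfg = SimulationConfig(seed=11)
    genes = generate_genome(cfg)
    tads = generate_tads(genes, cfg)
    lengths = genes.attrs["chrom_lengths"]
    for chrom, grp in tads.groupby("chrom"):
        grp = grp.sort_values("start")
        assert grp["start"].iloc[0] == 0
        assert grp["end"].iloc[-1] == lengths[chrom]
        # adjacent TADs share exactly one boundary coordinate
        assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()
    approx = lengths["chr1"] / cfg.tad_mean_size
    n1 = (tads["chrom"] == "chr1").sum()
    assert abs(n1 - approx) <= max(3, 0.4 * approx)
    pd.testing.assert_frame_equal(tads, generate_tads(genes, cfg))


def test_tads_reject_oversized_mean():
    cfg = SimulationConfig(seed=12, tad_mean_size=10**12)
    genes = generate_genome(cfg)
    with pytest.raises(ConfigurationError, match="tad_mean_size"):
        generate_tads(genes, cfg)


def _tiling(n, size=1_000_000):
    return pd.DataFrame(
        [{"domain_id": f"t{i}", "chrom": "chr1", "start": i * size,
          "end": (i + 1) * size} for i in range(n)]
    )


def test_contact_matrix_symmetry_and_multiplier():
    cfg = SimulationConfig(seed=13, within_tad_multiplier=3.0, contact_base=400.0)
    tads = _tiling(5)
    cm = generate_contact_matrix(tads, "chr1", 5_000_000, 10_000, cfg)
    assert np.array_equal(cm.matrix, cm.matrix.T)
    assert (cm.matrix >= 0).all()
    # within/across ratio at fixed distance ~ multiplier
    d = 5
    n = cm.n_bins
    tad_of = np.arange(n) // 100
    i = np.arange(n - d)
    same = tad_of[i] == tad_of[i + d]
    vals = cm.matrix[i, i + d]
    ratio = vals[same].mean() / vals[~same].mean()
    assert 2.5 <= ratio <= 3.5

    null_cfg = SimulationConfig(seed=13, within_tad_multiplier=1.0,
                                contact_base=400.0)
    cm0 = generate_contact_matrix(tads, "chr1", 5_000_000, 10_000, null_cfg)
    vals0 = cm0.matrix[i, i + d]
    ratio0 = vals0[same].mean() / vals0[~same].mean()
    assert 0.9 <= ratio0 <= 1.1


def test_contact_matrix_rejects_bad_bin():
    cfg = SimulationConfig(seed=14)
    with pytest.raises(ConfigurationError, match="bin_size"):
        generate_contact_matrix(_tiling(2), "chr1", 2_000_000, 0, cfg)


def _peaks_for_footprints(seed, odds):
    cfg = SimulationConfig(
        seed=seed, n_enhancers=3000,
        motif_enrichment_spec={"AP1": odds},
        frac_enhancers_opening=0.75,
    )
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    return cfg, enh


def test_footprints_planted_odds_realized():
    from coregdom import footprints as fp
    from coregdom.peaks import assign_accessibility_category

    cfg, enh = _peaks_for_footprints(15, {"FC>=4": 10.0})
    real, bg = generate_footprints(enh, cfg)
    assert len(bg) == 5 * len(real)
    cats = pd.Series(
        assign_accessibility_category(enh["atac_log2fc_2h"]).to_numpy(),
        index=enh["peak_id"],
    )
    top = set(cats[cats == "FC>=4"].index)
    fg = real[real["peak_id"].isin(top)]
    bg_top = bg[bg["peak_id"].str.replace(r"_bg\d+$", "", regex=True).isin(top)]
    table = fp.enrichment_table(fg, bg_top, motifs=["AP1"])
    assert 7.0 <= table["enr"].iloc[0] <= 13.0


def test_footprints_null_odds_near_one():
    from coregdom import footprints as fp

    cfg, enh = _peaks_for_footprints(16, {"FC>=4": 1.0})
    real, bg = generate_footprints(enh, cfg)
    table = fp.enrichment_table(real, bg, motifs=["AP1"])
    assert 0.85 <= table["enr"].iloc[0] <= 1.15


def test_footprints_require_motif_spec():
    cfg = SimulationConfig(seed=17, motif_enrichment_spec={})
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    with pytest.raises(ConfigurationError, match="motif"):
        generate_footprints(enh, cfg)
    with pytest.raises(ConfigurationError, match="odds"):
        SimulationConfig(motif_enrichment_spec={"AP1": {"FC>=4": 0}}).validate()


def test_fragments_length_mixture_and_strand_balance():
    cfg = SimulationConfig(seed=18, frac_sub100=0.6, n_enhancers=500,
                           motif_enrichment_spec={"AP1": {}})
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    frags = generate_fragments(enh, cfg)
    n = len(frags)
    sub = ((frags["end"] - frags["start"]) < 100).mean()
    assert abs(sub - 0.6) <= 4 * np.sqrt(0.6 * 0.4 / n)
    plus = (frags["strand"] == "+").mean()
    assert abs(plus - 0.5) <= 4 * np.sqrt(0.25 / n)
    pd.testing.assert_frame_equal(frags, generate_fragments(enh, cfg))
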