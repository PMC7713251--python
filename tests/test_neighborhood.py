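"""Genome-order neighborhood assignments, randomization schemes, distance
bins, binned correlations and signal metaplots."""

import numpy as np
import pandas as pd
import pytest

from coregdom import neighborhood as nb
from conftest import make_gene_table


def test_order_genes_skips_non_expressed():
    genes = make_gene_table(
        [10_000, 20_000, 30_000], expressed=[True, False, True]
    )
    ordered = nb.order_genes(genes)
    assert list(ordered["gene_id"]) == ["chr1_g1", "chr1_g3"]
    assert list(ordered["ordinal"]) == [1, 2]


def test_order_genes_empty_chromosome():
    genes = make_gene_table([], expressed=[])
    assert nb.order_genes(genes).empty


def test_order_genes_tie_break_stable():
    genes = make_gene_table([10_000, 10_000])
    ordered = nb.order_genes(genes)
    assert list(ordered["gene_id"]) == ["chr1_g1", "chr1_g2"]


def enhancer_frame(summits, chrom="chr1"):
    return pd.DataFrame(
        {
            "peak_id": [f"e{i}" for i in range(len(summits))],
            "chrom": chrom,
            "summit": summits,
        }
    )


def test_enhancer_neighbors_example():
    ordered = nb.order_genes(make_gene_table([10_000, 20_000, 30_000, 40_000]))
    assign = nb.assign_enhancer_neighbors(enhancer_frame([25_000]), ordered)
    got = assign.set_index("position")["gene_id"].to_dict()
    assert got == {-1: "chr1_g2", -2: "chr1_g1", 1: "chr1_g3", 2: "chr1_g4"}
    d = assign.set_index("position")["distance"].to_dict()
    assert d[-1] == -5000 and d[1] == 5000


def test_enhancer_left_of_all_genes_only_downstream():
    ordered = nb.order_genes(make_gene_table([10_000, 20_000]))
    assign = nb.assign_enhancer_neighbors(enhancer_frame([1_000]), ordered)
    assert (assign["position"] > 0).all()


def test_enhancer_unknown_chromosome():
    ordered = nb.order_genes(make_gene_table([10_000]))
    with pytest.raises(ValueError, match="unknown chromosome"):
        nb.assign_enhancer_neighbors(enhancer_frame([5_000], chrom="chrZ"), ordered)


def test_enhancer_neighbors_match_bruteforce():
    """Eg+-n assignment equals a brute-force scan over all genes."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(2, 25))
        tss = np.sort(rng.choice(1_000_000, size=n, replace=False))
        ordered = nb.order_genes(make_gene_table(list(tss)))
        summit = int(rng.integers(0, 1_050_000))
        assign = nb.assign_enhancer_neighbors(enhancer_frame([summit]), ordered)
        got = assign.set_index("position")["gene_id"].to_dict()
        down = [g for t, g in zip(tss, ordered["gene_id"]) if t >= summit]
        up = [g for t, g in zip(tss, ordered["gene_id"]) if t < summit][::-1]
        expected = {}
        for k in range(1, 5):
            if k <= len(up):
                expected[-k] = up[k - 1]
            if k <= len(down):
                expected[k] = down[k - 1]
        assert got == expected


@pytest.mark.parametrize(
    "d, side, b",
    [(-120_000, "-", 2), (50_000, "+", 1), (0, "+", 0), (-49_999, "-", 0)],
)
def test_distance_bins(d, side, b):
    out = nb.assign_distance_bins([d])
    assert out["side"][0] == side and out["bin"][0] == b and out["in_range"][0]


def test_distance_bins_out_of_range():
    out = nb.assign_distance_bins([300_000, 250_000])
    assert not out["in_range"].any()


def universe_frame(n, chrom="chr1"):
    return pd.DataFrame(
        {"peak_id": [f"u{i}" for i in range(n)], "chrom": chrom,
         "summit": np.arange(n) * 1000}
    )


def test_circular_shift_wraps():
    uni = universe_frame(5)
    scheme = nb.RandomizationScheme(shift_k=2)
    mapping = nb.randomize_anchors(uni, ["u4"], scheme)
    assert mapping["u4"] == "u1"  # (4 + 2) mod 5


def test_circular_shift_identity_and_modulo():
    uni = universe_frame(30)
    ids = [f"u{i}" for i in range(30)]
    zero = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=0))
    assert all(zero[i] == i for i in ids)
    big = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=50))
    eff = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=20))
    assert big == eff  # 50 mod 30
    full = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=30))
    assert all(full[i] == i for i in ids)


def test_circular_shift_preserves_multiset_and_composes():
    uni = universe_frame(7)
    ids = [f"u{i}" for i in range(7)]
    s3 = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=3))
    assert sorted(s3.values()) == sorted(ids)
    s2_of_s3 = {
        i: nb.randomize_anchors(uni, [s3[i]], nb.RandomizationScheme(shift_k=2))[s3[i]]
        for i in ids
    }
    s5 = nb.randomize_anchors(uni, ids, nb.RandomizationScheme(shift_k=5))
    assert s2_of_s3 == s5


def test_sampling_reproducible_with_seed():
    uni = universe_frame(20)
    scheme = nb.RandomizationScheme(method="sample", seed=3)
    a = nb.randomize_anchors(uni, ["u0", "u5"], scheme)
    b = nb.randomize_anchors(uni, ["u0", "u5"], scheme)
    assert a == b


def _linked_genome(seed):
    from coregdom.peaks import call_enhancer_regulation
    from coregdom.simulate import (
        PlantedDomain, SimulationConfig, generate_enhancers,
        generate_genome, plant_regulation,
    )

    cfg = SimulationConfig(
        seed=seed, n_chromosomes=2, genes_per_chromosome=750,
        planted_domains=[PlantedDomain("early-up", 3) for _ in range(25)],
        domain_enhancer_linkage=1.0, n_enhancers=1500,
        motif_enrichment_spec={"AP1": {}},
    )
    genes, labels = plant_regulation(generate_genome(cfg), cfg)
    enh, labels = generate_enhancers(genes, labels, cfg)
    enh["regulation"] = call_enhancer_regulation(enh).to_numpy()
    return genes, enh


def test_planted_up_domains_shift_flanking_gene_fc():
    """Genes at Eg+-1 of activated enhancers linked to planted up-domains
    are upshifted relative to the circular-shift null."""
    genes, enh = _linked_genome(31)
    ordered = nb.order_genes(genes)
    summary = nb.enhancer_neighborhood_summary(
        enh, "early-activated", ordered,
        scheme=nb.RandomizationScheme(seed=1),
    ).set_index("position")
    for pos in (-1, 1):
        assert summary.loc[pos, "median_real"] > summary.loc[pos, "median_random"]
        assert summary.loc[pos, "mannwhitney_p"] < 0.01


def test_continuity_interposed_genes_follow_domain_direction():
    """When an enhancer's Eg+2 gene is robustly upregulated, the interposed
    Eg+1 distribution is shifted up relative to the random baseline."""
    from coregdom import regulation

    genes, enh = _linked_genome(32)
    classified = regulation.classify_genes(genes)
    robust = regulation.robust_subset(classified)
    res = nb.continuity_test(
        enh, "early-activated", nb.order_genes(genes),
        robust.loc[robust["category"] == "early-up", "gene_id"],
        target_position=2, scheme=nb.RandomizationScheme(seed=2),
    )
    assert res["n_anchors"] > 5
    assert (
        np.median(res["positions"][1]) > np.median(res["baseline"][1]) + 0.5
    )


def test_continuity_rejects_position_three():
    genes = make_gene_table([10_000, 20_000])
    ordered = nb.order_genes(genes)
    enh = enhancer_frame([15_000])
    enh["regulation"] = "early-activated"
    with pytest.raises(ValueError, match="-2 or \\+2"):
        nb.continuity_test(enh, "early-activated", ordered, set(), 3)


def test_binned_correlation_exact_relations():
    x = np.linspace(-2, 2, 200)
    rho, slope, bins = nb.binned_fc_correlation(x, 2 * x)
    assert rho == 1.0 and slope == pytest.approx(2.0)
    rho_neg, _, _ = nb.binned_fc_correlation(x, -x)
    assert rho_neg == -1.0
    assert len(bins) == 20


def test_binned_correlation_noisy_slope():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 2000)
    y = x + rng.normal(0, 0.1, 2000)
    _, slope, _ = nb.binned_fc_correlation(x, y)
    assert 0.9 <= slope <= 1.1


def test_binned_correlation_degenerate_inputs():
    with pytest.raises(ValueError, match="identical"):
        nb.binned_fc_correlation(np.ones(50), np.arange(50))
    with pytest.raises(ValueError, match="at least 3 bins"):
        nb.binned_fc_correlation(np.arange(50), np.arange(50), n_bins=2)
    with pytest.raises(ValueError, match="pairs"):
        nb.binned_fc_correlation(np.arange(5), np.arange(5), n_bins=20)


def point_signal(positions, treat, ctrl, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "treat": treat, "ctrl": ctrl})


def test_metaplot_identity_and_self_subtraction():
    anchors = pd.DataFrame({"chrom": ["chr1"], "tss": [500_000]})
    pos = np.arange(250_000, 750_000, 5_000)
    sig = point_signal(pos, np.full(len(pos), 4.0), np.full(len(pos), 4.0))
    prof = nb.signal_metaplot_around_genes(anchors, anchors, sig)
    assert np.allclose(prof["log2fc_real"], 0.0)
    assert np.allclose(prof["log2fc_over_random"], 0.0)


def test_metaplot_locality_of_planted_signal():
    anchors = pd.DataFrame({"chrom": ["chr1"], "tss": [500_000]})
    rand = pd.DataFrame({"chrom": ["chr1"], "tss": [1_500_000]})
    pos = np.arange(0, 2_000_000, 5_000)
    treat = np.full(len(pos), 2.0)
    near = np.abs(pos - 500_000) < 50_000
    treat[near] = 20.0
    sig = point_signal(pos, treat, np.full(len(pos), 2.0))
    prof = nb.signal_metaplot_around_genes(anchors, rand, sig)
    central = prof["offset"].abs() < 50_000
    assert (prof.loc[central, "log2fc_over_random"] > 1.0).all()
    outer = prof["offset"].abs() >= 60_000
    assert prof.loc[outer, "log2fc_over_random"].abs().max() < 0.5


def test_metaplot_rejects_misaligned_bins():
    anchors = pd.DataFrame({"chrom": ["chr1"], "tss": [0]})
    with pytest.raises(ValueError, match="divide"):
        nb.signal_metaplot_around_genes(
            anchors, anchors, point_signal([1], [1], [1]), bin_size=7_000
        )


def test_exclusion_interval_modes():
    genes = make_gene_table([10_000])
    gb = nb.exclusion_intervals(genes, "gene_bodies")
    assert (gb["start"][0], gb["end"][0]) == (8_000, 22_000)
    ts = nb.exclusion_intervals(genes, "tss")
    assert (ts["start"][0], ts["end"][0]) == (5_000, 15_000)
    assert nb.exclusion_intervals(genes, "none").empty
    with pytest.raises(ValueError, match="exclusion"):
        nb.exclusion_intervals(genes, "bodies")
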