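"""Stratification, histograms, and the GCU vs non-GCU statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modaudit import (
    SiteRecord,
    compare_gcu,
    paired_sample_compare,
    stratify,
    summarize_density,
)
from modaudit.context_compare import cohens_d, welch_z
from modaudit.errors import ComparisonError, DegenerateVarianceError


def _sites_from_fractions(fracs, tx="tx1", positions=None, depth=1000):
    """Sites at given positions with mod_count chosen to hit each fraction."""
    out = []
    for i, f in enumerate(fracs):
        pos = positions[i] if positions else i
        mod = round(f * depth)
        out.append(SiteRecord(tx, pos, depth, mod, mod / depth))
    return out


# --- summarize_density -----------------------------------------------------

def test_bins_half_open_with_final_closed():
    hist = summarize_density([0.0, 0.024, 0.025])
    assert hist[0] == (0.0, 2)
    assert hist[1] == (0.025, 1)
    # fraction 1.0 lands in the final bin [0.975, 1.0]
    hist = summarize_density([1.0])
    assert hist[-1] == (pytest.approx(0.975), 1)


def test_empty_histogram_is_all_zero():
    hist = summarize_density([])
    assert len(hist) == 40
    assert all(c == 0 for _, c in hist)


def test_partial_final_bin():
    hist = summarize_density([0.95], bin_width=0.3)
    assert [low for low, _ in hist] == pytest.approx([0.0, 0.3, 0.6, 0.9])
    assert hist[-1][1] == 1


@given(st.lists(st.floats(0, 1), max_size=200), st.sampled_from([0.025, 0.1, 0.3]))
def test_histogram_conserves_n(fracs, width):
    hist = summarize_density(fracs, width)
    assert sum(c for _, c in hist) == len(fracs)


# --- stratify --------------------------------------------------------------

def test_stratify_groups_by_central_kmer():
    #        0123456789
    ref = {"tx1": "AGCTAGCTACCCA"}  # GCU at 2 and 6; CCC at 10
    sites = _sites_from_fractions([0.4, 0.6, 0.2], positions=[2, 6, 10], depth=100)
    strata = stratify(sites, ref, min_depth=0, min_fraction=-1)
    assert strata["GCU"].n == 2
    assert strata["GCU"].median == pytest.approx(0.5)
    assert strata["CCC"].n == 1
    assert strata["CCC"].median == pytest.approx(0.2)


def test_stratify_fraction_filter_is_strict():
    ref = {"tx1": "AGCTAGCTA"}
    sites = _sites_from_fractions([0.0, 0.6], positions=[2, 6], depth=100)
    strata = stratify(sites, ref, min_depth=0, min_fraction=0.0)
    assert strata["GCU"].n == 1  # fraction exactly 0 excluded under ">0"


def test_stratify_depth_filter_is_strict():
    ref = {"tx1": "AGCTAGCTA"}
    sites = [SiteRecord("tx1", 2, 10, 5, 0.5), SiteRecord("tx1", 6, 11, 5, 5 / 11)]
    strata = stratify(sites, ref, min_depth=10, min_fraction=0.0)
    assert strata["GCU"].n == 1


def test_stratum_histogram_conserves_n(sim_small):
    ref, sites, _, _ = sim_small
    for s in stratify(sites, ref, min_depth=10, min_fraction=0.0).values():
        assert sum(c for _, c in s.histogram) == s.n


# --- Welch z and Cohen's d -------------------------------------------------

def test_cohens_d_hand_example():
    a = np.array([0.1, 0.2, 0.3])
    b = np.array([0.2, 0.3, 0.4])
    assert cohens_d(a, b) == pytest.approx(-1.0)  # mean diff -0.1, pooled SD 0.1


def test_welch_z_against_statsmodels():
    """Independent oracle: statsmodels CompareMeans with unequal variances."""
    from statsmodels.stats.weightstats import CompareMeans, DescrStatsW

    rng = np.random.default_rng(77)
    for _ in range(50):
        a = rng.normal(0.3, 0.1, rng.integers(5, 40))
        b = rng.normal(0.25, 0.15, rng.integers(5, 40))
        z, p = welch_z(a, b)
        z_ref, p_ref = CompareMeans(DescrStatsW(a), DescrStatsW(b)).ztest_ind(
            usevar="unequal"
        )
        assert z == pytest.approx(z_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)


def test_cohens_d_against_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(78)
    for _ in range(25):
        a = rng.normal(0.3, 0.1, rng.integers(5, 30))
        b = rng.normal(0.2, 0.2, rng.integers(5, 30))
        assert cohens_d(a, b) == pytest.approx(
            pg.compute_effsize(a, b, eftype="cohen"), abs=1e-9
        )


# --- compare_gcu -----------------------------------------------------------

def _gcu_ref_sites(gcu_fracs, other_fracs, depth=1000):
    gcu_pos = [2, 6, 10]
    other_pos = [15, 21]
    ref = {"tx1": "AGCTAGCTAGCTAACCCAACCCAA"}
    sites = _sites_from_fractions(gcu_fracs, positions=gcu_pos[: len(gcu_fracs)], depth=depth)
    sites += _sites_from_fractions(other_fracs, positions=other_pos[: len(other_fracs)], depth=depth)
    return ref, sites


def test_compare_identical_groups_is_null():
    ref, sites = _gcu_ref_sites([0.1, 0.2], [0.1, 0.2])
    r = compare_gcu(sites, ref, min_depth=0)
    assert r.z == 0 and r.p_two_tailed == 1.0 and r.cohens_d == 0
    assert r.median_fold == pytest.approx(1.0)


def test_compare_median_fold():
    ref, sites = _gcu_ref_sites([0.3, 0.4, 0.5], [0.15, 0.25])
    r = compare_gcu(sites, ref, min_depth=0)
    assert r.median_fold == pytest.approx(0.4 / 0.2)


def test_compare_p_matches_z_within_1e12():
    from scipy.stats import norm

    ref, sites = _gcu_ref_sites([0.3, 0.4, 0.5], [0.15, 0.25])
    r = compare_gcu(sites, ref, min_depth=0)
    assert r.p_two_tailed == pytest.approx(2 * (1 - norm.cdf(abs(r.z))), abs=1e-12)


def test_compare_empty_group_errors():
    ref, sites = _gcu_ref_sites([0.3, 0.4], [])
    with pytest.raises(ComparisonError):
        compare_gcu(sites, ref, min_depth=0)


def test_compare_degenerate_variance_errors():
    ref, sites = _gcu_ref_sites([0.3, 0.3], [0.3, 0.3])
    with pytest.raises(DegenerateVarianceError):
        compare_gcu(sites, ref, min_depth=0)


def test_partition_property(sim_small):
    """n_gcu + n_other equals the central-C sites passing the depth filter
    with full 3-mer context."""
    from modaudit import central_kmer, filter_depth
    from modaudit.site_stats import Rejection

    ref, sites, _, _ = sim_small
    refd = {t.id: t.seq for t in ref}
    r = compare_gcu(sites, ref, min_depth=50)
    expected = sum(
        1
        for s in filter_depth(sites, 50)
        if not isinstance(central_kmer(refd, s.transcript_id, s.pos), Rejection)
    )
    assert r.n_gcu + r.n_other == expected


# --- paired_sample_compare -------------------------------------------------

def test_paired_identical_inputs_are_indistinguishable(sim_small):
    ref, sites, _, _ = sim_small
    strata = paired_sample_compare(sites, sites, ref, min_depth=10)
    assert strata
    for s in strata.values():
        assert s.ks_statistic == 0.0
        assert s.median_difference == 0.0


def test_paired_no_shared_kmers_errors():
    ref = {"tx1": "AGCTAGCTA"}
    a = _sites_from_fractions([0.5], positions=[2], depth=100)
    with pytest.raises(ComparisonError):
        paired_sample_compare(a, [], ref, min_depth=0)


def test_paired_position_matching_drops_unshared():
    ref = {"tx1": "AGCTAGCTA"}
    native = _sites_from_fractions([0.5, 0.6], positions=[2, 6], depth=100)
    ivt = _sites_from_fractions([0.5], positions=[2], depth=100)
    strata = paired_sample_compare(native, ivt, ref, min_depth=0, position_matched=True)
    assert strata["GCU"].n_native == strata["GCU"].n_ivt == 1
    unmatched = paired_sample_compare(native, ivt, ref, min_depth=0, position_matched=False)
    assert unmatched["GCU"].n_native == 2


def test_paired_same_generator_medians_close():
    """Native and IVT simulated from the same per-context probabilities agree
    per k-mer to within binomial sampling error at depth 100."""
    from modaudit import SimulationConfig, generate_transcriptome, make_ivt_config, simulate_pair

    cfg = SimulationConfig(n_transcripts=10, length_mean=1000, seed=5)
    ref = generate_transcriptome(cfg)
    (nat, _), (ivt, _) = simulate_pair(ref, cfg, make_ivt_config(cfg))
    strata = paired_sample_compare(nat, ivt, ref, min_depth=10, min_fraction=0.0)
    big = {k: s for k, s in strata.items() if min(s.n_native, s.n_ivt) >= 50}
    assert len(big) >= 10
    assert max(abs(s.median_difference) for s in big.values()) < 0.05
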