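"""Coalescent ROH tracts, closed-form expectations, Ne estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from clankin.genmap import GeneticMapSpec
from clankin.rohne import (FIT_EDGES_CM, CoalParams, InbreedingFilter,
                           NeEstimate, RohBins, bin_roh, estimate_ne,
                           estimate_ne_from_bins, expected_tract_counts,
                           simulate_roh_cohort, simulate_tracts,
                           tract_density)


@pytest.fixture(scope="module")
def one_chrom_map():
    return GeneticMapSpec.from_rows([("1", 200.0, 200_000_000)])


def test_tracts_partition_chromosomes(one_chrom_map):
    params = CoalParams(ne=100, gmap=GeneticMapSpec.toy(), n_individuals=5,
                        seed=3)
    for tl in simulate_tracts(params):
        for c, (starts, ends, t) in enumerate(tl.tracts):
            L = GeneticMapSpec.toy().lengths_cM[c]
            assert starts[0] == 0.0
            assert ends[-1] == pytest.approx(L)
            assert np.allclose(starts[1:], ends[:-1])
            assert np.all(ends > starts)
            assert np.all(t > 0)


def test_conditional_tract_length_is_exponential_in_tmrca(one_chrom_map):
    """Interior tract length given its TMRCA t is Exp(2t) per Morgan, so
    2 t * length has unit mean."""
    params = CoalParams(ne=50, gmap=one_chrom_map, n_individuals=300, seed=4)
    prods = []
    for tl in simulate_tracts(params):
        starts, ends, t = tl.tracts[0]
        if len(t) > 2:
            lens_m = (ends[1:-1] - starts[1:-1]) / 100.0
            prods.extend(2.0 * t[1:-1] * lens_m)
    prods = np.asarray(prods)
    se = prods.std(ddof=1) / np.sqrt(len(prods))
    assert abs(prods.mean() - 1.0) < 3 * se


def test_tmrca_marginals(one_chrom_map):
    """Pointwise TMRCA (chromosome-start tract) has mean 2 Ne; tract-initial
    TMRCA at breakpoints is size-biased with mean 4 Ne."""
    ne = 200
    params = CoalParams(ne=ne, gmap=one_chrom_map, n_individuals=400, seed=5)
    first, interior = [], []
    for tl in simulate_tracts(params):
        _, _, t = tl.tracts[0]
        first.append(t[0])
        interior.extend(t[1:])
    first, interior = np.asarray(first), np.asarray(interior)
    se_f = first.std(ddof=1) / np.sqrt(len(first))
    assert abs(first.mean() - 2 * ne) < 3 * se_f
    se_i = interior.std(ddof=1) / np.sqrt(len(interior))
    assert abs(interior.mean() - 4 * ne) < 3 * se_i


def test_expected_counts_match_tmrca_mixture_quadrature(one_chrom_map):
    """Closed form equals numeric integration of the TMRCA mixture
    n(l) = integral of 4 t^2 exp(-2tl) lam exp(-lam t) dt at 20 grid points,
    weighted by (L - l)."""
    ne = 500
    lam = 1.0 / (2 * ne)
    L = 2.0  # Morgans

    def density(l):
        val, _ = integrate.quad(
            lambda t: 4 * t * t * np.exp(-2 * t * l) * lam * np.exp(-lam * t),
            0, np.inf)
        return val

    grid_l = np.linspace(0.04, 0.20, 21)
    for lo, hi in zip(grid_l[:-1], grid_l[1:]):
        closed = expected_tract_counts(ne, (lo * 100, hi * 100), one_chrom_map)
        brute, _ = integrate.quad(lambda l: density(l) * max(L - l, 0.0),
                                  lo, hi)
        assert closed[0] == pytest.approx(brute, rel=1e-6)
        # and the density itself matches the closed form
        assert density((lo + hi) / 2) == pytest.approx(
            float(tract_density((lo + hi) / 2, ne)), rel=1e-8)


def test_expected_counts_limits(one_chrom_map):
    # huge Ne -> vanishing counts in every positive-length bin
    tiny = expected_tract_counts(1e9, FIT_EDGES_CM, one_chrom_map)
    assert np.all(tiny < 1e-3)
    # long-tract limit: halving Ne doubles expected counts
    long_bin = (60.0, 80.0)
    a = expected_tract_counts(4000, long_bin, one_chrom_map)[0]
    b = expected_tract_counts(2000, long_bin, one_chrom_map)[0]
    assert b / a == pytest.approx(2.0, rel=0.05)
    with pytest.raises(ValueError):
        expected_tract_counts(500, (8.0, 4.0), one_chrom_map)


def test_simulator_matches_expected_counts_small():
    gmap = GeneticMapSpec.human_autosomes()
    ne = 500
    params = CoalParams(ne=ne, gmap=gmap, n_individuals=250, seed=6)
    counts = simulate_roh_cohort(params)
    exp = expected_tract_counts(ne, FIT_EDGES_CM, gmap)
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(len(counts))
    assert np.all(np.abs(mean - exp) < 3 * se)


def test_msprime_cross_check():
    """Independent oracle: tree spans of an msprime two-haplotype ancestry
    approximate the tract process; bin counts agree with the closed form to
    within the SMC-vs-exact-coalescent discrepancy."""
    msprime = pytest.importorskip("msprime")
    ne, L_bp, rho = 200, 200_000_000, 1e-8
    gmap = GeneticMapSpec.from_rows([("1", 200.0, L_bp)])
    reps = msprime.sim_ancestry(samples=1, ploidy=2, population_size=ne,
                                recombination_rate=rho, sequence_length=L_bp,
                                num_replicates=150, random_seed=11)
    edges_m = np.array([4.0, 20.0]) / 100.0
    count = 0
    n_rep = 0
    for ts in reps:
        n_rep += 1
        spans = []
        for tree in ts.trees():
            spans.append(tree.interval.span * rho)  # Morgans
        spans = np.asarray(spans)
        if len(spans) > 2:
            inner = spans[1:-1]
            count += int(np.sum((inner >= edges_m[0]) & (inner < edges_m[1])))
    mean = count / n_rep
    exp = expected_tract_counts(ne, (4.0, 20.0), gmap)[0]
    assert mean == pytest.approx(exp, rel=0.2)


# ---------------------------------------------------------------------------
# binning and the inbreeding filter
# ---------------------------------------------------------------------------

def _seg_df(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start_cM", "end_cM"])


def test_bin_roh_arithmetic_and_filter():
    df = _seg_df([("i", "1", 0, 5), ("i", "1", 10, 19), ("i", "2", 0, 25)])
    bins = bin_roh(df)
    assert bins.counts[0].tolist() == [1, 1, 0, 1]
    assert not bins.excluded[0]          # 25 cM of >20 cM ROH <= 40
    assert bins.max_segment_cM[0] == 25.0

    df2 = _seg_df([("a", "1", 0, 30), ("a", "2", 0, 15)])
    assert not bin_roh(df2).excluded[0]  # 30 <= 40 -> retained
    df3 = _seg_df([("b", "1", 0, 30), ("b", "2", 0, 25)])
    assert bin_roh(df3).excluded[0]      # 55 > 40 -> excluded
    assert not bin_roh(df3).consanguineous[0]
    df4 = _seg_df([("c", "1", 0, 80), ("c", "2", 0, 30)])
    assert bin_roh(df4).consanguineous[0]  # 110 > 100 cM


def test_bin_roh_rejects_overlapping_segments():
    df = _seg_df([("i", "1", 0, 10), ("i", "1", 5, 15)])
    with pytest.raises(ValueError, match="overlapping"):
        bin_roh(df)


def test_configurable_exclusion_threshold():
    df = _seg_df([("a", "1", 0, 45)])
    assert bin_roh(df).excluded[0]
    relaxed = bin_roh(df, inbreeding_filter=InbreedingFilter(threshold_cM=50))
    assert not relaxed.excluded[0]


def test_endogamy_contrast_flags_inbred_individuals(toy_map):
    from clankin.community import SimConfig, simulate_community
    cfg_hi = SimConfig(seed=21, founders_per_clan=3, generations=5,
                       endogamy_prob=0.95, offspring_mean=2.4)
    _, truth_hi = simulate_community(cfg_hi, toy_map, ibd_pairs="none")
    cfg_lo = SimConfig(seed=21, founders_per_clan=3, generations=5,
                       endogamy_prob=0.0, offspring_mean=2.4)
    _, truth_lo = simulate_community(cfg_lo, toy_map, ibd_pairs="none")
    hi = bin_roh(truth_hi.roh)
    assert len(truth_lo.roh) == 0 or not bin_roh(truth_lo.roh).excluded.any()
    assert hi.counts.sum() > 0


# ---------------------------------------------------------------------------
# Ne estimation
# ---------------------------------------------------------------------------

def test_mle_recovers_generating_value_exactly():
    gmap = GeneticMapSpec.human_autosomes()
    ne0 = 400.0
    observed = 1000 * expected_tract_counts(ne0, FIT_EDGES_CM, gmap)
    est = estimate_ne(observed, 1000, gmap)
    assert est.ne_mle == pytest.approx(ne0, rel=0.01)
    assert est.ci_low <= ne0 <= est.ci_high


def test_more_roh_means_smaller_ne():
    gmap = GeneticMapSpec.human_autosomes()
    observed = 500 * expected_tract_counts(600.0, FIT_EDGES_CM, gmap)
    a = estimate_ne(observed, 500, gmap)
    b = estimate_ne(observed * 4, 500, gmap)
    assert b.ne_mle < a.ne_mle


def test_all_zero_counts_reports_unbounded_upper():
    gmap = GeneticMapSpec.toy()
    est = estimate_ne(np.zeros(3), 10, gmap)
    assert est.upper_unbounded
    assert est.ci_high == np.inf


def test_parameter_recovery_simulated(caplog):
    gmap = GeneticMapSpec.human_autosomes()
    params = CoalParams(ne=300, gmap=gmap, n_individuals=1000, seed=12)
    counts = simulate_roh_cohort(params)
    est = estimate_ne(counts.sum(axis=0), 1000, gmap)
    assert est.ci_low <= 300 <= est.ci_high
    assert est.ne_mle == pytest.approx(300, rel=0.15)


def test_pedigree_census_cross_check(toy_map):
    """A long-run closed population of census size N yields Ne-hat within a
    factor of 2 of N (census is not effective size; the pedigree must run for
    tens of generations so that the medium-ROH coalescent spectrum fills in;
    the band is deliberately wide)."""
    from clankin.community import SimConfig, simulate_community
    for census, founders in ((50, 13), (200, 50)):
        cfg = SimConfig(seed=31, n_clans=2, founders_per_clan=founders,
                        generations=45, endogamy_prob=1.0, offspring_mean=2.8,
                        mt_mut_prob=0.0, max_generation_size=census)
        com, truth = simulate_community(cfg, toy_map, ibd_pairs="none",
                                        degrees=False)
        last_gen = max(i.generation for i in com.individuals)
        keep_ids = {i.id for i in com.individuals
                    if i.generation >= last_gen - 1}
        roh = truth.roh[truth.roh["id"].isin(keep_ids)]
        bins = bin_roh(roh, inbreeding_filter=InbreedingFilter(
            threshold_cM=1e9))
        est = estimate_ne_from_bins(bins, toy_map)
        assert 0.5 * census <= est.ne_mle <= 2.0 * census


def test_ne_decreases_with_endogamy(toy_map):
    from clankin.community import SimConfig, simulate_community

    def ne_at(e):
        vals = []
        for seed in (41, 42, 43):
            cfg = SimConfig(seed=seed, founders_per_clan=4, generations=5,
                            endogamy_prob=e, offspring_mean=2.3)
            _, truth = simulate_community(cfg, toy_map, ibd_pairs="none")
            bins = bin_roh(truth.roh, inbreeding_filter=InbreedingFilter(
                threshold_cM=1e9))
            if bins.counts.sum() == 0:
                vals.append(np.inf)
            else:
                vals.append(estimate_ne_from_bins(bins, toy_map).ne_mle)
        return np.median(vals)

    assert ne_at(0.95) < ne_at(0.2)
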