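"""Community generator: pedigree rules, gene dropping, truth tables."""

import numpy as np
import pandas as pd
import pytest

from clankin.community import (MISSING, DiploidGenotypes, MatingPoolError,
                               SimConfig, UNRELATED_DEGREE, degree_from_kinship,
                               derive_true_ibd, derive_true_roh, gene_drop,
                               kinship_coefficients, pseudo_haploidize,
                               sample_genotypes, simulate_community,
                               simulate_pair_matrix, transmit_uniparental)
from clankin.genmap import GeneticMapSpec

from conftest import build_pedigree


# ---------------------------------------------------------------------------
# pedigree and burial rules
# ---------------------------------------------------------------------------

def test_matriclan_burial_equals_matriline(small_community):
    com, _ = small_community
    for ind in com.individuals:
        assert ind.cemetery == ind.matriline


def test_full_endogamy_keeps_mt_lineages_on_founding_mothers(toy_map):
    cfg = SimConfig(seed=5, founders_per_clan=8, generations=3,
                    endogamy_prob=1.0, offspring_mean=2.6, avoid_full_sib=True)
    com, _ = simulate_community(cfg, toy_map, ibd_pairs="none")
    clans = {"N", "S"}
    # generation 1 has external fathers by necessity (no gen-0 males);
    # from then on every mt lineage is a founding-clan lineage
    assert {i.mt_lineage for i in com.individuals} <= clans
    assert all(not x.sex == "F" for x in com.externals)


def test_impossible_mating_pool_names_generation(toy_map):
    # a single founding mother's children are all full sibs, so at full
    # endogamy generation 2 has no eligible couple
    cfg = SimConfig(seed=1, n_clans=1, founders_per_clan=1, generations=3,
                    endogamy_prob=1.0, offspring_mean=4.0)
    with pytest.raises(MatingPoolError, match="generation"):
        simulate_community(cfg, toy_map, ibd_pairs="none")


def test_child_matriline_follows_mother(small_community):
    com, _ = small_community
    by_id = com.by_id
    for ind in com.individuals:
        if ind.mother_id is not None:
            assert ind.matriline == by_id[ind.mother_id].matriline
            assert ind.mt_lineage == by_id[ind.mother_id].mt_lineage
        if ind.sex == "M" and ind.father_id is not None:
            assert ind.y_lineage == by_id[ind.father_id].y_lineage


def test_determinism_identical_config_and_seed(toy_map):
    cfg = SimConfig(seed=17, founders_per_clan=3, generations=2, n_sites=500)
    com1, truth1 = simulate_community(cfg, toy_map)
    com2, truth2 = simulate_community(cfg, toy_map)
    assert com1.roster().equals(com2.roster())
    pd.testing.assert_frame_equal(truth1.pairs, truth2.pairs)
    pd.testing.assert_frame_equal(truth1.ibd, truth2.ibd)
    rng1, rng2 = (np.random.default_rng(4), np.random.default_rng(4))
    g1 = sample_genotypes(com1, 500, rng1)
    g2 = sample_genotypes(com2, 500, rng2)
    assert np.array_equal(g1.dosage, g2.dosage)


# ---------------------------------------------------------------------------
# gene dropping: conservation, crossovers, IBD/ROH truth
# ---------------------------------------------------------------------------

def test_tile_lengths_conserve_chromosome_length(small_community, toy_map):
    com, _ = small_community
    for iid, per_chrom in com.tilings.items():
        for c, (h1, h2) in enumerate(per_chrom):
            for h in (h1, h2):
                assert h.breaks[0] == 0.0
                assert h.breaks[-1] == pytest.approx(toy_map.lengths_cM[c])
                assert np.all(np.diff(h.breaks) > 0)
                total = np.sum(np.diff(h.breaks))
                assert total == pytest.approx(toy_map.lengths_cM[c])


def test_mean_crossover_count_is_map_length_in_morgans(toy_map):
    # one 100 cM chromosome -> mean one crossover per meiosis
    rows = [("P", "F", None, None, 0), ("X", "M", None, None, 0)]
    rows += [(f"C{i}", "F", "P", "X", 1) for i in range(600)]
    com = build_pedigree(rows, toy_map, seed=2)
    counts = [len(com.tilings[f"C{i}"][0][0].ids) - 1 for i in range(600)]
    # merged adjacent tiles can hide a crossover; tolerate broad 3-SE band
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 1.0) < 3 * se + 0.05


def test_parent_child_ibd1_spans_whole_map(toy_map):
    rows = [("P", "F", None, None, 0), ("X", "M", None, None, 0),
            ("C", "F", "P", "X", 1)]
    com = build_pedigree(rows, toy_map, seed=3)
    segs = derive_true_ibd(com, "P", "C")
    by_chrom = {}
    for chrom, s, e, state in segs:
        assert state in ("IBD1", "IBD2")
        by_chrom.setdefault(chrom, 0.0)
        by_chrom[chrom] += e - s
    for c, chrom in enumerate(toy_map.chrom_ids):
        assert by_chrom[chrom] == pytest.approx(toy_map.lengths_cM[c])


def test_self_pair_is_ibd2_everywhere(small_community, toy_map):
    com, _ = small_community
    iid = com.ids[0]
    segs = derive_true_ibd(com, iid, iid)
    assert all(state == "IBD2" for _, _, _, state in segs)
    assert sum(e - s for _, s, e, _ in segs) == pytest.approx(toy_map.total_cM)


def test_two_founders_share_nothing(toy_map):
    rows = [("A", "F", None, None, 0), ("B", "M", None, None, 0)]
    com = build_pedigree(rows, toy_map)
    assert derive_true_ibd(com, "A", "B") == []
    assert derive_true_roh(com, "A") == []


def test_unknown_individual_raises(toy_map):
    rows = [("A", "F", None, None, 0)]
    com = build_pedigree(rows, toy_map)
    with pytest.raises(KeyError):
        derive_true_ibd(com, "A", "nope")
    with pytest.raises(KeyError):
        derive_true_roh(com, "nope")


def _grid_scan_ibd(com, a, b, step=0.01):
    """Dense-grid oracle for IBD states."""
    out = []
    for c, chrom in enumerate(com.gmap.chrom_ids):
        grid = np.arange(step / 2, com.gmap.lengths_cM[c], step)
        a1, a2 = com.tilings[a][c]
        b1, b2 = com.tilings[b][c]
        va1, va2 = a1.id_at(grid), a2.id_at(grid)
        vb1, vb2 = b1.id_at(grid), b2.id_at(grid)
        ibd2 = ((va1 == vb1) & (va2 == vb2)) | ((va1 == vb2) & (va2 == vb1))
        share = (va1 == vb1) | (va1 == vb2) | (va2 == vb1) | (va2 == vb2)
        out.append(np.where(ibd2, 2, np.where(share, 1, 0)))
    return out


def test_ibd_and_roh_agree_with_grid_scan(small_community):
    com, _ = small_community
    rng = np.random.default_rng(0)
    ids = com.ids
    pairs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(20)]
    step = 0.01
    for a, b in pairs:
        segs = derive_true_ibd(com, a, b)
        states = _grid_scan_ibd(com, a, b, step)
        for c, chrom in enumerate(com.gmap.chrom_ids):
            grid = np.arange(step / 2, com.gmap.lengths_cM[c], step)
            from_segs = np.zeros(len(grid), dtype=int)
            for ch, s, e, st in segs:
                if ch == chrom:
                    from_segs[(grid >= s) & (grid < e)] = int(st[-1])
            assert np.array_equal(from_segs, states[c])
    for iid in rng.choice(ids, 5, replace=False):
        roh = derive_true_roh(com, iid)
        for c, chrom in enumerate(com.gmap.chrom_ids):
            grid = np.arange(step / 2, com.gmap.lengths_cM[c], step)
            h1, h2 = com.tilings[iid][c]
            expect = h1.id_at(grid) == h2.id_at(grid)
            got = np.zeros(len(grid), dtype=bool)
            for ch, s, e in roh:
                if ch == chrom:
                    got[(grid >= s) & (grid < e)] = True
            assert np.array_equal(got, expect)


def test_mendelian_k_fractions_for_standard_relationships(toy_map):
    """Realized IBD fractions match the pedigree k-vectors within 3 SE."""
    n_fam = 350
    rows = []
    for i in range(n_fam):
        rows += [(f"M{i}", "F", None, None, 0), (f"F{i}", "M", None, None, 0),
                 (f"F2{i}", "M", None, None, 0),
                 (f"A{i}", "F", f"M{i}", f"F{i}", 1),
                 (f"B{i}", "M", f"M{i}", f"F{i}", 1),
                 (f"H{i}", "F", f"M{i}", f"F2{i}", 1)]
    com = build_pedigree(rows, toy_map, seed=8)
    total = toy_map.total_cM

    def k_of(a, b):
        segs = derive_true_ibd(com, a, b)
        k1 = sum(e - s for _, s, e, st in segs if st == "IBD1") / total
        k2 = sum(e - s for _, s, e, st in segs if st == "IBD2") / total
        return k1, k2

    def check(pairs, want_k1, want_k2):
        k1s, k2s = zip(*(k_of(a, b) for a, b in pairs))
        for vals, want in ((k1s, want_k1), (k2s, want_k2)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - want) < 3 * max(se, 1e-9)

    check([(f"A{i}", f"B{i}") for i in range(n_fam)], 0.5, 0.25)   # full sibs
    check([(f"M{i}", f"A{i}") for i in range(n_fam)], 1.0, 0.0)    # parent-child
    check([(f"A{i}", f"H{i}") for i in range(n_fam)], 0.5, 0.0)    # half sibs
    check([(f"A{i}", f"A{(i+1) % n_fam}") for i in range(n_fam)], 0.0, 0.0)


def test_selfed_pedigree_shows_roh():
    """Parent-offspring mating: inbreeding coefficient 0.25, so at genome
    scale the grandchild carries ROH in essentially every replicate and ~25%
    of the map on average."""
    gmap = GeneticMapSpec.human_autosomes()
    hits, fracs = 0, []
    for seed in range(100):
        rows = [("A", "F", None, None, 0), ("X", "M", None, None, 0),
                ("C", "M", "A", "X", 1), ("G", "F", "A", "C", 2)]
        com = build_pedigree(rows, gmap, seed=seed)
        roh = derive_true_roh(com, "G")
        total = sum(e - s for _, s, e in roh)
        hits += total > 0
        fracs.append(total / gmap.total_cM)
    assert hits >= 99
    assert abs(np.mean(fracs) - 0.25) < 3 * np.std(fracs, ddof=1) / 10 + 0.01


def test_endogamy_does_not_decrease_roh(toy_map):
    def mean_roh(e, seed):
        cfg = SimConfig(seed=seed, founders_per_clan=4, generations=4,
                        endogamy_prob=e, offspring_mean=2.4)
        com, truth = simulate_community(cfg, toy_map, ibd_pairs="none")
        lens = truth.roh["end_cM"] - truth.roh["start_cM"]
        keep = lens >= 4.0
        n = len(com.individuals)
        return lens[keep].sum() / n

    lo = np.mean([mean_roh(0.1, s) for s in range(5)])
    hi = np.mean([mean_roh(0.9, s) for s in range(5)])
    assert hi >= lo


# ---------------------------------------------------------------------------
# pedigree degrees
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi,expected", [
    (0.25, 1), (0.375, 1), (0.125, 2), (0.0625, 3), (0.03125, 4),
    (1.5 * 2 ** -7, 6), (1.5 * 2 ** -8, UNRELATED_DEGREE),
    (0.0, UNRELATED_DEGREE),
])
def test_degree_band_rule(phi, expected):
    assert degree_from_kinship(phi) == expected


def test_kinship_coefficients_on_known_pedigree(toy_map):
    rows = [("M", "F", None, None, 0), ("F", "M", None, None, 0),
            ("A", "F", "M", "F", 1), ("B", "M", "M", "F", 1),
            ("X", "M", None, None, 0), ("C", "F", "A", "X", 2)]
    com = build_pedigree(rows, toy_map)
    phi = kinship_coefficients(com)

    def get(a, b):
        return phi[(a, b) if (a, b) in phi else (b, a)]

    assert get("A", "B") == pytest.approx(0.25)     # full sibs
    assert get("M", "A") == pytest.approx(0.25)     # parent-child
    assert get("B", "C") == pytest.approx(0.125)    # avuncular
    assert get("M", "C") == pytest.approx(0.125)    # grandmother
    assert get("M", "F") == pytest.approx(0.0)
    assert get("A", "A") == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# pseudo-haploidization
# ---------------------------------------------------------------------------

def test_pseudo_haploid_deterministic_homozygotes(toy_map):
    sites = pd.DataFrame({"snp_id": ["a", "b"], "chrom": ["1", "1"],
                          "bp": [10, 20], "cM": [0.1, 0.2],
                          "ref": "A", "alt": "G", "founder_alt_freq": 0.5})
    geno = DiploidGenotypes(sites=sites, ids=["i1", "i2"],
                            dosage=np.array([[0, 2], [2, 0]], dtype=np.int8))
    m = pseudo_haploidize(geno, 0.0, 0.0, np.random.default_rng(0))
    assert np.array_equal(m.calls, np.array([[0, 1], [1, 0]]))


def test_pseudo_haploid_het_sampling_and_missingness(toy_map):
    n = 10_000
    sites = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n)],
                          "chrom": "1", "bp": np.arange(1, n + 1),
                          "cM": np.arange(1, n + 1) * 1e-5,
                          "ref": "A", "alt": "G", "founder_alt_freq": 0.5})
    geno = DiploidGenotypes(sites=sites, ids=["i"],
                            dosage=np.ones((n, 1), dtype=np.int8))
    m = pseudo_haploidize(geno, 0.0, 0.0, np.random.default_rng(1))
    frac = m.calls.mean()
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)
    m2 = pseudo_haploidize(geno, 0.3, 0.0, np.random.default_rng(2))
    miss = (m2.calls == MISSING).mean()
    assert abs(miss - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)
    with pytest.raises(ValueError):
        pseudo_haploidize(geno, 1.5, 0.0, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# uniparental transmission
# ---------------------------------------------------------------------------

def test_mt_identical_within_matriline_when_no_mutation(toy_map):
    cfg = SimConfig(seed=9, founders_per_clan=3, generations=3,
                    mt_mut_prob=0.0, clan_mt_divergence=3)
    com, _ = simulate_community(cfg, toy_map, ibd_pairs="none")
    by_matriline = {}
    for ind in com.individuals:
        by_matriline.setdefault(ind.matriline, set()).add(
            com.mt_mutations[ind.id])
    for sets in by_matriline.values():
        assert len(sets) == 1
    mats = list(by_matriline.values())
    assert len(mats[0].pop() ^ mats[1].pop()) >= 3


def test_mt_zero_difference_clustering_recovers_matrilines(toy_map):
    from clankin.uniparental import MtSequenceSet, mt_cluster
    for seed in range(100):
        cfg = SimConfig(seed=seed, founders_per_clan=2, generations=2,
                        offspring_mean=2.0, mt_mut_prob=0.0)
        com, _ = simulate_community(cfg, toy_map, ibd_pairs="none")
        seqset = MtSequenceSet.from_mutation_sets(com.mt_mutations)
        part = mt_cluster(seqset)
        truth = {ind.id: ind.matriline for ind in com.individuals}
        # partitions equal: same grouping of ids
        by_label, by_truth = {}, {}
        for iid in seqset.ids:
            by_label.setdefault(part.labels[iid], set()).add(iid)
            by_truth.setdefault(truth[iid], set()).add(iid)
        assert set(map(frozenset, by_label.values())) == \
            set(map(frozenset, by_truth.values()))


# ---------------------------------------------------------------------------
# direct pair simulator
# ---------------------------------------------------------------------------

def test_pair_matrix_rejects_bad_k(toy_map):
    with pytest.raises(ValueError):
        simulate_pair_matrix((0.5, 0.2, 0.2), 100, toy_map,
                             np.random.default_rng(0))
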