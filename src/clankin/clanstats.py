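"""Cemetery-level social-structure statistics.

Association of maternal lineages with cemeteries (permutation test on the
modal-matriline statistic), intra- versus inter-cemetery relatedness
(Welch t on cumulative IBD plus a label-permutation test), a Mantel test of
burial distance against genetic distance within a cemetery, and community
endogamy summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def modal_lineage_fraction(labels) -> float:
    """Fraction of individuals carrying the modal lineage label."""
    s = pd.Series(list(labels))
    if len(s) == 0:
        raise ValueError("no labels")
    return float(s.value_counts().iloc[0] / len(s))


@dataclass
class PairGroups:
    pairs: pd.DataFrame         # id1, id2, group ("intra-<cem>" or "inter")
    intra_counts: dict          # cemetery -> C(n, 2)
    n_inter: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pair_groups(table: pd.DataFrame) -> PairGroups:
    """Label every unordered pair of individuals intra-/inter-cemetery.

    ``table`` needs columns id and cemetery with unique ids.
    """
    if table["id"].duplicated().any():
        raise ValueError("duplicate individual ids")
    cem = dict(zip(table["id"], table["cemetery"]))
    if any(pd.isna(c) for c in cem.values()):
        raise ValueError("unknown cemetery label")
    ids = list(table["id"])
    rows = []
    for a, b in itertools.combinations(ids, 2):
        group = f"intra-{cem[a]}" if cem[a] == cem[b] else "inter"
        rows.append((a, b, group))
    pairs = pd.DataFrame(rows, columns=["id1", "id2", "group"])
    sizes = table["cemetery"].value_counts()
    intra = {c: int(n * (n - 1) // 2) for c, n in sizes.items()}
    n_inter = len(pairs) - sum(intra.values())
    return PairGroups(pairs=pairs, intra_counts=intra, n_inter=n_inter)


@dataclass
class AssociationTest:
    observed: int               # individuals matching their cemetery's modal matriline
    n: int
    p_value: float
    n_permutations: int
    seed: int


def _modal_match_stat(cemetery: np.ndarray, matriline: np.ndarray) -> int:
    stat = 0
    for c in np.unique(cemetery):
        sub = matriline[cemetery == c]
        _, counts = np.unique(sub, return_counts=True)
        stat += int(counts.max())
    return stat


def test_lineage_association(table: pd.DataFrame, n_perm: int = 9999,
                             seed: int = 0) -> AssociationTest:
    """Permutation test of matriline-cemetery correspondence.

    Statistic: number of individuals whose matriline is the modal matriline
    of their own cemetery.  The null shuffles cemetery labels over
    individuals; p uses +1 smoothing.
    """
    cemetery = table["cemetery"].to_numpy()
    matriline = table["matriline"].to_numpy()
    if len(np.unique(cemetery)) < 2:
        raise ValueError("association test needs at least two cemeteries")
    rng = np.random.default_rng(seed)
    obs = _modal_match_stat(cemetery, matriline)
    hits = 0
    for _ in range(n_perm):
        if _modal_match_stat(rng.permutation(cemetery), matriline) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AssociationTest(observed=obs, n=len(table), p_value=p,
                           n_permutations=n_perm, seed=seed)


@dataclass
class IntraInterComparison:
    group_values: dict          # group label -> np.ndarray of cumulative IBD
    mean_intra: float
    mean_inter: float
    t_statistic: float          # Welch, intra pooled vs inter (NaN if undefined)
    t_p_value: float
    permutation_p: float
    n_permutations: int
    seed: int
    note: str = ("Welch t treats pairs as independent and is anti-conservative "
                 "for pair data; the permutation p is the headline number.")


def compare_intra_inter(table: pd.DataFrame, ibd_cumulative: dict,
                        n_perm: int = 9999, seed: int = 0
                        ) -> IntraInterComparison:
    """Compare cumulative pairwise IBD within versus between cemeteries.

    ``ibd_cumulative`` maps unordered id pairs (tuple, either order) to
    cumulative IBD in cM; absent pairs count as 0.  The permutation null
    shuffles individual cemetery labels (preserving the pair dependence
    structure) and recomputes the intra-minus-inter mean difference;
    p is two-sided with +1 smoothing.
    """
    ids = list(table["id"])
    cemetery = table["cemetery"].to_numpy()
    n = len(ids)
    vals = np.zeros((n, n))
    for (a, b), v in ibd_cumulative.items():
        if a in ids and b in ids:
            i, j = ids.index(a), ids.index(b)
            vals[i, j] = vals[j, i] = v
    iu = np.triu_indices(n, k=1)
    flat = vals[iu]

    def mean_diff(cem):
        intra = cem[iu[0]] == cem[iu[1]]
        if intra.all() or (~intra).all():
            return np.nan, intra
        return float(flat[intra].mean() - flat[~intra].mean()), intra

    obs_diff, intra_mask = mean_diff(cemetery)
    groups = {}
    for c in np.unique(cemetery):
        m = (cemetery[iu[0]] == c) & (cemetery[iu[1]] == c)
        groups[f"intra-{c}"] = flat[m]
    groups["inter"] = flat[~intra_mask]

    intra_vals = flat[intra_mask]
    inter_vals = flat[~intra_mask]
    if len(intra_vals) >= 2 and len(inter_vals) >= 2:
        t, tp = stats.ttest_ind(intra_vals, inter_vals, equal_var=False)
        t, tp = float(t), float(tp)
    else:
        t, tp = float("nan"), float("nan")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        d, _ = mean_diff(rng.permutation(cemetery))
        if not np.isnan(d) and abs(d) >= abs(obs_diff) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return IntraInterComparison(
        group_values=groups,
        mean_intra=float(intra_vals.mean()) if len(intra_vals) else float("nan"),
        mean_inter=float(inter_vals.mean()) if len(inter_vals) else float("nan"),
        t_statistic=t, t_p_value=tp, permutation_p=p,
        n_permutations=n_perm, seed=seed)


@dataclass
class MantelResult:
    r: float                    # NaN when degenerate
    p_value: float
    n_permutations: int
    n_individuals: int
    degenerate: bool
    seed: int


def mantel_burial(coords: pd.DataFrame, genetic_distance: np.ndarray,
                  n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """Mantel test of burial distance against genetic distance.

    ``coords`` needs columns id, x, y for one cemetery's individuals;
    ``genetic_distance`` is the matching square distance matrix.  Rows and
    columns are permuted jointly; p is one-sided on |r| with +1 smoothing.
    Constant coordinates or distances give an explicit degenerate result.
    """
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals with coordinates")
    if genetic_distance.shape != (n, n):
        raise ValueError("genetic distance matrix does not match coordinates")
    spatial = np.hypot(xy[:, 0, None] - xy[None, :, 0],
                       xy[:, 1, None] - xy[None, :, 1])
    iu = np.triu_indices(n, k=1)
    s, g = spatial[iu], genetic_distance[iu]
    if np.std(s) == 0 or np.std(g) == 0:
        return MantelResult(r=float("nan"), p_value=float("nan"),
                            n_permutations=n_perm, n_individuals=n,
                            degenerate=True, seed=seed)
    r_obs = float(np.corrcoef(s, g)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = genetic_distance[np.ix_(perm, perm)][iu]
        if abs(float(np.corrcoef(s, gp)[0, 1])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm,
                        n_individuals=n, degenerate=False, seed=seed)


@dataclass
class EndogamyReport:
    frac_pairs_over_100cM: float
    median_cumulative_cM: float
    frac_short_roh_over_40cM: float  # individuals with > 40 cM of < 8 cM ROH
    n_consanguineous: int
    n_pairs: int
    n_individuals: int


def endogamy_report(ibd_summaries, roh_bins) -> EndogamyReport:
    """Community endogamy summary from pairwise IBD and per-individual ROH.

    ``ibd_summaries`` is an iterable of objects with ``cumulative_cM``
    (absent sharing should be present as zero-valued entries);
    ``roh_bins`` is a :class:`clankin.rohne.RohBins` over the community.
    """
    cums = np.array([s.cumulative_cM for s in ibd_summaries], dtype=float)
    frac100 = float((cums > 100.0).mean()) if len(cums) else 0.0
    median = float(np.median(cums)) if len(cums) else 0.0
    edges = np.asarray(roh_bins.edges_cM)
    short_cols = np.flatnonzero(edges[1:] <= 8.0)
    short_sum = roh_bins.sums_cM[:, short_cols].sum(axis=1)
    frac_short = (float((short_sum > 40.0).mean())
                  if len(roh_bins.individuals) else 0.0)
    return EndogamyReport(
        frac_pairs_over_100cM=frac100, median_cumulative_cM=median,
        frac_short_roh_over_40cM=frac_short,
        n_consanguineous=int(roh_bins.consanguineous.sum()),
        n_pairs=len(cums), n_individuals=len(roh_bins.individuals))
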