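"""Runs of homozygosity and effective population size.

A diploid's two haplotypes are followed along a chromosome: at any fixed
position the time to their most recent common ancestor (TMRCA) t is
exponential with mean 2 Ne generations, and recombination breakpoints
arrive at rate 2t per Morgan.  At each breakpoint the next tract's TMRCA is
redrawn independently from the size-biased marginal Gamma(2, 1/(2 Ne)) —
breakpoints fall preferentially into high-TMRCA regions — which keeps the
pointwise Exp marginal intact (a sequentially Markov, marginal-preserving
approximation that ignores TMRCA correlations across breakpoints).  ROH
tracts are the constant-TMRCA intervals between breakpoints.

The analytic companion is the marginal tract-length density per Morgan of
map, ``n(l) = 8 lam / (2 l + lam)^3`` with ``lam = 1/(2 Ne)`` and l in
Morgans; on a chromosome of length L the expected count of tracts with
length in [l1, l2) whose ends are both recombination events carries the
finite-length weight (L - l)+.  Ne is estimated by maximizing an
independent-Poisson likelihood of binned tract counts against these
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genmap import GeneticMapSpec

DEFAULT_BIN_EDGES_CM = (4.0, 8.0, 12.0, 20.0, np.inf)
#: sub-bins used for Ne fitting (reliable range 4-20 cM)
FIT_EDGES_CM = (4.0, 8.0, 12.0, 20.0)


@dataclass
class CoalParams:
    ne: float                   # diploid effective size
    gmap: GeneticMapSpec
    n_individuals: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class TractList:
    """Coalescent tracts for one diploid: per chromosome, arrays of
    (start_cM, end_cM, tmrca_generations).  Tracts partition [0, L_c)."""

    gmap: GeneticMapSpec
    tracts: list                # per chromosome: (starts, ends, tmrcas)

    def lengths_cm(self, interior_only: bool = False) -> np.ndarray:
        out = []
        for starts, ends, _ in self.tracts:
            lens = ends - starts
            if interior_only and len(lens) > 1:
                lens = lens[1:-1]
            elif interior_only:
                lens = lens[:0]
            out.append(lens)
        return np.concatenate(out) if out else np.array([])


def _chrom_tracts(L_morgans: float, ne: float, rng: np.random.Generator):
    """Tract boundaries and TMRCAs on one chromosome (lengths in Morgans).

    The tract covering the chromosome start (a fixed point) has the pointwise
    marginal TMRCA Exp(rate lam); tracts beginning at recombination
    breakpoints carry the size-biased marginal Gamma(2, rate lam), because
    breakpoints arrive at rate proportional to the local TMRCA.  This renewal
    construction preserves the Exp(lam) marginal at every position and yields
    the tract-count density n(l) = 8 lam / (2 l + lam)^3 exactly.
    """
    ts, lens = [], []
    pos = 0.0
    first = True
    # geometric batching keeps the loop vectorized
    batch = max(16, int(4 * ne * L_morgans * 1.3) + 16)
    while pos < L_morgans:
        t = rng.gamma(2.0, 2.0 * ne, size=batch)
        if first:
            t[0] = rng.exponential(2.0 * ne)
            first = False
        l = rng.exponential(1.0, size=batch) / (2.0 * t)
        cs = pos + np.cumsum(l)
        k = int(np.searchsorted(cs, L_morgans))
        ts.append(t[:k + 1])
        lens.append(l[:k + 1])
        if k < batch:
            pos = L_morgans
        else:
            pos = cs[-1]
    t = np.concatenate(ts)
    ends = np.minimum(np.cumsum(np.concatenate(lens)), L_morgans)
    starts = np.concatenate([[0.0], ends[:-1]])
    return starts, ends, t


def simulate_tracts(params: CoalParams,
                    rng: np.random.Generator | None = None):
    """Simulate ROH tracts for ``n_individuals`` independent diploids.

    Returns a list of :class:`TractList` (one per diploid).  Terminal tracts
    are truncated at chromosome ends; interior tracts are delimited by two
    recombination events on both sides.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    out = []
    for _ in range(params.n_individuals):
        per_chrom = []
        for L_cm in params.gmap.lengths_cM:
            s, e, t = _chrom_tracts(L_cm / 100.0, params.ne, rng)
            per_chrom.append((s * 100.0, e * 100.0, t))
        out.append(TractList(gmap=params.gmap, tracts=per_chrom))
    return out


def simulate_roh_cohort(params: CoalParams, edges_cm=FIT_EDGES_CM,
                        rng: np.random.Generator | None = None,
                        interior_only: bool = True,
                        chunk: int = 200) -> np.ndarray:
    """Per-individual binned tract counts without materializing tracts.

    Returns an array of shape (n_individuals, n_bins) with counts of tracts
    whose length falls in ``[edges_cm[i], edges_cm[i+1])``.  With
    ``interior_only`` (default) chromosome-end-truncated tracts are excluded,
    matching the (L - l)+ weighting of :func:`expected_tract_counts`.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    edges = np.asarray(edges_cm, dtype=float) / 100.0  # Morgans
    n_bins = len(edges) - 1
    counts = np.zeros((params.n_individuals, n_bins), dtype=np.int64)
    ne = params.ne
    for L_cm in params.gmap.lengths_cM:
        L = L_cm / 100.0
        mean_n = 4.0 * ne * L
        m = int(mean_n + 8.0 * np.sqrt(mean_n) + 20)
        for lo in range(0, params.n_individuals, chunk):
            hi = min(lo + chunk, params.n_individuals)
            nrow = hi - lo
            t = rng.gamma(2.0, 2.0 * ne, size=(nrow, m))
            t[:, 0] = rng.exponential(2.0 * ne, size=nrow)
            lens = rng.exponential(1.0, size=(nrow, m)) / (2.0 * t)
            cs = np.cumsum(lens, axis=1)
            # rows whose batch did not span the chromosome: finish one by one
            short = np.flatnonzero(cs[:, -1] < L)
            for r in short:
                s, e, _ = _chrom_tracts(L, ne, rng)
                ln = e - s
                if interior_only:
                    ln = ln[1:-1] if len(ln) > 1 else ln[:0]
                b = np.searchsorted(edges, ln, side="right") - 1
                ok = (b >= 0) & (b < n_bins) & (ln >= edges[0]) & (ln < edges[-1])
                np.add.at(counts[lo + r], b[ok], 1)
            mask = cs < L
            if interior_only:
                mask[:, 0] = False
            if len(short):
                mask[short, :] = False
            ln = lens[mask]
            rows = np.broadcast_to(np.arange(lo, hi)[:, None], mask.shape)[mask]
            b = np.searchsorted(edges, ln, side="right") - 1
            ok = (ln >= edges[0]) & (ln < edges[-1])
            np.add.at(counts, (rows[ok], b[ok]), 1)
    return counts


def expected_tract_counts(ne: float, edges_cm, gmap: GeneticMapSpec) -> np.ndarray:
    """Closed-form expected interior-tract counts per diploid genome per bin.

    Integrates n(l) (L - l)+ dl over each [l1, l2) bin and sums over
    chromosomes; the antiderivative of 8 lam (L - l) / (2 l + lam)^3 in
    u = 2 l + lam is 2 lam / u - lam (2 L + lam) / u^2.
    """
    edges = np.asarray(edges_cm, dtype=float) / 100.0
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lam = 1.0 / (2.0 * ne)

    def antideriv(l, L):
        u = 2.0 * l + lam
        return 2.0 * lam / u - lam * (2.0 * L + lam) / u ** 2

    out = np.zeros(len(edges) - 1)
    for L_cm in gmap.lengths_cM:
        L = L_cm / 100.0
        lo = np.minimum(edges[:-1], L)
        hi = np.minimum(edges[1:], L)
        out += antideriv(hi, L) - antideriv(lo, L)
    return out


def tract_density(l_morgans, ne: float) -> np.ndarray:
    """Marginal density n(l) of tract lengths per Morgan of map."""
    lam = 1.0 / (2.0 * ne)
    l = np.asarray(l_morgans, dtype=float)
    return 8.0 * lam / (2.0 * l + lam) ** 3


# ---------------------------------------------------------------------------
# ROH binning and the inbreeding filter
# ---------------------------------------------------------------------------

@dataclass
class InbreedingFilter:
    """Exclude individuals whose ROH segments longer than ``long_cM`` sum to
    more than ``threshold_cM``; flag close consanguinity above
    ``consanguinity_cM``."""

    long_cM: float = 20.0
    threshold_cM: float = 40.0
    consanguinity_cM: float = 100.0

    def __post_init__(self):
        if self.threshold_cM <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class RohBins:
    edges_cM: tuple
    individuals: list
    counts: np.ndarray          # (n_individuals, n_bins)
    sums_cM: np.ndarray         # (n_individuals, n_bins)
    max_segment_cM: np.ndarray
    excluded: np.ndarray        # bool, inbreeding filter
    consanguineous: np.ndarray  # bool, > consanguinity_cM of long ROH

    @property
    def retained(self) -> list:
        return [i for i, ex in zip(self.individuals, self.excluded) if not ex]


def bin_roh(segments: pd.DataFrame, edges_cm=DEFAULT_BIN_EDGES_CM,
            inbreeding_filter: InbreedingFilter | None = None) -> RohBins:
    """Bin per-individual ROH segments and apply the inbreeding exclusion.

    ``segments`` needs columns id, chrom, start_cM, end_cM with sorted,
    non-overlapping segments per (id, chrom).
    """
    filt = inbreeding_filter or InbreedingFilter()
    edges = np.asarray(edges_cm, dtype=float)
    individuals = sorted(segments["id"].unique()) if len(segments) else []
    n_bins = len(edges) - 1
    counts = np.zeros((len(individuals), n_bins), dtype=np.int64)
    sums = np.zeros((len(individuals), n_bins))
    max_seg = np.zeros(len(individuals))
    excluded = np.zeros(len(individuals), dtype=bool)
    consang = np.zeros(len(individuals), dtype=bool)

    for k, iid in enumerate(individuals):
        sub = segments[segments["id"] == iid]
        for _, chrom_sub in sub.groupby("chrom"):
            s = chrom_sub["start_cM"].to_numpy()
            e = chrom_sub["end_cM"].to_numpy()
            order = np.argsort(s)
            s, e = s[order], e[order]
            if np.any(e < s) or np.any(s[1:] < e[:-1]):
                raise ValueError(
                    f"unsorted or overlapping ROH segments for {iid}")
        lens = (sub["end_cM"] - sub["start_cM"]).to_numpy()
        b = np.searchsorted(edges, lens, side="right") - 1
        ok = (b >= 0) & (b < n_bins)
        np.add.at(counts[k], b[ok], 1)
        np.add.at(sums[k], b[ok], lens[ok])
        max_seg[k] = lens.max() if len(lens) else 0.0
        long_total = lens[lens > filt.long_cM].sum()
        excluded[k] = long_total > filt.threshold_cM
        consang[k] = long_total > filt.consanguinity_cM
    return RohBins(edges_cM=tuple(edges), individuals=individuals,
                   counts=counts, sums_cM=sums, max_segment_cM=max_seg,
                   excluded=excluded, consanguineous=consang)


# ---------------------------------------------------------------------------
# Ne maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    ne_mle: float
    ci_low: float
    ci_high: float              # inf when unbounded
    edges_cM: tuple
    n_individuals: int
    log_likelihood: float
    upper_unbounded: bool = False


def _poisson_loglik(ne, observed, n_ind, edges_cm, gmap):
    mu = n_ind * expected_tract_counts(ne, edges_cm, gmap)
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(observed * np.log(mu) - mu))


def estimate_ne(observed_counts, n_individuals: int, gmap: GeneticMapSpec,
                edges_cm=FIT_EDGES_CM, grid=(50.0, 20000.0, 80)) -> NeEstimate:
    """Poisson MLE of Ne from binned tract counts.

    ``observed_counts`` are total counts over individuals per fitting bin.
    The likelihood is maximized on a log-spaced grid then refined by bounded
    scalar optimization; the 95% CI is the profile region with log-likelihood
    within 1.92 of the maximum.  With all-zero counts the MLE runs to the
    upper bound and the CI upper limit is reported as unbounded.
    """
    observed = np.asarray(observed_counts, dtype=float)
    if len(observed) != len(edges_cm) - 1:
        raise ValueError("observed counts do not match fitting bins")
    lo, hi, n_grid = grid
    ne_grid = np.geomspace(lo, hi, int(n_grid))
    ll = np.array([_poisson_loglik(ne, observed, n_individuals, edges_cm, gmap)
                   for ne in ne_grid])
    i = int(np.argmax(ll))
    a = ne_grid[max(i - 1, 0)]
    b = ne_grid[min(i + 1, len(ne_grid) - 1)]
    res = minimize_scalar(
        lambda x: -_poisson_loglik(np.exp(x), observed, n_individuals,
                                   edges_cm, gmap),
        bounds=(np.log(a), np.log(b)), method="bounded",
        options={"xatol": 1e-6})
    ne_mle = float(np.exp(res.x))
    ll_max = -float(res.fun)

    fine = np.geomspace(lo, hi, 2000)
    ll_fine = np.array([_poisson_loglik(ne, observed, n_individuals,
                                        edges_cm, gmap) for ne in fine])
    inside = ll_fine >= ll_max - 1.92
    if not inside.any():
        inside[np.argmax(ll_fine)] = True
    ci_low = float(fine[inside][0])
    ci_high = float(fine[inside][-1])
    upper_unbounded = bool(inside[-1]) or observed.sum() == 0
    if observed.sum() == 0:
        ne_mle = float("inf")
        ci_high = float("inf")
    elif upper_unbounded:
        ci_high = float("inf")
    return NeEstimate(ne_mle=ne_mle, ci_low=ci_low, ci_high=ci_high,
                      edges_cM=tuple(edges_cm), n_individuals=n_individuals,
                      log_likelihood=ll_max, upper_unbounded=upper_unbounded)


def estimate_ne_from_bins(bins: RohBins, gmap: GeneticMapSpec,
                          edges_cm=FIT_EDGES_CM) -> NeEstimate:
    """Fit Ne from :func:`bin_roh` output, using retained individuals and the
    4-20 cM fitting sub-bins recomputed from the per-bin sums."""
    keep = ~bins.excluded
    # recount retained individuals' segments into the fitting bins
    sub_edges = np.asarray(edges_cm)
    col = [np.flatnonzero((np.asarray(bins.edges_cM[:-1]) >= sub_edges[i])
                          & (np.asarray(bins.edges_cM[1:]) <= sub_edges[i + 1]))
           for i in range(len(sub_edges) - 1)]
    observed = np.array([bins.counts[keep][:, c].sum() for c in col])
    return estimate_ne(observed, int(keep.sum()), gmap, edges_cm=edges_cm)
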