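"""Pairwise relatedness from pseudo-haploid genotypes.

Three complementary views, all driven by the windowed mismatch proportion P0
(fraction of non-matching single-allele calls among sites where both
individuals are called):

* mismatch-based degree classes with median normalization and the cutoffs
  0.625 / 0.8125 / 0.90625 (midpoints of the expected normalized P0 of
  identical, first- and second-degree pairs under pseudo-haploid sampling);
* a windowed (k0, k1, k2) relationship-model likelihood that separates
  same-degree relationships (e.g. siblings from parent-child) through the
  window-level mixture they induce;
* IBD segment-list summaries (cumulative length, count, longest, >100 cM
  flag).

Under pseudo-haploid sampling the expected normalized P0 of a pair with
IBD-state genome fractions (k0, k1, k2) is ``1 - k1/4 - k2/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .community import MISSING, PseudoHaploidMatrix

#: normalized P0 upper cutoffs, strict less-than
CUTOFF_IDENTICAL = 0.625
CUTOFF_FIRST = 0.8125
CUTOFF_SECOND = 0.90625

CLASS_LABELS = ("IDENTICAL", "FIRST", "SECOND", "UNRELATED")


@dataclass(frozen=True)
class RelationshipModel:
    """Named (k0, k1, k2) genome-fraction vector over IBD states 0/1/2."""

    name: str
    k: tuple

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        if len(k) != 3 or (k < 0).any() or abs(k.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid k-vector for {self.name}: {self.k}")


DEFAULT_MODELS = (
    RelationshipModel("unrelated", (1.0, 0.0, 0.0)),
    RelationshipModel("third_degree", (0.75, 0.25, 0.0)),
    RelationshipModel("second_degree", (0.5, 0.5, 0.0)),
    RelationshipModel("parent_child", (0.0, 1.0, 0.0)),
    RelationshipModel("sibling", (0.25, 0.5, 0.25)),
    RelationshipModel("identical", (0.0, 0.0, 1.0)),
)


@dataclass
class WindowGrid:
    """Non-overlapping fixed-physical-span windows tiling each chromosome."""

    window_bp: int
    keys: list                  # (chrom, window_start_bp) per window
    site_window: np.ndarray     # window index per site

    @property
    def n_windows(self) -> int:
        return len(self.keys)


def build_window_grid(sites: pd.DataFrame, window_bp: int = 1_000_000) -> WindowGrid:
    keys = []
    idx = np.empty(len(sites), dtype=np.int64)
    offset = 0
    for chrom, sub in sites.groupby("chrom", sort=False):
        w = (sub["bp"].to_numpy() // window_bp).astype(np.int64)
        uniq, local = np.unique(w, return_inverse=True)
        idx[sub.index.to_numpy()] = offset + local
        keys.extend((chrom, int(u) * window_bp) for u in uniq)
        offset += len(uniq)
    return WindowGrid(window_bp=window_bp, keys=keys, site_window=idx)


@dataclass
class PairwiseMismatch:
    id1: str
    id2: str
    p0: np.ndarray              # per-window P0, NaN where overlap < min_overlap
    overlap: np.ndarray         # per-window jointly-called site count
    retained: np.ndarray        # bool mask of windows entering the mean
    mean_p0: float              # unweighted mean over retained windows (NaN if none)
    min_overlap: int

    @property
    def insufficient(self) -> bool:
        return not bool(self.retained.any())

    @property
    def n_windows(self) -> int:
        return int(self.retained.sum())


def compute_p0(matrix: PseudoHaploidMatrix, pair, grid: WindowGrid,
               min_overlap: int = 20) -> PairwiseMismatch:
    """Windowed mismatch proportion for one pair.

    Windows with fewer than ``min_overlap`` jointly-called sites are dropped
    from the unweighted mean; a pair with no retained window is flagged
    insufficient and excluded downstream.
    """
    id1, id2 = pair
    ca = matrix.column(id1)
    cb = matrix.column(id2)
    called = (ca != MISSING) & (cb != MISSING)
    mism = called & (ca != cb)
    overlap = np.bincount(grid.site_window[called], minlength=grid.n_windows)
    mcount = np.bincount(grid.site_window[mism], minlength=grid.n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(overlap > 0, mcount / np.maximum(overlap, 1), np.nan)
    retained = overlap >= min_overlap
    p0 = np.where(retained, p0, np.nan)
    mean = float(np.nanmean(p0[retained])) if retained.any() else float("nan")
    return PairwiseMismatch(id1=id1, id2=id2, p0=p0, overlap=overlap,
                            retained=retained, mean_p0=mean,
                            min_overlap=min_overlap)


def all_pairwise_p0(matrix: PseudoHaploidMatrix, grid: WindowGrid | None = None,
                    ids=None, min_overlap: int = 20):
    """``compute_p0`` over all unordered pairs of ``ids`` (default: all)."""
    grid = grid or build_window_grid(matrix.sites)
    ids = list(ids) if ids is not None else list(matrix.ids)
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            out.append(compute_p0(matrix, (ids[a], ids[b]), grid, min_overlap))
    return out


@dataclass
class ReadClassification:
    id1: str
    id2: str
    mean_p0: float
    baseline: float
    normalized_p0: float
    degree_class: str
    absolute_cutoffs: dict = field(default_factory=dict)


def absolute_cutoffs(baseline: float) -> dict:
    """Non-normalized P0 cutoffs implied by a cohort baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return {"identical": CUTOFF_IDENTICAL * baseline,
            "first": CUTOFF_FIRST * baseline,
            "second": CUTOFF_SECOND * baseline}


def classify_normalized(normalized: float) -> str:
    if normalized < CUTOFF_IDENTICAL:
        return "IDENTICAL"
    if normalized < CUTOFF_FIRST:
        return "FIRST"
    if normalized < CUTOFF_SECOND:
        return "SECOND"
    return "UNRELATED"


def read_classify(mismatches, baseline: float | None = None):
    """Degree classes from mean P0 with median normalization.

    The baseline defaults to the median of mean P0 across all supplied pairs,
    assumed to represent unrelated individuals — a biased assumption in
    heavily related cohorts, hence the override argument.  Returns
    ``(classifications, baseline)``; insufficient-overlap pairs are skipped.
    """
    usable = [m for m in mismatches if not m.insufficient]
    if not usable:
        raise ValueError("no pair with sufficient window overlap")
    if baseline is None:
        baseline = float(np.median([m.mean_p0 for m in usable]))
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    cuts = absolute_cutoffs(baseline)
    out = []
    for m in usable:
        norm = m.mean_p0 / baseline
        out.append(ReadClassification(
            id1=m.id1, id2=m.id2, mean_p0=m.mean_p0, baseline=baseline,
            normalized_p0=norm, degree_class=classify_normalized(norm),
            absolute_cutoffs=cuts))
    return out, baseline


@dataclass
class KinLikelihoodResult:
    id1: str
    id2: str
    log_likelihoods: dict       # model name -> summed window log-likelihood
    best_model: str
    log_lr_vs_unrelated: float
    reliable: bool              # log-LR > 1.0 and enough windows
    n_windows: int


def kin_classify(mismatch: PairwiseMismatch, baseline: float,
                 models=DEFAULT_MODELS, error_spread: float = 1.5,
                 min_windows: int = 20) -> KinLikelihoodResult:
    """Windowed (k0, k1, k2) mixture likelihood over relationship models.

    Per retained window the observed P0 is modelled as a normal mixture over
    IBD states with weights (k0, k1, k2), state means (b, 0.75 b, 0.5 b) for
    baseline b, and binomial variance m(1-m)/n inflated by ``error_spread``.
    The best model maximizes the summed log-likelihood; results are reliable
    when the log-likelihood ratio against the unrelated model exceeds 1.0.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    keep = mismatch.retained
    x = mismatch.p0[keep]
    n = mismatch.overlap[keep].astype(float)
    state_means = baseline * np.array([1.0, 0.75, 0.5])
    var = error_spread * state_means * (1.0 - state_means) / n[:, None]
    var = np.maximum(var, 1e-12)
    # log N(x; m_s, v_s) per window per state
    log_norm = (-0.5 * np.log(2.0 * np.pi * var)
                - 0.5 * (x[:, None] - state_means[None, :]) ** 2 / var)

    loglik = {}
    for model in models:
        k = np.asarray(model.k, dtype=float)
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(np.maximum(k, 1e-300)), -np.inf)
        loglik[model.name] = float(np.sum(logsumexp(log_norm + logk[None, :],
                                                    axis=1)))
    best = max(loglik, key=loglik.get)
    lr = loglik[best] - loglik["unrelated"]
    enough = len(x) >= min_windows
    return KinLikelihoodResult(
        id1=mismatch.id1, id2=mismatch.id2, log_likelihoods=loglik,
        best_model=best, log_lr_vs_unrelated=lr,
        reliable=bool(lr > 1.0 and enough), n_windows=len(x))


@dataclass
class IbdSummary:
    id1: str
    id2: str
    min_len_cM: float
    cumulative_cM: float
    n_segments: int
    longest_cM: float
    over_100cM: bool


def ibd_summarize(segments, min_len_cM: float = 12.0,
                  pair=("", "")) -> IbdSummary:
    """Cumulative length / count / longest of a pair's IBD segments at or
    above ``min_len_cM``; flags cumulative sharing above 100 cM.

    ``segments`` is an iterable of (start_cM, end_cM) or
    (chrom, start_cM, end_cM[, state]) records.
    """
    lengths = []
    for seg in segments:
        if len(seg) == 2:
            s, e = seg
        else:
            s, e = seg[1], seg[2]
        if e < s:
            raise ValueError(f"negative-length segment: {seg}")
        lengths.append(e - s)
    lengths = np.asarray([l for l in lengths if l >= min_len_cM], dtype=float)
    cum = float(lengths.sum())
    return IbdSummary(id1=pair[0], id2=pair[1], min_len_cM=min_len_cM,
                      cumulative_cM=cum, n_segments=int(len(lengths)),
                      longest_cM=float(lengths.max()) if len(lengths) else 0.0,
                      over_100cM=bool(cum > 100.0))
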