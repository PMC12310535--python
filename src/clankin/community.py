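"""Synthetic matrilineal two-clan community generator.

Simulates a pedigree with configurable descent/burial rules and community
endogamy, gene-drops founder haplotypes through it along a genetic map, and
derives exact truth tables (pairwise pedigree degrees, IBD segments, ROH
segments, uniparental lineages) so that every downstream inference stage can
be validated against known ground truth.

Model sketch
------------
Generation 0 consists of founding mothers, split between ``n_clans``
matrilineal clans; all founding mothers of a clan share an mtDNA lineage but
carry unrelated autosomal founder haplotypes.  Each subsequent generation is
produced through the community's women: a mother takes an internal husband
(same generation, full-sib unions avoided, other-clan preferred) with
probability ``endogamy_prob``, otherwise an external male founder who brings
two fresh haplotypes and a fresh Y lineage.  Children inherit their mother's
matriline and mt lineage, and sons their father's Y lineage.  Burial
(cemetery) labels follow ``burial_rule``.

Recombination is a Poisson process on the genetic axis (no interference):
crossover count per meiosis ~ Poisson(map length in Morgans), breakpoints
uniform in cM.  All coordinates are half-open ``[start, end)`` cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMapSpec

MISSING = -1          # in-memory pseudo-haploid missing call
UNRELATED_DEGREE = -1  # pedigree degree code for "beyond 6th degree"
MT_LENGTH = 16_569     # positions on the circular mtDNA reference

BURIAL_RULES = ("matriclan", "patriclan", "random")


class MatingPoolError(RuntimeError):
    """No eligible internal mate exists and endogamy_prob forces one."""


@dataclass
class SimConfig:
    """Scenario knobs for the community generator.

    Defaults describe a small, strongly endogamous two-clan community with
    matriclan burial, the social structure the downstream pipeline is built
    to detect.
    """

    n_clans: int = 2
    founders_per_clan: int = 5
    generations: int = 4
    endogamy_prob: float = 0.8
    burial_rule: str = "matriclan"
    offspring_mean: float = 2.4
    mt_mut_prob: float = 0.005
    n_sites: int = 50_000
    missing_rate: float = 0.5
    error_rate: float = 0.005
    seed: int = 0
    # secondary knobs
    avoid_full_sib: bool = True
    clan_exogamy: bool = True
    clan_mt_divergence: int = 6
    max_generation_size: int | None = None  # cap via random child subsampling
    freq_lo: float = 0.05
    freq_hi: float = 0.95

    def __post_init__(self):
        for name in ("endogamy_prob", "mt_mut_prob", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_clans < 1 or self.founders_per_clan < 1:
            raise ValueError("need at least one clan and one founder per clan")
        if self.offspring_mean <= 0:
            raise ValueError("offspring_mean must be positive")
        if self.burial_rule not in BURIAL_RULES:
            raise ValueError(f"burial_rule must be one of {BURIAL_RULES}")


@dataclass
class Individual:
    id: str
    sex: str                    # "M" or "F"
    mother_id: str | None       # None for founders
    father_id: str | None
    generation: int
    matriline: str
    patriline: str
    mt_lineage: str
    y_lineage: str | None       # males only
    cemetery: str | None = None  # internal individuals only
    external: bool = False
    coords: tuple | None = None  # burial coordinates (x, y) in metres


@dataclass
class ChromTiling:
    """One haplotype on one chromosome as ordered founder-haplotype tiles.

    ``breaks`` has length ``len(ids) + 1``, starts at 0 and ends at the
    chromosome's genetic length; tile ``i`` spans ``[breaks[i], breaks[i+1])``
    and carries founder haplotype ``ids[i]``.
    """

    breaks: np.ndarray
    ids: np.ndarray

    def id_at(self, cm) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.breaks, cm, side="right") - 1,
                      0, len(self.ids) - 1)
        return self.ids[idx]


@dataclass
class Community:
    config: SimConfig
    gmap: GeneticMapSpec
    individuals: list            # internal members, generation order
    externals: list              # external founders (spouses)
    tilings: dict = field(default_factory=dict)  # id -> [ (ChromTiling, ChromTiling) per chrom ]
    mt_mutations: dict = field(default_factory=dict)  # id -> frozenset of positions
    n_founder_haps: int = 0

    @property
    def by_id(self) -> dict:
        return {ind.id: ind for ind in self.individuals + self.externals}

    @property
    def ids(self) -> list:
        return [ind.id for ind in self.individuals]

    def roster(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            rows.append({
                "id": ind.id, "sex": ind.sex,
                "mother_id": ind.mother_id or "EXTERNAL_FOUNDER",
                "father_id": ind.father_id or "EXTERNAL_FOUNDER",
                "generation": ind.generation,
                "matriline": ind.matriline, "patriline": ind.patriline,
                "mt_lineage": ind.mt_lineage,
                "y_lineage": ind.y_lineage if ind.y_lineage else "",
                "cemetery": ind.cemetery,
                "x": ind.coords[0] if ind.coords else np.nan,
                "y": ind.coords[1] if ind.coords else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class TruthTables:
    """Ground truth for downstream validation.

    ``pairs``: id1, id2, degree (0=self/identical, 1..6, -1=unrelated) and,
    where IBD was derived, realized genome fractions k0/k1/k2.
    ``ibd``: id1, id2, chrom, start_cM, end_cM, state ("IBD1"/"IBD2").
    ``roh``: id, chrom, start_cM, end_cM.
    """

    pairs: pd.DataFrame
    ibd: pd.DataFrame
    roh: pd.DataFrame


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------

def _clan_labels(n: int) -> list:
    return ["N", "S"] if n == 2 else [f"C{i+1}" for i in range(n)]


def _build_pedigree(config: SimConfig, rng: np.random.Generator):
    clans = _clan_labels(config.n_clans)
    internal, external = [], []
    counter = {"I": 0, "X": 0, "Y": 0}

    def new_id(kind):
        counter[kind] += 1
        return f"{kind}{counter[kind]:04d}"

    for clan in clans:
        for _ in range(config.founders_per_clan):
            iid = new_id("I")
            internal.append(Individual(
                id=iid, sex="F", mother_id=None, father_id=None, generation=0,
                matriline=clan, patriline=f"P-{iid}", mt_lineage=clan,
                y_lineage=None))

    for g in range(1, config.generations + 1):
        mothers = [i for i in internal if i.sex == "F" and i.generation == g - 1]
        if not mothers and config.endogamy_prob >= 1.0:
            raise MatingPoolError(
                f"generation {g}: no mothers left and endogamy_prob = 1")
        pool = [i for i in internal if i.sex == "M" and i.generation == g - 1]
        unmarried = list(pool)
        children = []
        for mother in mothers:
            def eligible_from(cands):
                out = [m for m in cands
                       if not (config.avoid_full_sib
                               and m.mother_id is not None
                               and m.mother_id == mother.mother_id
                               and m.father_id == mother.father_id)]
                if config.clan_exogamy:
                    cross = [m for m in out if m.matriline != mother.matriline]
                    if cross:
                        return cross
                return out

            eligible = eligible_from(unmarried)
            # generation 0 holds founding mothers only, so the first
            # generation of fathers is external by necessity
            internal_mate = (g > 1
                             and bool(rng.random() < config.endogamy_prob))
            if internal_mate and not eligible:
                # monogamy preferred; polygyny fallback before giving up
                eligible = eligible_from(pool)
            if internal_mate and eligible:
                father = eligible[int(rng.integers(len(eligible)))]
                if father in unmarried:
                    unmarried.remove(father)
            elif internal_mate and config.endogamy_prob >= 1.0:
                raise MatingPoolError(
                    f"generation {g}: no eligible internal mate for {mother.id} "
                    "with endogamy_prob = 1")
            else:
                xid = new_id("X")
                father = Individual(
                    id=xid, sex="M", mother_id=None, father_id=None,
                    generation=g - 1, matriline=f"EXT-{xid}",
                    patriline=f"P-{xid}", mt_lineage=f"EXT-{xid}",
                    y_lineage=f"Y-{xid}", external=True)
                external.append(father)
            n_child = int(rng.poisson(config.offspring_mean))
            for _ in range(n_child):
                sex = "F" if rng.random() < 0.5 else "M"
                children.append(Individual(
                    id=new_id("I"), sex=sex, mother_id=mother.id,
                    father_id=father.id, generation=g,
                    matriline=mother.matriline, patriline=father.patriline,
                    mt_lineage=mother.mt_lineage,
                    y_lineage=father.y_lineage if sex == "M" else None))
        cap = config.max_generation_size
        if cap is not None and len(children) > cap:
            keep = sorted(rng.choice(len(children), size=cap, replace=False))
            children = [children[i] for i in keep]
        internal.extend(children)

    _assign_burials(internal, clans, config, rng)
    return internal, external


def _assign_burials(internal, clans, config: SimConfig, rng):
    for ind in internal:
        if config.burial_rule == "matriclan":
            ind.cemetery = ind.matriline
        elif config.burial_rule == "patriclan":
            ind.cemetery = ind.patriline
        else:
            ind.cemetery = clans[int(rng.integers(len(clans)))]
    centers = {}
    for ind in internal:
        if ind.cemetery not in centers:
            centers[ind.cemetery] = (40.0 * len(centers), 0.0)
    for ind in internal:
        cx, cy = centers[ind.cemetery]
        dx, dy = rng.normal(0.0, 4.0, size=2)
        ind.coords = (cx + dx, cy + dy)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _founder_tiling(gmap: GeneticMapSpec, hap_id: int):
    return [ChromTiling(np.array([0.0, L]), np.array([hap_id], dtype=np.int64))
            for L in gmap.lengths_cM]


def _slice_tiles(tiling: ChromTiling, lo: float, hi: float):
    """Tiles of ``tiling`` restricted to [lo, hi)."""
    b, ids = tiling.breaks, tiling.ids
    i = np.searchsorted(b, lo, side="right") - 1
    j = np.searchsorted(b, hi, side="left")
    sub_b = np.concatenate([[lo], b[i + 1:j], [hi]])
    sub_ids = ids[i:j]
    return sub_b, sub_ids


def _merge_tiles(parts, L: float) -> ChromTiling:
    breaks = [0.0]
    ids = []
    for sub_b, sub_ids in parts:
        for k in range(len(sub_ids)):
            s, e = sub_b[k], sub_b[k + 1]
            if e <= s:
                continue  # zero-length guard (coincident breakpoints)
            if ids and ids[-1] == sub_ids[k]:
                breaks[-1] = e
            else:
                breaks.append(e)
                ids.append(sub_ids[k])
    breaks[-1] = L
    return ChromTiling(np.asarray(breaks, dtype=float),
                       np.asarray(ids, dtype=np.int64))


def meiosis(parent_tiling, gmap: GeneticMapSpec, rng: np.random.Generator):
    """One gamete: per chromosome, a Poisson-crossover mosaic of the parent's
    two haplotypes."""
    gamete = []
    for c, L in enumerate(gmap.lengths_cM):
        k = int(rng.poisson(L / 100.0))
        cuts = np.sort(rng.uniform(0.0, L, size=k))
        start = int(rng.integers(2))
        bounds = np.concatenate([[0.0], cuts, [L]])
        parts = []
        for s in range(len(bounds) - 1):
            source = parent_tiling[c][(start + s) % 2]
            parts.append(_slice_tiles(source, bounds[s], bounds[s + 1]))
        gamete.append(_merge_tiles(parts, L))
    return gamete


def gene_drop(community: Community, rng: np.random.Generator) -> None:
    """Assign founder haplotypes and drop them through the pedigree.

    Fills ``community.tilings`` (two ChromTilings per chromosome per
    individual) and ``community.n_founder_haps``.
    """
    gmap = community.gmap
    hap = 0
    founders = ([i for i in community.individuals if i.generation == 0]
                + community.externals)
    for f in sorted(founders, key=lambda i: i.id):
        community.tilings[f.id] = [
            (_founder_tiling(gmap, hap)[c], _founder_tiling(gmap, hap + 1)[c])
            for c in range(gmap.n_chrom)]
        hap += 2
    community.n_founder_haps = hap

    for ind in community.individuals:
        if ind.generation == 0:
            continue
        mat = meiosis([t for t in community.tilings[ind.mother_id]], gmap, rng)
        pat = meiosis([t for t in community.tilings[ind.father_id]], gmap, rng)
        community.tilings[ind.id] = list(zip(mat, pat))


# ---------------------------------------------------------------------------
# truth IBD / ROH
# ---------------------------------------------------------------------------

def _segments_from_states(bounds, states):
    """Merge adjacent equal-state elementary intervals; drop state 0."""
    out = []
    cur_s, cur_lo = None, None
    for k in range(len(states)):
        s = states[k]
        if s == cur_s:
            continue
        if cur_s not in (None, 0):
            out.append((cur_lo, bounds[k], cur_s))
        cur_s, cur_lo = s, bounds[k]
    if cur_s not in (None, 0):
        out.append((cur_lo, bounds[-1], cur_s))
    return out


def derive_true_ibd(community: Community, id_a: str, id_b: str):
    """Maximal intervals where the pair shares founder haplotypes.

    State "IBD2" where the two diploids match haplotype-for-haplotype,
    "IBD1" where exactly one founder haplotype is shared.  Returns a list of
    (chrom_id, start_cM, end_cM, state).
    """
    for i in (id_a, id_b):
        if i not in community.tilings:
            raise KeyError(f"unknown or untiled individual: {i}")
    gmap = community.gmap
    out = []
    for c, chrom in enumerate(gmap.chrom_ids):
        a1, a2 = community.tilings[id_a][c]
        b1, b2 = community.tilings[id_b][c]
        bounds = np.unique(np.concatenate(
            [a1.breaks, a2.breaks, b1.breaks, b2.breaks]))
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        va1, va2 = a1.id_at(mids), a2.id_at(mids)
        vb1, vb2 = b1.id_at(mids), b2.id_at(mids)
        ibd2 = ((va1 == vb1) & (va2 == vb2)) | ((va1 == vb2) & (va2 == vb1))
        share = ((va1 == vb1) | (va1 == vb2) | (va2 == vb1) | (va2 == vb2))
        states = np.where(ibd2, 2, np.where(share, 1, 0))
        for lo, hi, s in _segments_from_states(bounds, states):
            out.append((chrom, float(lo), float(hi), f"IBD{s}"))
    return out


def derive_true_roh(community: Community, ind_id: str):
    """Maximal intervals where an individual's two haplotypes share a founder
    haplotype; (chrom_id, start_cM, end_cM) tuples."""
    if ind_id not in community.tilings:
        raise KeyError(f"unknown or untiled individual: {ind_id}")
    gmap = community.gmap
    out = []
    for c, chrom in enumerate(gmap.chrom_ids):
        h1, h2 = community.tilings[ind_id][c]
        bounds = np.unique(np.concatenate([h1.breaks, h2.breaks]))
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        states = (h1.id_at(mids) == h2.id_at(mids)).astype(int)
        for lo, hi, _ in _segments_from_states(bounds, states):
            out.append((chrom, float(lo), float(hi)))
    return out


# ---------------------------------------------------------------------------
# pedigree kinship coefficients and degrees
# ---------------------------------------------------------------------------

def kinship_coefficients(community: Community) -> dict:
    """Recursive pedigree kinship coefficient phi for all internal pairs."""
    parents = {}
    gen = {}
    for ind in community.individuals + community.externals:
        parents[ind.id] = (ind.mother_id, ind.father_id)
        gen[ind.id] = ind.generation
    memo = {}

    def phi(i, j):
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            m, f = parents[i]
            val = 0.5 * (1.0 + (phi(m, f) if m and f else 0.0))
        else:
            # recurse on the later-generation member; founders are unrelated
            if gen[i] < gen[j]:
                i, j = j, i
            m, f = parents[i]
            if m is None and f is None:
                val = 0.0
            else:
                val = 0.5 * ((phi(m, j) if m else 0.0) + (phi(f, j) if f else 0.0))
        memo[key] = val
        return val

    ids = community.ids
    out = {}
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            out[(ids[a], ids[b])] = phi(ids[a], ids[b])
    return out


def degree_from_kinship(phi: float, self_pair: bool = False) -> int:
    """Deterministic band rule: degree d when phi in (1.5*2^-(d+2), 1.5*2^-(d+1)].

    Degree 0 is reserved for self/identical; beyond degree 6 returns
    UNRELATED_DEGREE (-1).
    """
    if self_pair:
        return 0
    if phi <= 0.0:
        return UNRELATED_DEGREE
    d = math.floor(-math.log2(phi / 1.5)) - 1
    if d < 1:
        return 0 if phi > 0.375 else 1
    return d if d <= 6 else UNRELATED_DEGREE


# ---------------------------------------------------------------------------
# uniparental transmission
# ---------------------------------------------------------------------------

def transmit_uniparental(community: Community, mt_mut_prob: float,
                         rng: np.random.Generator) -> dict:
    """Model mtDNA as mutated-position sets on a 16,569-position circle.

    Each clan's founding mothers share a seed set; clans are separated by
    ``config.clan_mt_divergence`` private positions.  Every mother-to-child
    transmission adds a fresh singleton position with probability
    ``mt_mut_prob``.  Y lineages were already assigned during pedigree
    construction (copied father to son, fresh per external founder).
    Returns and stores ``{individual_id: frozenset(positions)}``.
    """
    config = community.config
    clans = _clan_labels(config.n_clans)
    div = config.clan_mt_divergence
    pool = rng.permutation(MT_LENGTH)
    used = 0
    clan_sets = {}
    for i, clan in enumerate(clans):
        if i == 0:
            clan_sets[clan] = frozenset()
        else:
            clan_sets[clan] = frozenset(int(p) for p in pool[used:used + div])
            used += div

    def fresh_position():
        nonlocal used
        if used >= MT_LENGTH:
            raise RuntimeError("mtDNA mutation positions exhausted")
        p = int(pool[used])
        used += 1
        return p

    muts = {}
    for ind in community.individuals:
        if ind.generation == 0:
            muts[ind.id] = clan_sets[ind.matriline]
        else:
            s = muts[ind.mother_id]
            if rng.random() < mt_mut_prob:
                s = s | {fresh_position()}
            muts[ind.id] = frozenset(s)
    community.mt_mutations = muts
    return muts


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class DiploidGenotypes:
    """Site table plus diploid dosages derived from the gene-dropped tilings."""

    sites: pd.DataFrame          # chrom, bp, cM, ref, alt, founder_alt_freq
    ids: list
    dosage: np.ndarray           # (n_sites, n_individuals) int8 in {0,1,2}


@dataclass
class PseudoHaploidMatrix:
    """Single randomly sampled allele per site per individual.

    ``calls`` is (n_sites, n_individuals) int8 over {0 (ref), 1 (alt),
    MISSING (-1)}.  Sites are sorted by (chromosome order, bp).
    """

    sites: pd.DataFrame
    ids: list
    calls: np.ndarray

    def __post_init__(self):
        if self.calls.shape != (len(self.sites), len(self.ids)):
            raise ValueError("call matrix shape inconsistent with sites/roster")

    def column(self, ind_id: str) -> np.ndarray:
        return self.calls[:, self.ids.index(ind_id)]


def _truncated_beta(rng, n, a=0.5, b=0.5, lo=0.05, hi=0.95):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(a, b, size=max(n - filled, 64))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def sample_genotypes(community: Community, n_sites: int,
                     rng: np.random.Generator) -> DiploidGenotypes:
    """Draw a SNP panel and founder alleles, then read diploid dosages off the
    tilings.  Founder alternate-allele frequencies follow a Beta(0.5, 0.5)
    truncated to [freq_lo, freq_hi]."""
    gmap = community.gmap
    config = community.config
    bp_tot = sum(gmap.lengths_bp)
    per_chrom = [max(1, int(round(n_sites * b / bp_tot))) for b in gmap.lengths_bp]
    # trim/pad to the requested total
    while sum(per_chrom) > n_sites:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < n_sites:
        per_chrom[int(np.argmax(gmap.lengths_bp))] += 1

    site_rows = []
    cm_by_chrom = []
    for c, chrom in enumerate(gmap.chrom_ids):
        n_c = per_chrom[c]
        bp = np.sort(rng.choice(gmap.lengths_bp[c], size=n_c, replace=False))
        cm = gmap.bp_to_cm(c, bp)
        cm_by_chrom.append(cm)
        bases = np.array(list("ACGT"))
        ref = bases[rng.integers(4, size=n_c)]
        alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=n_c)) % 4]
        freq = _truncated_beta(rng, n_c, lo=config.freq_lo, hi=config.freq_hi)
        site_rows.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{p}" for p in bp],
            "chrom": chrom, "bp": bp, "cM": cm,
            "ref": ref, "alt": alt, "founder_alt_freq": freq}))
    sites = pd.concat(site_rows, ignore_index=True)

    freq = sites["founder_alt_freq"].to_numpy()
    founder_alleles = (rng.random((community.n_founder_haps, len(sites)))
                       < freq[None, :]).astype(np.int8)

    ids = community.ids
    dosage = np.zeros((len(sites), len(ids)), dtype=np.int8)
    offsets = np.cumsum([0] + per_chrom)
    for k, iid in enumerate(ids):
        for c in range(gmap.n_chrom):
            lo, hi = offsets[c], offsets[c + 1]
            cm = cm_by_chrom[c]
            h1, h2 = community.tilings[iid][c]
            a1 = founder_alleles[h1.id_at(cm), np.arange(lo, hi)]
            a2 = founder_alleles[h2.id_at(cm), np.arange(lo, hi)]
            dosage[lo:hi, k] = a1 + a2
    return DiploidGenotypes(sites=sites, ids=list(ids), dosage=dosage)


def pseudo_haploidize(geno: DiploidGenotypes, missing_rate: float,
                      error_rate: float, rng: np.random.Generator
                      ) -> PseudoHaploidMatrix:
    """Sample a single allele per site per individual, add allele-flip error,
    then mask calls at ``missing_rate``."""
    for name, v in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    d = geno.dosage
    calls = np.where(d == 2, 1, 0).astype(np.int8)
    het = d == 1
    calls[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    if error_rate > 0:
        flip = rng.random(d.shape) < error_rate
        calls[flip] ^= 1
    if missing_rate > 0:
        calls[rng.random(d.shape) < missing_rate] = MISSING
    return PseudoHaploidMatrix(sites=geno.sites, ids=list(geno.ids), calls=calls)


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def build_truth(community: Community, ibd_pairs="all",
                degrees: bool = True) -> TruthTables:
    """Pedigree degrees for all internal pairs; realized IBD/ROH segments.

    ``ibd_pairs`` is "all", "none", or an explicit list of ids restricting
    which pairs get segment-level truth.  ``degrees=False`` skips the
    quadratic pedigree-degree table (long-run closed-population scenarios
    where only ROH truth is needed).
    """
    ids = community.ids
    phis = kinship_coefficients(community) if degrees else {}
    subset = set(ids if ibd_pairs == "all" else
                 ([] if ibd_pairs == "none" else ibd_pairs))
    total = community.gmap.total_cM

    pair_rows, ibd_rows = [], []
    if degrees or subset:
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                ia, ib = ids[a], ids[b]
                if not degrees and not (ia in subset and ib in subset):
                    continue
                deg = (degree_from_kinship(phis[(ia, ib)]) if degrees
                       else UNRELATED_DEGREE)
                k1 = k2 = np.nan
                if ia in subset and ib in subset:
                    segs = derive_true_ibd(community, ia, ib)
                    k1 = sum(e - s for _, s, e, st in segs
                             if st == "IBD1") / total
                    k2 = sum(e - s for _, s, e, st in segs
                             if st == "IBD2") / total
                    for chrom, s, e, st in segs:
                        ibd_rows.append((ia, ib, chrom, s, e, st))
                pair_rows.append((ia, ib, deg,
                                  1.0 - k1 - k2 if k1 == k1 else np.nan,
                                  k1, k2))

    roh_rows = []
    for iid in ids:
        for chrom, s, e in derive_true_roh(community, iid):
            roh_rows.append((iid, chrom, s, e))

    pairs = pd.DataFrame(pair_rows,
                         columns=["id1", "id2", "degree", "k0", "k1", "k2"])
    ibd = pd.DataFrame(ibd_rows,
                       columns=["id1", "id2", "chrom", "start_cM", "end_cM", "state"])
    roh = pd.DataFrame(roh_rows, columns=["id", "chrom", "start_cM", "end_cM"])
    return TruthTables(pairs=pairs, ibd=ibd, roh=roh)


def simulate_community(config: SimConfig, gmap: GeneticMapSpec | None = None,
                       ibd_pairs="all", degrees: bool = True):
    """Simulate a community and its truth tables.

    Returns ``(Community, TruthTables)``.  The community carries the pedigree,
    burial labels and coordinates, gene-dropped haplotype tilings and mtDNA
    mutation sets; genotypes are drawn separately with
    :func:`sample_genotypes` / :func:`pseudo_haploidize`.
    """
    gmap = gmap or GeneticMapSpec.human_autosomes()
    rng = np.random.default_rng(config.seed)
    internal, external = _build_pedigree(config, rng)
    community = Community(config=config, gmap=gmap,
                          individuals=internal, externals=external)
    gene_drop(community, rng)
    transmit_uniparental(community, config.mt_mut_prob, rng)
    truth = build_truth(community, ibd_pairs=ibd_pairs, degrees=degrees)
    return community, truth


# ---------------------------------------------------------------------------
# direct pair simulator (for calibration experiments)
# ---------------------------------------------------------------------------

def simulate_pair_matrix(k_vector, n_sites: int, gmap: GeneticMapSpec,
                         rng: np.random.Generator, missing_rate: float = 0.0,
                         error_rate: float = 0.0, block_cM: float | None = None,
                         ids=("A", "B")) -> PseudoHaploidMatrix:
    """Pseudo-haploid calls for one pair with prescribed IBD-state fractions.

    IBD state (0/1/2) is drawn with probabilities ``k_vector`` either
    independently per site or in blocks of ``block_cM`` along the genetic map
    (blockwise states preserve the genome-fraction semantics while giving
    windows a single state, as real segments do).  Founder allele frequencies
    follow the default truncated Beta spectrum.
    """
    k = np.asarray(k_vector, dtype=float)
    if abs(k.sum() - 1.0) > 1e-9 or (k < 0).any():
        raise ValueError("k-vector must be a probability vector")
    bp_tot = sum(gmap.lengths_bp)
    per_chrom = [max(1, int(round(n_sites * b / bp_tot))) for b in gmap.lengths_bp]
    rows = []
    states = []
    for c, chrom in enumerate(gmap.chrom_ids):
        n_c = per_chrom[c]
        bp = np.sort(rng.choice(gmap.lengths_bp[c], size=n_c, replace=False))
        cm = gmap.bp_to_cm(c, bp)
        rows.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{p}" for p in bp],
            "chrom": chrom, "bp": bp, "cM": cm,
            "ref": "A", "alt": "G",
            "founder_alt_freq": np.nan}))
        if block_cM is None:
            states.append(rng.choice(3, size=n_c, p=k))
        else:
            n_blocks = int(np.ceil(gmap.lengths_cM[c] / block_cM))
            block_state = rng.choice(3, size=n_blocks, p=k)
            states.append(block_state[(cm // block_cM).astype(int)])
    sites = pd.concat(rows, ignore_index=True)
    state = np.concatenate(states)
    n = len(sites)
    freq = _truncated_beta(rng, n)
    sites["founder_alt_freq"] = freq

    hap = (rng.random((4, n)) < freq[None, :]).astype(np.int8)  # a1,a2,b1,b2
    hap[2, state >= 1] = hap[0, state >= 1]
    hap[3, state == 2] = hap[1, state == 2]

    pick_a = rng.integers(2, size=n)
    pick_b = rng.integers(2, size=n)
    calls = np.stack([np.where(pick_a == 0, hap[0], hap[1]),
                      np.where(pick_b == 0, hap[2], hap[3])], axis=1).astype(np.int8)
    if error_rate > 0:
        calls[rng.random(calls.shape) < error_rate] ^= 1
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return PseudoHaploidMatrix(sites=sites, ids=list(ids), calls=calls)
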