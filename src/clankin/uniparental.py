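"""Uniparental marker analysis.

Haplogroup assignment scores a sample's SNP calls against the theoretical
allele state of every haplogroup on a tree (derived exactly on the
root-to-haplogroup path, ancestral elsewhere); matriline clustering joins
individuals whose mtDNA consensus sequences are identical; Simpson's
diversity index summarizes lineage composition per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo

from .community import MT_LENGTH


class HaplogroupTableError(ValueError):
    pass


@dataclass
class HaplogroupTable:
    """Haplogroup tree plus branch-defining SNPs.

    ``parent`` maps every haplogroup to its parent (root maps to None);
    ``branch_markers`` maps a haplogroup to the (marker_id, ancestral,
    derived) triples on the branch leading to it.  Each marker belongs to
    exactly one branch.
    """

    parent: dict
    branch_markers: dict = field(default_factory=dict)

    def __post_init__(self):
        roots = [h for h, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise HaplogroupTableError(f"need exactly one root, found {roots}")
        self.root = roots[0]
        seen = {}
        for h, markers in self.branch_markers.items():
            if h not in self.parent:
                raise HaplogroupTableError(f"markers on unknown haplogroup {h}")
            for m, _, _ in markers:
                if m in seen:
                    raise HaplogroupTableError(
                        f"marker {m} assigned to both {seen[m]} and {h}")
                seen[m] = h
        # reachability / acyclicity
        for h in self.parent:
            path, node = set(), h
            while node is not None:
                if node in path:
                    raise HaplogroupTableError(f"cycle through {node}")
                path.add(node)
                node = self.parent[node]
            if self.root not in path:
                raise HaplogroupTableError(f"{h} unreachable from root")

    @property
    def haplogroups(self) -> list:
        return sorted(self.parent)

    @property
    def markers(self) -> list:
        out = []
        for h in sorted(self.branch_markers):
            out.extend(m for m, _, _ in self.branch_markers[h])
        return out

    def path_to_root(self, h: str) -> list:
        out = []
        while h is not None:
            out.append(h)
            h = self.parent[h]
        return out

    @classmethod
    def from_files(cls, newick_path, markers_tsv) -> "HaplogroupTable":
        """Load tree topology from newick and branch SNPs from a TSV with
        columns haplogroup, marker_id, ancestral, derived."""
        tree = Phylo.read(str(newick_path), "newick")
        parent = {}

        def walk(clade, par):
            name = clade.name
            if name is None:
                raise HaplogroupTableError("every tree node must be named")
            parent[name] = par
            for child in clade.clades:
                walk(child, name)

        walk(tree.root, None)
        df = pd.read_csv(markers_tsv, sep="\t", dtype=str)
        branch = {}
        for row in df.itertuples(index=False):
            branch.setdefault(row.haplogroup, []).append(
                (row.marker_id, row.ancestral, row.derived))
        return cls(parent=parent, branch_markers=branch)


def theoretical_genotypes(table: HaplogroupTable) -> pd.DataFrame:
    """Theoretical allele per (haplogroup, marker): derived at markers on the
    root-to-haplogroup path, ancestral everywhere else."""
    markers, anc, hg_of = [], {}, {}
    for h, trips in table.branch_markers.items():
        for m, a, d in trips:
            markers.append(m)
            anc[m] = a
            hg_of[m] = (h, d)
    theo = pd.DataFrame({m: anc[m] for m in markers},
                        index=table.haplogroups, columns=markers, dtype=object)
    for h in table.haplogroups:
        on_path = set(table.path_to_root(h))
        for m in markers:
            branch_h, derived = hg_of[m]
            if branch_h in on_path:
                theo.loc[h, m] = derived
    return theo


@dataclass
class AssignmentResult:
    individual: str
    best_haplogroups: list      # all maximizers
    score: float                # matches / markers compared
    n_markers_compared: int
    qc_pass: bool
    ambiguous: bool
    scores: dict = field(default_factory=dict)


def assign_haplogroup(individual: str, calls: dict, table: HaplogroupTable,
                      min_snps: int = 1000) -> AssignmentResult:
    """Similarity-score haplogroup assignment.

    ``calls`` maps marker_id to the observed allele (only markers with at
    least one read and no heterozygosity belong here).  The score of a
    haplogroup is the fraction of compared markers whose call equals its
    theoretical allele; alleles that are neither ancestral nor derived count
    as mismatches against every haplogroup.  Ties are reported, never broken.
    ``qc_pass`` requires at least ``min_snps`` called markers.
    """
    theo = theoretical_genotypes(table)
    compared = [m for m in theo.columns if m in calls]
    if not compared:
        raise ValueError(f"no called markers overlap the tree for {individual}")
    obs = np.array([calls[m] for m in compared], dtype=object)
    sub = theo[compared].to_numpy(dtype=object)
    matches = (sub == obs[None, :]).sum(axis=1)
    best = matches.max()
    winners = [h for h, m in zip(theo.index, matches) if m == best]
    return AssignmentResult(
        individual=individual,
        best_haplogroups=winners,
        score=float(best / len(compared)),
        n_markers_compared=len(compared),
        qc_pass=len(compared) >= min_snps,
        ambiguous=len(winners) > 1,
        scores={h: float(m / len(compared)) for h, m in zip(theo.index, matches)})


# ---------------------------------------------------------------------------
# mtDNA sequences and matriline clustering
# ---------------------------------------------------------------------------

@dataclass
class MtSequenceSet:
    """Per-individual mutated-position sets on the circular mtDNA reference."""

    ids: list
    mutations: list             # list of frozensets, parallel to ids

    @classmethod
    def from_mutation_sets(cls, sets: dict) -> "MtSequenceSet":
        ids = sorted(sets)
        return cls(ids=ids, mutations=[frozenset(sets[i]) for i in ids])

    @classmethod
    def from_sequences(cls, seqs: dict, reference: str) -> "MtSequenceSet":
        if any(len(s) != len(reference) for s in seqs.values()):
            raise ValueError("sequence length differs from reference")
        ref = np.frombuffer(reference.encode(), dtype="S1")
        ids = sorted(seqs)
        muts = []
        for i in ids:
            arr = np.frombuffer(seqs[i].encode(), dtype="S1")
            muts.append(frozenset(np.flatnonzero(arr != ref).tolist()))
        return cls(ids=ids, mutations=muts)

    def difference_matrix(self) -> np.ndarray:
        n = len(self.ids)
        d = np.zeros((n, n), dtype=int)
        for a in range(n):
            for b in range(a + 1, n):
                d[a, b] = d[b, a] = len(self.mutations[a] ^ self.mutations[b])
        return d


@dataclass
class MatrilinePartition:
    labels: dict                # id -> component index
    n_components: int
    min_inter_difference: int | None  # None when a single component


def mt_cluster(seqset: MtSequenceSet) -> MatrilinePartition:
    """Partition individuals into matrilines as connected components of the
    zero-difference graph; reports the smallest between-component difference."""
    d = seqset.difference_matrix()
    n = len(seqset.ids)
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for a in range(n):
        for b in range(a + 1, n):
            if d[a, b] == 0:
                comp[find(a)] = find(b)
    roots = [find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    labels = {seqset.ids[i]: relabel[roots[i]] for i in range(n)}
    inter = [d[a, b] for a in range(n) for b in range(a + 1, n)
             if roots[a] != roots[b]]
    return MatrilinePartition(labels=labels, n_components=len(relabel),
                              min_inter_difference=min(inter) if inter else None)


# ---------------------------------------------------------------------------
# Simpson's diversity index
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    counts: tuple
    estimator: str
    value: float


def simpson(counts, estimator: str = "unbiased") -> DiversityResult:
    """Simpson's diversity index of category counts.

    ``plain``: 1 - sum((n_i/N)^2), defined for N >= 1.
    ``unbiased``: 1 - sum(n_i (n_i - 1)) / (N (N - 1)), requires N >= 2.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = np.asarray(counts, dtype=float)
    total = n.sum()
    if estimator == "plain":
        if total < 1:
            raise ValueError("plain estimator needs N >= 1")
        value = 1.0 - float(((n / total) ** 2).sum())
    elif estimator == "unbiased":
        if total < 2:
            raise ValueError("unbiased estimator needs N >= 2")
        value = 1.0 - float((n * (n - 1)).sum() / (total * (total - 1)))
    else:
        raise ValueError(f"unknown estimator: {estimator}")
    return DiversityResult(counts=counts, estimator=estimator, value=value)
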