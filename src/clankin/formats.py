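"""File formats.

EIGENSTRAT-dialect genotypes with pseudo-haploid encoding: the .geno
alphabet is {0, 2, 9} — 0 = reference call (written as dosage 0), 2 =
alternate call, 9 = missing.  The value 1 never occurs: a single sampled
allele is stored in a diploid container, and consumers assuming true diploid
dosages would misread these files.  Genetic positions are stored in Morgans
in .snp (the common dialect) but centimorgans everywhere in memory;
conversion happens only at this boundary.

Readers validate rather than coerce: dimension mismatches, non-monotone
positions and illegal characters raise distinct, named errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import MISSING, MT_LENGTH, PseudoHaploidMatrix


class EigenstratError(ValueError):
    pass


class DimensionMismatchError(EigenstratError):
    pass


class NonMonotonePositionError(EigenstratError):
    pass


class IllegalCharacterError(EigenstratError):
    pass


_GENO_CHAR = {0: "0", 1: "2", MISSING: "9"}
_CHAR_GENO = {"0": 0, "2": 1, "9": MISSING}


def write_eigenstrat(prefix, matrix: PseudoHaploidMatrix, roster: pd.DataFrame
                     ) -> None:
    """Write .geno/.snp/.ind with deterministic formatting.

    ``roster`` needs columns id and sex (M/F/U); a matriline or cemetery
    column, if present, becomes the .ind group label.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    lut = np.array(["9"] * 256)
    for v, ch in _GENO_CHAR.items():
        lut[v % 256] = ch
    with open(f"{prefix}.geno", "w") as fh:
        view = matrix.calls.astype(np.int16) % 256
        for row in view:
            fh.write("".join(lut[row]) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for r in matrix.sites.itertuples(index=False):
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.cM / 100.0:.8f}\t{int(r.bp)}"
                     f"\t{r.ref}\t{r.alt}\n")
    group_col = next((c for c in ("group", "matriline", "cemetery")
                      if c in roster.columns), None)
    by_id = roster.set_index("id")
    with open(f"{prefix}.ind", "w") as fh:
        for iid in matrix.ids:
            sex = by_id.loc[iid, "sex"] if iid in by_id.index else "U"
            group = (by_id.loc[iid, group_col]
                     if group_col and iid in by_id.index else "POP")
            fh.write(f"{iid}\t{sex}\t{group}\n")


def read_eigenstrat(prefix):
    """Read .geno/.snp/.ind back into a matrix and roster.

    Returns ``(PseudoHaploidMatrix, roster_df)``; founder allele frequencies
    are not stored on disk and come back as NaN.
    """
    prefix = Path(prefix)
    snp = pd.read_csv(f"{prefix}.snp", sep="\t", header=None,
                      names=["snp_id", "chrom", "morgans", "bp", "ref", "alt"],
                      dtype={"chrom": str})
    ind = pd.read_csv(f"{prefix}.ind", sep="\t", header=None,
                      names=["id", "sex", "group"])
    with open(f"{prefix}.geno") as fh:
        lines = [line.rstrip("\n") for line in fh]
    if len(lines) != len(snp):
        raise DimensionMismatchError(
            f".geno has {len(lines)} lines but .snp has {len(snp)} rows")
    n_ind = len(ind)
    calls = np.empty((len(lines), n_ind), dtype=np.int8)
    for i, line in enumerate(lines):
        if len(line) != n_ind:
            raise DimensionMismatchError(
                f".geno line {i + 1} has {len(line)} characters for "
                f"{n_ind} individuals")
        for ch in set(line):
            if ch not in _CHAR_GENO:
                raise IllegalCharacterError(
                    f"illegal .geno character {ch!r} on line {i + 1}")
        calls[i] = [_CHAR_GENO[ch] for ch in line]
    for chrom, sub in snp.groupby("chrom", sort=False):
        g = sub["morgans"].to_numpy()
        if np.any(np.diff(g) < 0):
            raise NonMonotonePositionError(
                f"genetic positions decrease within chromosome {chrom}")
    sites = pd.DataFrame({
        "snp_id": snp["snp_id"], "chrom": snp["chrom"], "bp": snp["bp"],
        "cM": snp["morgans"] * 100.0, "ref": snp["ref"], "alt": snp["alt"],
        "founder_alt_freq": np.nan})
    matrix = PseudoHaploidMatrix(sites=sites, ids=list(ind["id"]), calls=calls)
    return matrix, ind


# ---------------------------------------------------------------------------
# mtDNA FASTA
# ---------------------------------------------------------------------------

_NEXT_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def mt_reference(seed: int = 101) -> str:
    """Deterministic synthetic mtDNA reference string (16,569 bp)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=MT_LENGTH)])


def mt_sequences_from_mutations(mutations: dict, reference: str | None = None
                                ) -> dict:
    """Render mutated-position sets as full-length sequences (each mutated
    position is substituted by a fixed transition of the reference base)."""
    ref = reference or mt_reference()
    out = {}
    for iid, positions in mutations.items():
        seq = list(ref)
        for p in positions:
            seq[p] = _NEXT_BASE[seq[p]]
        out[iid] = "".join(seq)
    return out


def write_mt_fasta(path, sequences: dict) -> None:
    records = [SeqRecord(Seq(seq), id=iid, description="")
               for iid, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_mt_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.6f")


def read_segments_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
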