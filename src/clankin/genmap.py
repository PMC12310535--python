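"""Genetic maps with a constant cM-per-bp rate within each chromosome.

All interval arithmetic in the package is done on the genetic (cM) axis,
half-open ``[start, end)`` and 0-based.  Physical positions are derived from
the per-chromosome constant rate and only matter at format boundaries
(window building, EIGENSTRAT output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Sex-averaged autosomal map lengths (cM) and physical lengths (Mb), rounded.
# Totals ~35.3 Morgans / ~2.88 Gb, the scale of a human 1240k-style panel.
_HUMAN_AUTOSOMES = [
    ("1", 286.3, 249_000_000), ("2", 268.6, 243_000_000),
    ("3", 223.4, 198_000_000), ("4", 214.6, 191_000_000),
    ("5", 204.1, 181_000_000), ("6", 192.0, 171_000_000),
    ("7", 187.2, 159_000_000), ("8", 168.0, 146_000_000),
    ("9", 166.4, 141_000_000), ("10", 181.1, 136_000_000),
    ("11", 158.2, 135_000_000), ("12", 174.7, 134_000_000),
    ("13", 125.9, 115_000_000), ("14", 120.2, 107_000_000),
    ("15", 141.9, 103_000_000), ("16", 134.0, 90_000_000),
    ("17", 128.5, 81_000_000), ("18", 117.9, 78_000_000),
    ("19", 107.9, 59_000_000), ("20", 108.3, 63_000_000),
    ("21", 62.8, 48_000_000), ("22", 74.1, 51_000_000),
]


@dataclass(frozen=True)
class GeneticMapSpec:
    """Per-chromosome genetic and physical lengths.

    Parameters
    ----------
    chrom_ids
        Unique chromosome identifiers, in output order.
    lengths_cM
        Genetic length of each chromosome in centimorgans (> 0).
    lengths_bp
        Physical length of each chromosome in base pairs (> 0).
    """

    chrom_ids: tuple
    lengths_cM: tuple
    lengths_bp: tuple

    def __post_init__(self):
        if not (len(self.chrom_ids) == len(self.lengths_cM) == len(self.lengths_bp)):
            raise ValueError("chromosome field lengths differ")
        if len(set(self.chrom_ids)) != len(self.chrom_ids):
            raise ValueError("duplicate chromosome ids")
        if any(l <= 0 for l in self.lengths_cM):
            raise ValueError("genetic lengths must be positive")
        if any(l <= 0 for l in self.lengths_bp):
            raise ValueError("physical lengths must be positive")

    @classmethod
    def from_rows(cls, rows) -> "GeneticMapSpec":
        """Build from an iterable of (chrom_id, length_cM, length_bp)."""
        ids, cm, bp = zip(*rows)
        return cls(tuple(str(i) for i in ids), tuple(float(x) for x in cm),
                   tuple(int(x) for x in bp))

    @classmethod
    def human_autosomes(cls) -> "GeneticMapSpec":
        """Default 22-autosome map (~35.3 Morgans)."""
        return cls.from_rows(_HUMAN_AUTOSOMES)

    @classmethod
    def toy(cls) -> "GeneticMapSpec":
        """Small three-chromosome map used for desk-scale tests."""
        return cls.from_rows([("1", 100.0, 100_000_000),
                              ("2", 80.0, 80_000_000),
                              ("3", 60.0, 60_000_000)])

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    @property
    def total_cM(self) -> float:
        return float(sum(self.lengths_cM))

    @property
    def total_morgans(self) -> float:
        return self.total_cM / 100.0

    def bp_per_cM(self, c: int) -> float:
        return self.lengths_bp[c] / self.lengths_cM[c]

    def cm_to_bp(self, c: int, cm) -> np.ndarray:
        """Physical position for genetic position(s) on chromosome index ``c``."""
        return np.asarray(np.floor(np.asarray(cm) * self.bp_per_cM(c)), dtype=np.int64)

    def bp_to_cm(self, c: int, bp) -> np.ndarray:
        return np.asarray(bp, dtype=float) / self.bp_per_cM(c)

    def chrom_index(self, chrom_id: str) -> int:
        return self.chrom_ids.index(str(chrom_id))
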