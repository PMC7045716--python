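"""In-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypeMatrix:
    """Binary segregating-site matrix for one locus.

    Rows are haplotypes (the first ``nA`` from population A, the rest
    from population B), columns segregating sites (0 = ancestral,
    1 = derived).  ``positions`` are relative positions in [0, 1),
    strictly increasing.
    """

    matrix: np.ndarray
    positions: np.ndarray
    nA: int
    nB: int
    locus_id: str = "locus"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[0] != self.nA + self.nB:
            raise ValueError("row count must equal nA + nB")
        if self.matrix.shape[1] != self.positions.shape[0]:
            raise ValueError("positions must match the site count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def site_masks(self) -> np.ndarray:
        """Derived-allele bitmasks per site (haplotype i -> bit i)."""
        n = self.matrix.shape[0]
        if n > 64:
            raise ValueError("bitmask representation supports <= 64 haplotypes")
        weights = (np.uint64(1) << np.arange(n, dtype=np.uint64))
        return (self.matrix.astype(np.uint64).T * weights).sum(axis=1,
                                                               dtype=np.uint64)

    @classmethod
    def from_site_masks(cls, masks: np.ndarray, positions: np.ndarray,
                        nA: int, nB: int, locus_id: str = "locus"):
        n = nA + nB
        masks = np.asarray(masks, dtype=np.uint64)
        mat = np.zeros((n, masks.size), dtype=np.uint8)
        for i in range(n):
            mat[i] = (masks >> np.uint64(i)) & np.uint64(1)
        return cls(mat, positions, nA, nB, locus_id)
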