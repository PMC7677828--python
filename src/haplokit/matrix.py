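"""Central genotype container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Sample x variant matrix of diploid genotype codes.

    Codes are alternate-allele counts 0/1/2; ``MISSING`` (-1) marks a
    no-call.  Variants are kept in positional order.
    """

    samples: list[str]
    variants: list[str]
    positions: np.ndarray
    genotypes: np.ndarray  # shape (n_samples, n_variants), int8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.positions) != len(self.variants):
            raise ValueError("positions and variants length mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variants.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(variant_id)]

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            positions=self.positions[idx],
            genotypes=self.genotypes[:, idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            positions=self.positions.copy(),
            genotypes=self.genotypes[idx, :],
        )
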