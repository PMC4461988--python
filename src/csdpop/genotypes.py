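"""Diploid genotype matrix with a region > field sample hierarchy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenotypeMatrix", "MISSING"]

MISSING = -1  # sentinel allele code for a missing call


@dataclass
class GenotypeMatrix:
    """Diploid calls for individuals x loci with a two-level hierarchy.

    ``calls`` has shape (n_individuals, n_loci, 2) with integer allele
    codes >= 0 and both entries equal to :data:`MISSING` for missing calls.
    Each individual belongs to exactly one field; each field to one region.
    """

    calls: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    field_of: dict[str, str]
    region_of: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        n, m, _ = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length does not match calls")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        missing_half = (self.calls[:, :, 0] == MISSING) != (
            self.calls[:, :, 1] == MISSING
        )
        if missing_half.any():
            raise ValueError("half-missing calls: both alleles must be missing")
        for ind in self.individual_ids:
            if ind not in self.field_of:
                raise ValueError(f"individual {ind!r} has no field")
        for f in set(self.field_of.values()):
            if f not in self.region_of:
                raise ValueError(f"field {f!r} has no region")

    # -- hierarchy helpers -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def fields(self) -> np.ndarray:
        """Field label per individual (aligned with rows)."""
        return np.array([self.field_of[i] for i in self.individual_ids])

    @property
    def regions(self) -> np.ndarray:
        """Region label per individual (aligned with rows)."""
        return np.array(
            [self.region_of[self.field_of[i]] for i in self.individual_ids]
        )

    def field_labels(self) -> list[str]:
        """Fields in first-appearance order."""
        seen: list[str] = []
        for i in self.individual_ids:
            f = self.field_of[i]
            if f not in seen:
                seen.append(f)
        return seen

    def region_labels(self) -> list[str]:
        seen: list[str] = []
        for f in self.field_labels():
            r = self.region_of[f]
            if r not in seen:
                seen.append(r)
        return seen

    # -- subsetting --------------------------------------------------------

    def subset_individuals(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        ids = [self.individual_ids[i] for i in index]
        return GenotypeMatrix(
            calls=self.calls[index],
            individual_ids=ids,
            locus_ids=list(self.locus_ids),
            field_of={i: self.field_of[i] for i in ids},
            region_of=dict(self.region_of),
        )

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        idx = [pos[l] for l in locus_ids]
        return GenotypeMatrix(
            calls=self.calls[:, idx, :],
            individual_ids=list(self.individual_ids),
            locus_ids=list(locus_ids),
            field_of=dict(self.field_of),
            region_of=dict(self.region_of),
        )

    def field_subset(self, field_label: str) -> "GenotypeMatrix":
        mask = self.fields == field_label
        return self.subset_individuals(np.flatnonzero(mask))

    # -- per-locus views ---------------------------------------------------

    def locus_calls(self, locus: str | int) -> np.ndarray:
        """Non-missing calls at one locus, shape (n_obs, 2)."""
        j = locus if isinstance(locus, int) else self.locus_ids.index(locus)
        col = self.calls[:, j, :]
        return col[col[:, 0] != MISSING]

    def missing_rate(self) -> float:
        return float((self.calls[:, :, 0] == MISSING).mean())
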