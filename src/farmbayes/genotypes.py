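"""Dosage-matrix container shared by the simulator, samplers and I/O layer.

Genotypes are biallelic dosages in {0, 1, 2} (copies of the counted allele).
Standardization follows the usual genomic-prediction convention: each marker
column is centered by twice its allele frequency and scaled by
sqrt(2 p (1 - p)), so that a column has (approximately) zero mean and unit
variance on the data used to compute the constants.  Monomorphic markers carry
no information and are dropped at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """n_animals x n_markers dosage matrix with standardization constants.

    Attributes
    ----------
    dosages : int8 array, shape (n_animals, n_markers)
        Allele dosages, every entry 0, 1 or 2 (missingness is resolved before
        construction).
    marker_ids, chrom, pos : arrays of length n_markers
        Marker identifiers and map coordinates (pos is 1-based, PLINK style).
    animal_ids : array of length n_animals
    allele_freq : float array in (0, 1)
        Counted-allele frequency on the construction data.
    center, scale : float arrays
        Per-marker standardization constants 2p and sqrt(2 p (1 - p)).
    n_dropped_monomorphic : int
        Markers removed at construction because they carried no variation.
    """

    dosages: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    animal_ids: np.ndarray
    allele_freq: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    n_dropped_monomorphic: int = 0
    ancestry: np.ndarray | None = field(default=None, repr=False)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dosages(
        cls,
        dosages,
        marker_ids=None,
        chrom=None,
        pos=None,
        animal_ids=None,
        ancestry=None,
    ) -> "GenotypeMatrix":
        """Build a matrix from raw dosages, dropping monomorphic markers."""
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (animals x markers) array")
        if not np.isin(dosages, (0, 1, 2)).all():
            raise ValueError("every dosage must be 0, 1 or 2")
        n, m = dosages.shape
        if marker_ids is None:
            marker_ids = np.array([f"snp{j}" for j in range(m)])
        if chrom is None:
            chrom = np.ones(m, dtype=np.int64)
        if pos is None:
            pos = np.arange(1, m + 1, dtype=np.int64)
        if animal_ids is None:
            animal_ids = np.array([f"animal{i}" for i in range(n)])
        marker_ids = np.asarray(marker_ids)
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        animal_ids = np.asarray(animal_ids)
        if not (len(marker_ids) == len(chrom) == len(pos) == m):
            raise ValueError("marker metadata length does not match marker count")
        if len(animal_ids) != n:
            raise ValueError("animal_ids length does not match animal count")

        p = dosages.mean(axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)
        n_dropped = int((~keep).sum())
        dosages = np.ascontiguousarray(dosages[:, keep], dtype=np.int8)
        p = p[keep]
        return cls(
            dosages=dosages,
            marker_ids=marker_ids[keep],
            chrom=chrom[keep],
            pos=pos[keep],
            animal_ids=animal_ids,
            allele_freq=p,
            center=2.0 * p,
            scale=np.sqrt(2.0 * p * (1.0 - p)),
            n_dropped_monomorphic=n_dropped,
            ancestry=None if ancestry is None else np.asarray(ancestry),
        )

    # ------------------------------------------------------------------ #
    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def standardized(self, order: str = "F") -> np.ndarray:
        """Centered/scaled dosage matrix Z (float64)."""
        Z = (self.dosages.astype(np.float64) - self.center) / self.scale
        return np.asfortranarray(Z) if order == "F" else np.ascontiguousarray(Z)

    def standardized_with(self, center, scale, order: str = "F") -> np.ndarray:
        """Standardize with externally supplied (training-set) constants."""
        Z = (self.dosages.astype(np.float64) - np.asarray(center)) / np.asarray(scale)
        return np.asfortranarray(Z) if order == "F" else np.ascontiguousarray(Z)

    def subset_animals(self, index) -> "GenotypeMatrix":
        """Row subset with standardization constants recomputed on the subset.

        Used for cross-validation reference sets, where allele frequencies
        must come from the reference animals only to avoid leakage.
        """
        index = np.asarray(index)
        return GenotypeMatrix.from_dosages(
            self.dosages[index],
            marker_ids=self.marker_ids,
            chrom=self.chrom,
            pos=self.pos,
            animal_ids=self.animal_ids[index],
        )

    def marker_indexer(self, marker_ids) -> np.ndarray:
        """Positions of the given marker ids in this matrix (-1 if absent)."""
        lookup = {mid: j for j, mid in enumerate(self.marker_ids)}
        return np.array([lookup.get(m, -1) for m in np.asarray(marker_ids)])
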