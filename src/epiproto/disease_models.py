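"""Two-locus binary disease models and their symmetry algebra.

A *disease model* is a 3x3 table of 0/1 risk indicators over the genotype
combinations of a SNP pair.  Rows are indexed by the minor-allele count of
SNP A (0 = AA, 1 = Aa, 2 = aa) and columns by the minor-allele count of
SNP B.  A "1" marks a genotype combination that elevates disease risk.
This is the classic two-locus, two-allele, two-phenotype,
complete-penetrance (TTTC) family: 2**9 = 512 tables, of which the all-0
and all-1 tables carry no signal and are called *trivial*.

Two symmetries matter for cataloguing these models:

* **locus exchange** -- swapping the two SNPs transposes the table;
* **disease-status exchange** -- relabelling risky/non-risky complements
  every cell.

Together with their composition these generate a group of order four
acting on the tables.  The 510 non-trivial models fall into 143 orbits;
``reduced_set`` returns one canonical representative per orbit.

Models serialize to a 9-character 0/1 string in row-major order
(index = 3 * countA + countB), which is the identifier used throughout
the package (library files, score tables).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DiseaseModel",
    "enumerate_nontrivial",
    "transpose",
    "complement",
    "canonical",
    "reduced_set",
    "risk_vector",
    "TRIVIAL_LOW",
    "TRIVIAL_HIGH",
]


class DiseaseModel:
    """A 3x3 binary risk table for a SNP pair.

    Immutable and hashable; two models compare equal iff their 9-bit ids
    are equal.

    Parameters
    ----------
    cells : array-like of shape (3, 3)
        Binary risk indicators; rows indexed by SNP-A minor-allele count,
        columns by SNP-B minor-allele count.
    """

    __slots__ = ("_cells", "_id")

    def __init__(self, cells):
        arr = np.asarray(cells, dtype=np.int8)
        if arr.shape != (3, 3):
            raise ValueError(f"disease model must be 3x3, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("disease model cells must be 0 or 1")
        arr = arr.copy()
        arr.setflags(write=False)
        self._cells = arr
        self._id = "".join(str(int(b)) for b in arr.ravel())

    @classmethod
    def from_id(cls, model_id: str) -> "DiseaseModel":
        """Parse a 9-character row-major 0/1 string."""
        if len(model_id) != 9 or set(model_id) - {"0", "1"}:
            raise ValueError(f"invalid model id {model_id!r}")
        return cls(np.fromiter((int(c) for c in model_id), dtype=np.int8).reshape(3, 3))

    @property
    def cells(self) -> np.ndarray:
        return self._cells

    @property
    def id(self) -> str:
        return self._id

    @property
    def bits(self) -> np.ndarray:
        """Flat row-major view of the 9 risk indicators."""
        return self._cells.ravel()

    @property
    def is_trivial(self) -> bool:
        """True for the all-0 and all-1 tables."""
        return self._id in ("000000000", "111111111")

    @property
    def is_symmetric(self) -> bool:
        """True when the table is invariant under locus exchange."""
        return bool((self._cells == self._cells.T).all())

    def transpose(self) -> "DiseaseModel":
        """Exchange the two loci (swap rows and columns)."""
        return DiseaseModel(self._cells.T)

    def complement(self) -> "DiseaseModel":
        """Exchange disease status (flip every cell)."""
        return DiseaseModel(1 - self._cells)

    def orbit(self) -> tuple["DiseaseModel", ...]:
        """The (<= 4) distinct images under the symmetry group."""
        images = {m.id: m for m in (self, self.transpose(), self.complement(),
                                    self.transpose().complement())}
        return tuple(images[i] for i in sorted(images))

    def canonical(self) -> "DiseaseModel":
        """Orbit representative with the lexicographically smallest id."""
        if self.is_trivial:
            raise ValueError("trivial models have no canonical representative")
        return self.orbit()[0]

    def risk_vector(self, geno_a, geno_b) -> np.ndarray:
        """Per-individual binary risk from the two genotype-count vectors."""
        return risk_vector(self, geno_a, geno_b)

    def __eq__(self, other):
        return isinstance(other, DiseaseModel) and self._id == other._id

    def __hash__(self):
        return hash(self._id)

    def __repr__(self):
        return f"DiseaseModel({self._id!r})"


TRIVIAL_LOW = DiseaseModel(np.zeros((3, 3), dtype=np.int8))
TRIVIAL_HIGH = DiseaseModel(np.ones((3, 3), dtype=np.int8))


def transpose(m: DiseaseModel) -> DiseaseModel:
    return m.transpose()


def complement(m: DiseaseModel) -> DiseaseModel:
    return m.complement()


def canonical(m: DiseaseModel) -> DiseaseModel:
    return m.canonical()


@lru_cache(maxsize=1)
def _enumerate_ids() -> tuple[str, ...]:
    ids = []
    for code in range(512):
        bits = format(code, "09b")
        if bits not in ("000000000", "111111111"):
            ids.append(bits)
    return tuple(sorted(ids))


def enumerate_nontrivial() -> list[DiseaseModel]:
    """All 510 non-trivial models in lexicographic id order."""
    return [DiseaseModel.from_id(i) for i in _enumerate_ids()]


@lru_cache(maxsize=1)
def _reduced_ids() -> tuple[str, ...]:
    reps = {DiseaseModel.from_id(i).canonical().id for i in _enumerate_ids()}
    return tuple(sorted(reps))


def reduced_set() -> list[DiseaseModel]:
    """One canonical representative per symmetry orbit (143 models).

    Sorted lexicographically by id; every member is its own canonical
    form.  This is the candidate set used for prototype clustering.
    """
    return [DiseaseModel.from_id(i) for i in _reduced_ids()]


def risk_vector(m: DiseaseModel, geno_a, geno_b) -> np.ndarray:
    """Apply a model's risk table to per-individual genotype counts.

    ``geno_a``/``geno_b`` are integer vectors with values in {0, 1, 2};
    element ``i`` of the result is ``m.cells[geno_a[i], geno_b[i]]``.
    Missing genotypes are not handled here -- exclude them upstream.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must have the same shape")
    for g in (ga, gb):
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("genotype counts must be 0, 1 or 2")
    return m.cells[ga, gb]


def bits_matrix(models: Sequence[DiseaseModel] | Iterable[DiseaseModel]) -> np.ndarray:
    """Stack models into an (n_models, 9) row-major 0/1 array."""
    return np.array([m.bits for m in models], dtype=np.int8)
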