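"""Case-control genotype container shared by simulation, I/O and screening."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeDataset", "MISSING"]

#: sentinel for a missing genotype in the int8 matrix
MISSING = -1


@dataclass
class GenotypeDataset:
    """Individuals x SNPs minor-allele counts with a binary phenotype.

    Parameters
    ----------
    genotypes : ndarray of shape (n_individuals, n_snps), int8
        Minor-allele counts in {0, 1, 2}; ``-1`` marks missing.
    phenotype : ndarray of shape (n_individuals,), int8
        1 = case, 0 = control.
    snp_ids : list of str, optional
        Defaults to ``snp1..snpP``.
    orient : bool, default True
        If True, columns whose control-sample allele frequency exceeds
        0.5 are flipped (count -> 2 - count) so the minor allele is
        counted; flipped columns are recorded in ``flipped``.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    orient: bool = True
    flipped: np.ndarray = field(init=False)
    control_maf: np.ndarray = field(init=False)

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotype, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-dimensional")
        if y.shape != (g.shape[0],):
            raise ValueError("phenotype length must match the number of individuals")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("phenotype must be binary (0 = control, 1 = case)")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("need at least one case and one control")
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(np.asarray(g)[~valid])
            raise ValueError(f"genotype values must be 0/1/2 or missing; found {bad}")
        g = g.astype(np.int8).copy()
        self.phenotype = y
        if not self.snp_ids:
            self.snp_ids = [f"snp{i + 1}" for i in range(g.shape[1])]
        elif len(self.snp_ids) != g.shape[1]:
            raise ValueError("snp_ids length must match the number of SNPs")

        freq = self._control_freq(g, y)
        if self.orient:
            flip = freq > 0.5
            if flip.any():
                cols = g[:, flip]
                obs = cols != MISSING
                cols[obs] = 2 - cols[obs]
                g[:, flip] = cols
                freq = self._control_freq(g, y)
        else:
            flip = np.zeros(g.shape[1], dtype=bool)
        self.genotypes = g
        self.flipped = flip
        self.control_maf = freq

    @staticmethod
    def _control_freq(g: np.ndarray, y: np.ndarray) -> np.ndarray:
        ctrl = g[y == 0]
        obs = ctrl != MISSING
        counts = np.where(obs, ctrl, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
        return freq

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def case_control_ratio(self) -> float:
        return self.n_cases / self.n_controls
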