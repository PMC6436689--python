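"""Chi-square screening of SNP pairs under three model-selection rules.

For every unordered SNP pair a method picks a binary disease model, the
model splits the sample into high-/low-risk groups, and the pair's
(nominal) association with the phenotype is the 1-df Pearson chi-square
of the induced 2x2 risk-by-status table.  The three rules are:

* **MDR** -- a genotype cell is high-risk when its case:control ratio
  reaches the sample ratio (cells with cases but no controls are high
  risk; empty cells are low risk);
* **RS** ("ratio split") -- cells are sorted by case:control ratio and
  the 8 nested top-x splits are tested; the best-scoring split wins;
* **PTY** -- candidates are restricted to an a-priori prototype library
  keyed by the pair's control-MAF bins; locus-asymmetric prototypes are
  tested in both orientations.

The *marginal* procedure scores every pair independently.  The
*sequential* procedure selects pairs one at a time, re-scoring each
remaining pair by the chi-square of the OR-combination of its risk
vector with those of the pairs already selected.

All statistics here are "nominal": the model was chosen to fit the same
data, so under the null the statistics are inflated relative to their
chi-square(1) reference (least so for PTY).

Everything is vectorized across pairs: per-status genotype one-hot
matrices are multiplied once to obtain all 3x3 pair tables, and model
evaluation reduces to small matrix products against 9-bit model rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dataset import GenotypeDataset, MISSING
from .disease_models import DiseaseModel, enumerate_nontrivial
from .prototype_selection import PrototypeLibrary, assign_bin

__all__ = [
    "PairContingency",
    "PairScore",
    "ScreenHistory",
    "pair_contingency",
    "chi2_test",
    "select_model_mdr",
    "select_model_rs",
    "select_model_pty",
    "marginal_screen",
    "sequential_screen",
    "EpistasisScreener",
]

METHODS = ("pty", "mdr", "rs")


@dataclass(frozen=True)
class PairContingency:
    """3x3x2 genotype-by-status counts for one SNP pair (complete cases)."""

    counts: np.ndarray  # (3, 3, 2); last axis: 0 = control, 1 = case

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (3, 3, 2) or (c < 0).any():
            raise ValueError("counts must be a non-negative (3, 3, 2) array")

    @property
    def case_cells(self) -> np.ndarray:
        """Row-major 9-vector of case counts."""
        return self.counts[:, :, 1].ravel().astype(float)

    @property
    def control_cells(self) -> np.ndarray:
        return self.counts[:, :, 0].ravel().astype(float)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PairScore:
    """A screened SNP pair with its chosen model and nominal statistic."""

    snp_i: int
    snp_j: int
    method: str
    model: DiseaseModel
    chi2: float
    pvalue: float

    def __post_init__(self):
        if self.chi2 < 0 or not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("chi2 must be >= 0 and pvalue in [0, 1]")


class ScreenHistory:
    """Ordered (pair, model) selections with their combined risk vector."""

    def __init__(self, n_individuals: int):
        self.pairs: list[tuple[int, int]] = []
        self.models: list[DiseaseModel] = []
        self.risk = np.zeros(n_individuals, dtype=bool)

    def add(self, pair: tuple[int, int], model: DiseaseModel,
            risk_vector: np.ndarray) -> None:
        if pair in self.pairs:
            raise ValueError(f"pair {pair} already selected")
        self.pairs.append(pair)
        self.models.append(model)
        self.risk |= risk_vector.astype(bool)


# ---------------------------------------------------------------------------
# vectorized machinery


def _pair_axes(n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_snps, 1)


def _tables_for_subset(geno: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """All-pairs 3x3 tables for a row subset -> (n_pairs, 9), row-major in i.

    Individuals missing at either SNP of a pair contribute to no cell
    (their one-hot block is all zero), so each pair's table is exactly
    its complete-case tally.
    """
    n_snps = geno.shape[1]
    sub = geno[rows]
    onehot = (sub[:, :, None] == np.arange(3)).astype(np.float64)
    x = onehot.reshape(sub.shape[0], 3 * n_snps)
    c = x.T @ x
    blocks = c.reshape(n_snps, 3, n_snps, 3).transpose(0, 2, 1, 3)
    iu, ju = _pair_axes(n_snps)
    return blocks[iu, ju].reshape(len(iu), 9)


def _chi2_from_highs(a: np.ndarray, c: np.ndarray,
                     n1: np.ndarray, n0: np.ndarray,
                     correction: bool = True) -> np.ndarray:
    """Chi-square of 2x2 tables given case-high / control-high counts.

    ``a`` = cases called high risk, ``c`` = controls called high risk,
    ``n1``/``n0`` = case/control totals.  With ``correction`` (the
    default) the Yates continuity correction is applied, matching the
    convention of standard 2x2 test routines.  Degenerate margins give 0.
    """
    b = n1 - a
    d = n0 - c
    n = n1 + n0
    diff = np.abs(a * d - b * c)
    if correction:
        diff = np.maximum(diff - n / 2.0, 0.0)
    num = n * diff ** 2
    den = n1 * n0 * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return chi


def chi2_test(risk, status, correction: bool = True) -> tuple[float, float]:
    """1-df chi-square of a binary risk assignment against case status.

    Continuity-corrected by default (set ``correction=False`` for the
    plain Pearson statistic).  Degenerate margins (all one risk class,
    or a single status) return (0.0, 1.0) by convention.
    """
    risk = np.asarray(risk).astype(bool)
    status = np.asarray(status).astype(bool)
    if risk.shape != status.shape:
        raise ValueError("risk and status must have the same length")
    if risk.size == 0:
        raise ValueError("empty vectors")
    a = float(np.sum(risk & status))
    n1 = float(np.sum(status))
    c = float(np.sum(risk & ~status))
    n0 = float(risk.size - n1)
    chi = float(_chi2_from_highs(np.array(a), np.array(c),
                                 np.array(n1), np.array(n0),
                                 correction=correction))
    return chi, float(stats.chi2.sf(chi, df=1))


def pair_contingency(ds: GenotypeDataset, i: int, j: int) -> PairContingency:
    """Complete-case 3x3x2 tally for SNPs ``i`` and ``j``."""
    if i == j:
        raise ValueError("need two distinct SNPs")
    n_snps = ds.n_snps
    if not (0 <= i < n_snps and 0 <= j < n_snps):
        raise ValueError(f"SNP indices out of range for {n_snps} SNPs")
    ga, gb = ds.genotypes[:, i], ds.genotypes[:, j]
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise ValueError(f"no complete cases for pair ({i}, {j})")
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    np.add.at(counts, (ga[ok], gb[ok], ds.phenotype[ok]), 1)
    return PairContingency(counts=counts)


# per-method model choice, vectorized over a block of pairs -----------------


def _mdr_models(nc: np.ndarray, no: np.ndarray, threshold: float) -> np.ndarray:
    """High-risk masks (n_pairs, 9): case:control ratio >= threshold."""
    return (nc >= threshold * no) & ((nc + no) > 0)


def _rs_candidates(nc: np.ndarray, no: np.ndarray) -> np.ndarray:
    """Nested top-x masks (n_pairs, 8, 9) from the sorted ratio order.

    Empty cells rank last; ratio ties break by row-major cell index
    (stable sort).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(no > 0, nc / np.maximum(no, 1.0),
                         np.where(nc > 0, np.inf, -np.inf))
    order = np.argsort(-ratio, axis=1, kind="stable")
    npairs = nc.shape[0]
    masks = np.zeros((npairs, 8, 9), dtype=bool)
    rows = np.arange(npairs)
    for x in range(8):
        # the cell ranked x is high risk for every candidate top-(x+1) .. top-8
        masks[:, x:, :][rows, :, order[:, x]] = True
    return masks


def _score_model_masks(masks: np.ndarray, nc: np.ndarray, no: np.ndarray,
                       nc_high_const: np.ndarray | float = 0.0,
                       no_high_const: np.ndarray | float = 0.0,
                       n1: np.ndarray | None = None,
                       n0: np.ndarray | None = None) -> np.ndarray:
    """Chi-square of each candidate mask; supports per-pair OR-history constants.

    ``masks`` is (n_pairs, n_cand, 9) or (n_cand, 9) shared across pairs.
    ``nc``/``no`` are the case/control cell counts the masks apply to
    (history-low-risk subset for sequential rounds); the ``*_const``
    terms add individuals already high risk through the history.
    """
    if n1 is None:
        n1 = nc.sum(axis=1) + np.asarray(nc_high_const)
    if n0 is None:
        n0 = no.sum(axis=1) + np.asarray(no_high_const)
    if masks.ndim == 2:
        a = nc @ masks.T + np.asarray(nc_high_const)[..., None]
        c = no @ masks.T + np.asarray(no_high_const)[..., None]
    else:
        a = np.einsum("pk,pck->pc", nc, masks) + np.asarray(nc_high_const)[..., None]
        c = np.einsum("pk,pck->pc", no, masks) + np.asarray(no_high_const)[..., None]
    return _chi2_from_highs(a, c, n1[:, None], n0[:, None])


def _pty_candidates(prototypes: Sequence[DiseaseModel]) -> tuple[np.ndarray, list[DiseaseModel]]:
    """Candidate bit rows: each prototype, then its transpose when asymmetric.

    Order (library order, untransposed before transposed) is the
    tie-break order; duplicates arising from symmetric prototypes are
    not repeated.
    """
    if not prototypes:
        raise ValueError("empty prototype list")
    cands: list[DiseaseModel] = []
    seen: set[str] = set()
    for m in prototypes:
        for cand in (m, m.transpose()):
            if cand.id not in seen:
                seen.add(cand.id)
                cands.append(cand)
    bits = np.array([m.bits for m in cands], dtype=float)
    return bits, cands


def _snp_bins(ds: GenotypeDataset, library: PrototypeLibrary) -> np.ndarray:
    maf = np.nan_to_num(ds.control_maf, nan=0.25)
    maf = np.clip(maf, 1e-9, 0.5)
    return np.array([assign_bin(q, library.bin_grid) for q in maf])


def _pty_groups(ds: GenotypeDataset, library: PrototypeLibrary,
                iu: np.ndarray, ju: np.ndarray):
    """Yield (pair-row indices, candidate bits, candidate models) per bin pair."""
    bins = _snp_bins(ds, library)
    keys = np.stack([bins[iu], bins[ju]], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g, (ba, bb) in enumerate(uniq):
        rows = np.where(inverse == g)[0]
        protos = library.entry(float(ba), float(bb)).prototypes()
        bits, cands = _pty_candidates(protos)
        yield rows, bits, cands


# single-pair wrappers -------------------------------------------------------


def _pvalues(chi: np.ndarray) -> np.ndarray:
    return stats.chi2.sf(chi, df=1)


def _single(c: PairContingency, masks: np.ndarray,
            models: list[DiseaseModel]) -> tuple[DiseaseModel, float, float]:
    nc = c.case_cells[None, :]
    no = c.control_cells[None, :]
    chi = _score_model_masks(masks.astype(float), nc, no)[0]
    best = int(np.argmax(chi))
    return models[best], float(chi[best]), float(_pvalues(chi[best]))


def select_model_mdr(c: PairContingency,
                     ratio_threshold: float | None = None
                     ) -> tuple[DiseaseModel, float, float]:
    """MDR rule: threshold each cell's case:control ratio.

    ``ratio_threshold`` defaults to the table's overall case:control
    ratio (1 on a balanced sample).
    """
    nc, no = c.case_cells, c.control_cells
    if ratio_threshold is None:
        n0 = no.sum()
        ratio_threshold = nc.sum() / n0 if n0 > 0 else 1.0
    mask = _mdr_models(nc[None, :], no[None, :], ratio_threshold)
    model = DiseaseModel(mask[0].astype(np.int8).reshape(3, 3))
    return _single(c, mask[0][None, :], [model])


def select_model_rs(c: PairContingency) -> tuple[DiseaseModel, float, float]:
    """Ratio-split rule: best of the 8 nested sorted-ratio partitions."""
    masks = _rs_candidates(c.case_cells[None, :], c.control_cells[None, :])[0]
    models = [DiseaseModel(m.astype(np.int8).reshape(3, 3)) for m in masks]
    return _single(c, masks, models)


def select_model_pty(c: PairContingency, prototypes: Sequence[DiseaseModel]
                     ) -> tuple[DiseaseModel, float, float]:
    """Prototype rule: best prototype (either orientation) by chi-square."""
    bits, cands = _pty_candidates(prototypes)
    return _single(c, bits, cands)


# screening procedures -------------------------------------------------------


def _marginal_core(ds: GenotypeDataset, method: str,
                   library: PrototypeLibrary | None,
                   mdr_threshold: float | None):
    """Per-pair chosen model bits and chi-square for all pairs."""
    iu, ju = _pair_axes(ds.n_snps)
    cases = np.where(ds.phenotype == 1)[0]
    ctrls = np.where(ds.phenotype == 0)[0]
    nc = _tables_for_subset(ds.genotypes, cases)
    no = _tables_for_subset(ds.genotypes, ctrls)
    npairs = len(iu)
    chi = np.zeros(npairs)
    model_bits = np.zeros((npairs, 9), dtype=np.int8)

    if method == "mdr":
        thr = mdr_threshold if mdr_threshold is not None else ds.case_control_ratio
        masks = _mdr_models(nc, no, thr)
        a = (nc * masks).sum(axis=1)
        c = (no * masks).sum(axis=1)
        chi = _chi2_from_highs(a, c, nc.sum(axis=1), no.sum(axis=1))
        model_bits = masks.astype(np.int8)
    elif method == "rs":
        masks = _rs_candidates(nc, no)
        scores = _score_model_masks(masks, nc, no)
        best = np.argmax(scores, axis=1)  # first max -> smallest x
        chi = scores[np.arange(npairs), best]
        model_bits = masks[np.arange(npairs), best].astype(np.int8)
    elif method == "pty":
        if library is None:
            raise ValueError("PTY screening requires a prototype library")
        for rows, bits, cands in _pty_groups(ds, library, iu, ju):
            scores = _score_model_masks(bits, nc[rows], no[rows])
            best = np.argmax(scores, axis=1)
            chi[rows] = scores[np.arange(len(rows)), best]
            model_bits[rows] = bits[best].astype(np.int8)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return iu, ju, nc, no, chi, model_bits


def _scores_frame(iu, ju, chi, model_bits, method, snp_ids) -> pd.DataFrame:
    order = np.lexsort((ju, iu, -chi))
    ids = ["".join(str(b) for b in row) for row in model_bits]
    df = pd.DataFrame({
        "snp_i": iu[order],
        "snp_j": ju[order],
        "snp_i_id": [snp_ids[k] for k in iu[order]],
        "snp_j_id": [snp_ids[k] for k in ju[order]],
        "method": method,
        "model_id": [ids[k] for k in order],
        "chi2": chi[order],
        "pvalue": _pvalues(chi[order]),
    })
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def marginal_screen(ds: GenotypeDataset, method: str,
                    library: PrototypeLibrary | None = None,
                    mdr_threshold: float | None = None) -> pd.DataFrame:
    """Score every unordered SNP pair independently.

    Returns a DataFrame sorted by chi-square (descending, ties by pair
    index) with one row per pair: indices, ids, chosen 9-bit model,
    chi2, nominal p-value and rank.
    """
    if ds.n_snps < 2:
        raise ValueError("need at least 2 SNPs to screen pairs")
    iu, ju, _, _, chi, model_bits = _marginal_core(ds, method, library, mdr_threshold)
    return _scores_frame(iu, ju, chi, model_bits, method, ds.snp_ids)


def sequential_screen(ds: GenotypeDataset, method: str, n_select: int,
                      library: PrototypeLibrary | None = None,
                      refit: bool = True,
                      mdr_threshold: float | None = None
                      ) -> tuple[pd.DataFrame, ScreenHistory]:
    """Select ``n_select`` pairs one at a time by conditional chi-square.

    Round 1 is the marginal top pair.  Later rounds re-score every
    unselected pair by the chi-square of OR(history risk, candidate
    risk) against the phenotype, re-choosing the candidate's model per
    the method's rule (``refit=True``) or keeping its marginal choice.
    MDR's model is ratio-determined and identical either way.

    Returns the per-round selections (conditional chi2 in later rounds)
    and the accumulated history.  Individuals missing at a selected
    pair contribute risk 0 to the history OR.
    """
    if ds.n_snps < 2:
        raise ValueError("need at least 2 SNPs to screen pairs")
    iu, ju, nc, no, chi_marg, bits_marg = _marginal_core(
        ds, method, library, mdr_threshold)
    npairs = len(iu)
    if not 1 <= n_select <= npairs:
        raise ValueError(f"n_select must be in [1, {npairs}], got {n_select}")

    y = ds.phenotype.astype(bool)
    history = ScreenHistory(ds.n_individuals)
    taken = np.zeros(npairs, dtype=bool)
    rows_out = []

    # precompute per-method candidate structures from the full data
    if method == "rs":
        rs_masks = _rs_candidates(nc, no)          # (npairs, 8, 9)
    if method == "pty":
        pty_groups = list(_pty_groups(ds, library, iu, ju))
    if method == "mdr":
        thr = mdr_threshold if mdr_threshold is not None else ds.case_control_ratio
        mdr_masks = _mdr_models(nc, no, thr)

    def pick(chi_vec: np.ndarray) -> int:
        masked = np.where(taken, -np.inf, chi_vec)
        order = np.lexsort((ju, iu, -masked))
        return int(order[0])

    for rnd in range(1, n_select + 1):
        if rnd == 1:
            chi_round = chi_marg
            bits_round = bits_marg
        else:
            h = history.risk
            low = np.where(~h)[0]
            high = np.where(h)[0]
            nc0 = _tables_for_subset(ds.genotypes, low[y[low]])
            no0 = _tables_for_subset(ds.genotypes, low[~y[low]])
            nc1c = _tables_for_subset(ds.genotypes, high[y[high]]).sum(axis=1)
            no1c = _tables_for_subset(ds.genotypes, high[~y[high]]).sum(axis=1)
            n1 = nc0.sum(axis=1) + nc1c
            n0 = no0.sum(axis=1) + no1c
            if method == "mdr":
                a = (nc0 * mdr_masks).sum(axis=1) + nc1c
                c = (no0 * mdr_masks).sum(axis=1) + no1c
                chi_round = _chi2_from_highs(a, c, n1, n0)
                bits_round = mdr_masks.astype(np.int8)
            elif method == "rs":
                scores = _score_model_masks(rs_masks, nc0, no0, nc1c, no1c, n1, n0)
                if not refit:
                    scores_m = _score_model_masks(rs_masks, nc, no)
                    best = np.argmax(scores_m, axis=1)
                else:
                    best = np.argmax(scores, axis=1)
                chi_round = scores[np.arange(npairs), best]
                bits_round = rs_masks[np.arange(npairs), best].astype(np.int8)
            else:  # pty
                chi_round = np.zeros(npairs)
                bits_round = np.zeros((npairs, 9), dtype=np.int8)
                for rows, bits, _ in pty_groups:
                    scores = _score_model_masks(bits, nc0[rows], no0[rows],
                                                nc1c[rows], no1c[rows],
                                                n1[rows], n0[rows])
                    if not refit:
                        scores_m = _score_model_masks(bits, nc[rows], no[rows])
                        best = np.argmax(scores_m, axis=1)
                    else:
                        best = np.argmax(scores, axis=1)
                    chi_round[rows] = scores[np.arange(len(rows)), best]
                    bits_round[rows] = bits[best].astype(np.int8)

        sel = pick(chi_round)
        taken[sel] = True
        i, j = int(iu[sel]), int(ju[sel])
        model = DiseaseModel(bits_round[sel].reshape(3, 3))
        ga, gb = ds.genotypes[:, i], ds.genotypes[:, j]
        ok = (ga != MISSING) & (gb != MISSING)
        risk = np.zeros(ds.n_individuals, dtype=bool)
        risk[ok] = model.cells[ga[ok], gb[ok]].astype(bool)
        history.add((i, j), model, risk)
        rows_out.append({
            "round": rnd, "snp_i": i, "snp_j": j,
            "snp_i_id": ds.snp_ids[i], "snp_j_id": ds.snp_ids[j],
            "method": method, "model_id": model.id,
            "chi2": float(chi_round[sel]),
            "pvalue": float(_pvalues(chi_round[sel])),
        })

    return pd.DataFrame(rows_out), history


class EpistasisScreener(BaseEstimator):
    """Case-control SNP-pair interaction screen (sklearn-style).

    Parameters
    ----------
    method : {'pty', 'mdr', 'rs'}, default 'pty'
        Disease-model selection rule per pair.
    procedure : {'marginal', 'sequential'}, default 'marginal'
    library : PrototypeLibrary, optional
        Required when ``method='pty'``.
    n_select : int, optional
        Number of pairs to pick with the sequential procedure.
    alpha : float, optional
        Nominal p-value threshold used by :meth:`detected_pairs`.
    refit_sequential : bool, default True
        Re-choose each candidate's model per round in the sequential
        procedure (RS/PTY); otherwise reuse the marginal choice.
    mdr_ratio_threshold : float, optional
        Override for MDR's case:control ratio threshold (defaults to
        the sample ratio).

    Attributes
    ----------
    scores_ : DataFrame
        Ranked pair scores (marginal) or per-round selections
        (sequential).
    history_ : ScreenHistory
        Sequential selections with the combined risk vector (sequential
        procedure only).
    n_pairs_ : int
    """

    def __init__(self, method: str = "pty", procedure: str = "marginal",
                 library: PrototypeLibrary | None = None,
                 n_select: int | None = None, alpha: float | None = None,
                 refit_sequential: bool = True,
                 mdr_ratio_threshold: float | None = None):
        self.method = method
        self.procedure = procedure
        self.library = library
        self.n_select = n_select
        self.alpha = alpha
        self.refit_sequential = refit_sequential
        self.mdr_ratio_threshold = mdr_ratio_threshold

    def _dataset(self, X, y) -> GenotypeDataset:
        if isinstance(X, GenotypeDataset):
            return X
        if y is None:
            raise ValueError("y (phenotype) is required when X is an array")
        return GenotypeDataset(genotypes=np.asarray(X), phenotype=np.asarray(y))

    def fit(self, X, y=None):
        """Screen a dataset; X may be a GenotypeDataset or (n, p) count matrix."""
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.procedure not in ("marginal", "sequential"):
            raise ValueError("procedure must be 'marginal' or 'sequential'")
        ds = self._dataset(X, y)
        if self.procedure == "marginal":
            self.scores_ = marginal_screen(ds, self.method, self.library,
                                           self.mdr_ratio_threshold)
            self.history_ = None
        else:
            if self.n_select is None:
                raise ValueError("sequential procedure requires n_select")
            self.scores_, self.history_ = sequential_screen(
                ds, self.method, self.n_select, self.library,
                refit=self.refit_sequential,
                mdr_threshold=self.mdr_ratio_threshold)
        self.n_pairs_ = ds.n_snps * (ds.n_snps - 1) // 2
        return self

    def detected_pairs(self, alpha: float | None = None) -> set[tuple[int, int]]:
        """Pairs whose nominal p-value falls below ``alpha``."""
        alpha = alpha if alpha is not None else self.alpha
        if alpha is None:
            raise ValueError("no alpha threshold given")
        df = self.scores_
        hit = df[df["pvalue"] < alpha]
        return {(int(r.snp_i), int(r.snp_j)) for r in hit.itertuples()}
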