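"""Population-calibrated similarity metric between disease models.

The metric asks: if the *true* disease mechanism were the two-level model
``M`` and we screened with a different model ``M'`` instead, how often
would the two agree in assigning individuals of a case-control sample to
high- vs low-risk groups?  Agreement is quantified by the phi coefficient
of the 2x2 cross-classification of the two risk assignments, evaluated in
closed form over a hypothetical infinite sample rather than by counting
individuals.

Inputs to the closed form:

* Hardy-Weinberg genotype probabilities at the two SNPs' minor-allele
  frequencies, which give the weight ``W_kl`` of genotype combinations
  classified ``k`` by ``M`` and ``l`` by ``M'``;
* the penetrances ``P1 > P0`` of the true model's risky / non-risky
  classes, recovered from an assumed disease prevalence ``P(D)`` and
  heritability ``h^2`` (the standardized genetic variance);
* the sample's case-control ratio ``r``, which re-weights agreement on
  risky genotypes more heavily than on non-risky ones whenever the
  sample is enriched for cases (``r`` above the population ratio
  ``r0 = P(D)/(1-P(D))``).

``distance = 1 - phi`` is *directional*: the first argument plays the
prototype, the second the truth.  A symmetrized average is provided for
embedding/visualisation purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .disease_models import DiseaseModel, bits_matrix

__all__ = [
    "PopulationContext",
    "JointWeights",
    "PenetrancePair",
    "EmpiricalConcordance",
    "InfeasibleModelError",
    "hwe_probs",
    "genotype_probs",
    "joint_weights",
    "solve_penetrance",
    "phi",
    "distance",
    "symmetrized_distance",
    "phi_empirical",
    "distance_matrix",
]

#: weights below this are treated as exactly zero to avoid catastrophic
#: cancellation in the phi denominator
WEIGHT_FLOOR = 1e-15


class InfeasibleModelError(ValueError):
    """A model/context combination admits no valid two-level penetrance."""


@dataclass(frozen=True)
class PopulationContext:
    """Population and sampling parameters driving the metric.

    Parameters
    ----------
    maf_a, maf_b : float
        Minor-allele frequencies of the two SNPs, in (0, 0.5].
    prevalence : float, default 0.02
        Disease prevalence P(D).
    heritability : float, default 0.02
        Standardized genetic variance h^2 attributed to the pair.
    sample_ratio : float, default 1.0
        Cases per control in the sample (r); 1 for balanced designs.
    """

    maf_a: float
    maf_b: float
    prevalence: float = 0.02
    heritability: float = 0.02
    sample_ratio: float = 1.0

    def __post_init__(self):
        for name, q in (("maf_a", self.maf_a), ("maf_b", self.maf_b)):
            if not 0.0 < q <= 0.5:
                raise ValueError(f"{name} must be in (0, 0.5], got {q}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.heritability < 0.0:
            raise ValueError("heritability must be >= 0")
        if self.sample_ratio <= 0.0:
            raise ValueError("sample_ratio must be > 0")

    @property
    def population_ratio(self) -> float:
        """r0 = P(D) / (1 - P(D)), the population-wide case-control ratio."""
        return self.prevalence / (1.0 - self.prevalence)


@dataclass(frozen=True)
class JointWeights:
    """Genotype-probability mass cross-classified by two models.

    ``w11`` is the mass of combinations risky under both the true model
    (first index) and the prototype (second index), etc.
    """

    w11: float
    w10: float
    w01: float
    w00: float

    def __post_init__(self):
        total = self.w11 + self.w10 + self.w01 + self.w00
        if min(self.w11, self.w10, self.w01, self.w00) < -1e-12:
            raise ValueError("joint weights must be non-negative")
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"joint weights must sum to 1, got {total}")

    @property
    def w1dot(self) -> float:
        """Risk mass of the true model."""
        return self.w11 + self.w10

    @property
    def w0dot(self) -> float:
        return self.w01 + self.w00

    @property
    def wdot1(self) -> float:
        """Risk mass of the prototype."""
        return self.w11 + self.w01

    @property
    def wdot0(self) -> float:
        return self.w10 + self.w00


@dataclass(frozen=True)
class PenetrancePair:
    """Penetrances of the risky (p1) and non-risky (p0) classes."""

    p1: float
    p0: float

    def __post_init__(self):
        if not (0.0 <= self.p0 <= self.p1 <= 1.0):
            raise ValueError(f"need 0 <= p0 <= p1 <= 1, got ({self.p1}, {self.p0})")


@dataclass(frozen=True)
class EmpiricalConcordance:
    """Counts of individuals cross-classified by two binary risk calls."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")


def hwe_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities (major hom, het, minor hom)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    q = maf
    return ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q)


def genotype_probs(maf_a: float, maf_b: float) -> np.ndarray:
    """Row-major 9-vector of two-locus HWE genotype probabilities."""
    pa = np.array(hwe_probs(maf_a))
    pb = np.array(hwe_probs(maf_b))
    return np.outer(pa, pb).ravel()


def joint_weights(m_true: DiseaseModel, m_proto: DiseaseModel,
                  maf_a: float, maf_b: float) -> JointWeights:
    """Cross-classify HWE genotype mass by the two models' risk calls."""
    p = genotype_probs(maf_a, maf_b)
    t = m_true.bits.astype(bool)
    s = m_proto.bits.astype(bool)
    return JointWeights(
        w11=float(p[t & s].sum()),
        w10=float(p[t & ~s].sum()),
        w01=float(p[~t & s].sum()),
        w00=float(p[~t & ~s].sum()),
    )


def solve_penetrance(w1dot: float, prevalence: float, h2: float) -> PenetrancePair:
    """Recover the two penetrance levels of a two-level disease model.

    Given the risk mass ``w1dot`` of the true model and target prevalence
    and heritability, the unique solution with ``p1 >= p0`` is

        p1 = P(D) + sqrt((w0./w1.) * P(D) (1-P(D)) h^2)
        p0 = P(D) - sqrt((w1./w0.) * P(D) (1-P(D)) h^2)

    Raises
    ------
    InfeasibleModelError
        If ``p0 < 0`` or ``p1 > 1`` -- the heritability is too large for
        this risk mass and prevalence.
    """
    if not 0.0 < w1dot < 1.0:
        raise InfeasibleModelError(f"risk mass must be in (0, 1), got {w1dot}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if h2 < 0.0:
        raise ValueError("heritability must be >= 0")
    w0dot = 1.0 - w1dot
    core = prevalence * (1.0 - prevalence) * h2
    p1 = prevalence + np.sqrt(w0dot / w1dot * core)
    p0 = prevalence - np.sqrt(w1dot / w0dot * core)
    if p0 < 0.0 or p1 > 1.0:
        raise InfeasibleModelError(
            f"no valid penetrances for risk mass {w1dot:.4g} at "
            f"prevalence {prevalence}, h2 {h2}: p1={p1:.4g}, p0={p0:.4g}"
        )
    return PenetrancePair(p1=float(p1), p0=float(p0))


def _uv(pen: PenetrancePair, ctx: PopulationContext) -> tuple[float, float]:
    r, pd = ctx.sample_ratio, ctx.prevalence
    u = r * pen.p1 * (1.0 - pd) + (1.0 - pen.p1) * pd
    v = r * pen.p0 * (1.0 - pd) + (1.0 - pen.p0) * pd
    return u, v


def phi(m_proto: DiseaseModel, m_true: DiseaseModel,
        ctx: PopulationContext) -> float:
    """Phi-coefficient concordance of a prototype with a true model.

    Returns a value in [-1, 1]; 1 when the models classify identically,
    -1 when one is the complement of the other.
    """
    w = joint_weights(m_true, m_proto, ctx.maf_a, ctx.maf_b)
    if not WEIGHT_FLOOR < w.wdot1 < 1.0 - WEIGHT_FLOOR:
        raise InfeasibleModelError(
            f"prototype {m_proto.id} is degenerate at MAFs "
            f"({ctx.maf_a}, {ctx.maf_b})"
        )
    pen = solve_penetrance(w.w1dot, ctx.prevalence, ctx.heritability)
    u, v = _uv(pen, ctx)
    w11 = w.w11 if w.w11 > WEIGHT_FLOOR else 0.0
    w10 = w.w10 if w.w10 > WEIGHT_FLOOR else 0.0
    w01 = w.w01 if w.w01 > WEIGHT_FLOOR else 0.0
    w00 = w.w00 if w.w00 > WEIGHT_FLOOR else 0.0
    denom_sq = ((u / v) * w11 + w01) * (w10 + (v / u) * w00) * w.w1dot * w.w0dot
    if denom_sq <= 0.0:
        raise InfeasibleModelError(
            f"degenerate phi denominator for prototype {m_proto.id} vs "
            f"true {m_true.id} at MAFs ({ctx.maf_a}, {ctx.maf_b})"
        )
    return float((w11 * w00 - w10 * w01) / np.sqrt(denom_sq))


def distance(m_proto: DiseaseModel, m_true: DiseaseModel,
             ctx: PopulationContext) -> float:
    """Directional distance 1 - phi(prototype, truth), in [0, 2]."""
    return 1.0 - phi(m_proto, m_true, ctx)


def symmetrized_distance(m1: DiseaseModel, m2: DiseaseModel,
                         ctx: PopulationContext) -> float:
    """Average of the two directional distances; symmetric in (m1, m2)."""
    return 0.5 * (distance(m1, m2, ctx) + distance(m2, m1, ctx))


def phi_empirical(c: EmpiricalConcordance) -> float:
    """Phi coefficient of an observed 2x2 concordance table."""
    n1d = c.n11 + c.n10
    n0d = c.n01 + c.n00
    nd1 = c.n11 + c.n01
    nd0 = c.n10 + c.n00
    if min(n1d, n0d, nd1, nd0) == 0:
        raise ValueError("phi is undefined when a margin of the 2x2 table is zero")
    num = c.n11 * c.n00 - c.n10 * c.n01
    return float(num / np.sqrt(float(n1d) * n0d * nd1 * nd0))


# ---------------------------------------------------------------------------
# vectorized form used for library construction


def feasible_mask(models: Sequence[DiseaseModel], ctx: PopulationContext) -> np.ndarray:
    """Which models admit valid penetrances as the *true* model under ctx.

    A model is infeasible when its HWE risk mass is so large (or small)
    that the implied p0 drops below 0 (or p1 exceeds 1) at the context's
    prevalence and heritability.
    """
    bits = bits_matrix(models).astype(float)
    p = genotype_probs(ctx.maf_a, ctx.maf_b)
    w1 = bits @ p
    w0 = 1.0 - w1
    core = ctx.prevalence * (1.0 - ctx.prevalence) * ctx.heritability
    ok = (w1 > WEIGHT_FLOOR) & (w0 > WEIGHT_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ctx.prevalence + np.sqrt(np.where(ok, w0 / np.maximum(w1, WEIGHT_FLOOR), np.inf) * core)
        p0 = ctx.prevalence - np.sqrt(np.where(ok, w1 / np.maximum(w0, WEIGHT_FLOOR), np.inf) * core)
    return ok & (p0 >= 0.0) & (p1 <= 1.0)


def distance_matrix(models: Sequence[DiseaseModel], ctx: PopulationContext,
                    symmetrized: bool = False) -> np.ndarray:
    """Pairwise directional distances ``D[i, j] = d(models[i], models[j])``.

    Row ``i`` plays the prototype, column ``j`` the true model --
    matching the orientation used by prototype clustering.  All models
    must be feasible under ``ctx`` (see :func:`feasible_mask`).
    """
    bits = bits_matrix(models).astype(float)
    p = genotype_probs(ctx.maf_a, ctx.maf_b)
    n = len(models)

    w11 = (bits * p) @ bits.T          # w11[s, t] mass risky under both
    mass = bits @ p                    # per-model risk mass
    # orientation: rows proto (s), columns true (t)
    w11 = w11.T.copy()                 # now [t, s]; symmetric anyway but explicit
    w1 = mass                          # true-model risk mass, per column index t
    wdot1 = mass                       # proto risk mass, per row index s

    if not feasible_mask(models, ctx).all():
        raise InfeasibleModelError("distance_matrix requires all models feasible; "
                                   "filter with feasible_mask first")

    core = ctx.prevalence * (1.0 - ctx.prevalence) * ctx.heritability
    p1 = ctx.prevalence + np.sqrt((1.0 - w1) / w1 * core)
    p0 = ctx.prevalence - np.sqrt(w1 / (1.0 - w1) * core)
    r, pd = ctx.sample_ratio, ctx.prevalence
    u = r * p1 * (1.0 - pd) + (1.0 - p1) * pd
    v = r * p0 * (1.0 - pd) + (1.0 - p0) * pd
    uv = u / v                         # per true model t

    # build W_kl with rows=true t, cols=proto s
    W11 = w11                                  # [t, s]
    W10 = w1[:, None] - W11
    W01 = wdot1[None, :] - W11
    W00 = 1.0 - W11 - W10 - W01
    for arr in (W11, W10, W01, W00):
        arr[arr < WEIGHT_FLOOR] = 0.0

    num = W11 * W00 - W10 * W01
    denom_sq = ((uv[:, None] * W11 + W01) * (W10 + W00 / uv[:, None])
                * (w1 * (1.0 - w1))[:, None])
    if (denom_sq <= 0.0).any():
        raise InfeasibleModelError("degenerate phi denominator in distance matrix")
    phi_ts = num / np.sqrt(denom_sq)           # phi(proto s, true t) at [t, s]
    d = 1.0 - phi_ts.T                         # D[s, t] = d(proto s, true t)
    if symmetrized:
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
    return d
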