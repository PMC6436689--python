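"""Synthetic case-control scenario generation.

Every study condition used by the test-bench is generated here:

* single causal SNP pairs whose penetrance table is either given
  explicitly (the "DMN" pure-epistasis tables, additive tables) or
  parameterized by an odds family (threshold, dominant-dominant,
  modifying-effect, XOR, multiplicative, threshold-multiplicative) whose
  two parameters are calibrated numerically to a target prevalence and
  heritability at a given MAF;
* two-pair scenarios -- the "pathological" configuration in which a
  four-penetrance joint model makes the case-control ratio constant
  across one pair's genotype cells, and an independent-mechanism union
  of two additive pairs that tempts greedy methods into a spurious
  cross-pair selection;
* pure-null data with no genotype-phenotype association.

Sampling is retrospective: the causal genotype distribution conditional
on case/control status is computed exactly by Bayes' rule over the 9 (or
81) causal-genotype states with Hardy-Weinberg priors, cases and
controls are drawn from those conditionals, and noise SNPs are drawn
independently from Hardy-Weinberg proportions.  This is exact and fast
at realistic prevalences (a prospective scheme would reject ~98% of
draws at prevalence 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache, reduce
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .dataset import GenotypeDataset
from .disease_models import DiseaseModel
from .model_metric import hwe_probs

__all__ = [
    "ODDS_FAMILIES",
    "OddsModelSpec",
    "PenetranceModelSpec",
    "TwoPairScenario",
    "SimulationSpec",
    "prevalence_and_h2",
    "solve_alpha_theta",
    "pathological_p11",
    "combine_independent",
    "simulate_dataset",
    "null_dataset",
    "ScenarioPreset",
    "PRESETS",
    "DMN_TABLES",
    "ADDITIVE_TABLE",
]

# odds exponent patterns: cell odds = alpha * (1 + theta) ** exponent,
# rows/cols indexed by minor-allele count of the two SNPs
ODDS_FAMILIES: dict[str, np.ndarray] = {
    "T":   np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1]]),
    "DD":  np.array([[0, 0, 0], [0, 1, 1], [0, 1, 1]]),
    "MOD": np.array([[0, 0, 0], [0, 0, 1], [1, 1, 1]]),
    "XOR": np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]]),
    "ME":  np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4]]),
    "MET": np.array([[0, 0, 0], [0, 1, 2], [0, 2, 4]]),
}

# Pure-epistasis penetrance tables, printed with rows/columns AA, Aa, aa
# where the quoted "MAF" is the frequency of allele A itself.  Under that
# convention (genotype AA has probability MAF^2) each table has no
# single-SNP marginal effect.  Our genotype code counts copies of A, so
# generation uses the 180-degree-rotated table (see `dmn_generation_table`).
DMN_TABLES: dict[str, np.ndarray] = {
    "DMN1": np.array([[0.08, 0.07, 0.05], [0.10, 0.00, 0.10], [0.03, 0.10, 0.04]]),
    "DMN2": np.array([[0.00, 0.10, 0.09], [0.04, 0.01, 0.08], [0.07, 0.09, 0.03]]),
    "DMN3": np.array([[0.07, 0.05, 0.02], [0.05, 0.09, 0.01], [0.02, 0.01, 0.03]]),
    "DMN4": np.array([[0.09, 0.001, 0.02], [0.08, 0.07, 0.005], [0.003, 0.007, 0.02]]),
}

# additive main-effect table used by the spurious-pair scenario
ADDITIVE_TABLE = np.array([[0.0, 0.0, 0.1], [0.0, 0.0, 0.1], [0.1, 0.1, 0.2]])


def dmn_generation_table(name: str) -> np.ndarray:
    """A DMN penetrance table in minor-allele-count orientation.

    The published tables list genotypes AA, Aa, aa where the stated
    "MAF" is the frequency of allele A, so AA is the *rare* homozygote.
    Rotating the table 180 degrees expresses it in our convention
    (index = count of the frequency-q allele), under which all four
    tables have essentially zero single-locus association -- the
    property these models were designed for.
    """
    return DMN_TABLES[name][::-1, ::-1].copy()


@dataclass(frozen=True)
class OddsModelSpec:
    """An odds-parameterized penetrance model: odds = alpha*(1+theta)^e."""

    family: str
    alpha: float
    theta: float

    def __post_init__(self):
        if self.family not in ODDS_FAMILIES:
            raise ValueError(f"unknown odds family {self.family!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.theta <= -1:
            raise ValueError("theta must be > -1")

    def odds_table(self) -> np.ndarray:
        return self.alpha * (1.0 + self.theta) ** ODDS_FAMILIES[self.family]

    def penetrance_table(self) -> np.ndarray:
        o = self.odds_table()
        return o / (1.0 + o)


@dataclass(frozen=True)
class PenetranceModelSpec:
    """Explicit 3x3 penetrance table."""

    table: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 3) or (t < 0).any() or (t > 1).any():
            raise ValueError("penetrance table must be 3x3 with values in [0, 1]")
        if t.max() <= 0:
            raise ValueError("penetrance table must have at least one positive cell")
        object.__setattr__(self, "table", t)


@dataclass(frozen=True)
class TwoPairScenario:
    """Two independent SNP pairs with a joint four-level penetrance.

    ``model1``/``model2`` mark each pair's risky genotype cells; the
    penetrance of an individual depends only on whether each pair's
    genotype falls in its risky set: ``p11`` (both risky), ``p10``
    (first only), ``p01`` (second only), ``p00`` (neither).
    """

    model1: DiseaseModel
    model2: DiseaseModel
    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self):
        for name in ("p11", "p10", "p01", "p00"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def joint_penetrance(self) -> np.ndarray:
        """(3,3,3,3) table indexed by (gA, gB, gC, gD)."""
        p = np.array([[self.p00, self.p01], [self.p10, self.p11]])
        k = self.model1.cells  # (3,3) in {0,1}
        l = self.model2.cells
        return p[k[:, :, None, None], l[None, None, :, :]]


@dataclass(frozen=True)
class SimulationSpec:
    """Fully-specified retrospective sampling run.

    ``causal_penetrance`` has shape (3,)*2 or (3,)*4; ``causal_mafs``
    matches its number of axes.  ``noise_maf`` is either a single MAF
    for every noise SNP or ``("uniform", lo, hi)`` for per-SNP draws.
    """

    n_cases: int
    n_controls: int
    n_snps: int
    causal_penetrance: np.ndarray
    causal_mafs: tuple[float, ...]
    noise_maf: float | tuple = 0.25
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.causal_penetrance, dtype=float)
        if f.shape not in ((3, 3), (3, 3, 3, 3)):
            raise ValueError("causal penetrance must be (3,3) or (3,3,3,3)")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("penetrances must be in [0, 1]")
        if len(self.causal_mafs) != f.ndim:
            raise ValueError("need one causal MAF per causal SNP")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.n_snps < f.ndim:
            raise ValueError("n_snps smaller than the causal block")
        object.__setattr__(self, "causal_penetrance", f)


def prevalence_and_h2(pen: np.ndarray, maf_a: float, maf_b: float
                      ) -> tuple[float, float]:
    """Population prevalence and heritability of a 3x3 penetrance table.

    Under HWE, prevalence is the genotype-weighted mean penetrance and
    heritability the standardized penetrance variance
    ``sum((f - P)^2 pi) / (P (1 - P))``.
    """
    f = np.asarray(pen, dtype=float)
    if f.shape != (3, 3):
        raise ValueError("penetrance table must be 3x3")
    if f.max() <= 0:
        raise ValueError("heritability undefined for an all-zero penetrance table")
    pi = np.outer(hwe_probs(maf_a), hwe_probs(maf_b))
    pd = float((f * pi).sum())
    h2 = float((((f - pd) ** 2) * pi).sum() / (pd * (1.0 - pd)))
    return pd, h2


@lru_cache(maxsize=128)
def solve_alpha_theta(family: str, maf: float, prevalence: float = 0.02,
                      h2: float = 0.02) -> OddsModelSpec:
    """Calibrate an odds family to a target prevalence and heritability.

    Both SNPs share ``maf``.  The solution takes the ``theta > 0``
    branch; for each candidate theta, alpha is solved so the prevalence
    matches, and theta is then adjusted to match the heritability.
    Verified to round-trip through :func:`prevalence_and_h2` to 1e-8.
    """
    if family not in ODDS_FAMILIES:
        raise ValueError(f"unknown odds family {family!r}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if h2 < 0:
        raise ValueError("h2 must be >= 0")
    if h2 == 0:
        return OddsModelSpec(family, prevalence / (1.0 - prevalence), 0.0)

    def alpha_for(theta: float) -> float:
        def gap(log_alpha):
            spec = OddsModelSpec(family, float(np.exp(log_alpha)), theta)
            return prevalence_and_h2(spec.penetrance_table(), maf, maf)[0] - prevalence
        return float(np.exp(optimize.brentq(gap, -40.0, 10.0, xtol=1e-14)))

    def h2_gap(theta: float) -> float:
        spec = OddsModelSpec(family, alpha_for(theta), theta)
        return prevalence_and_h2(spec.penetrance_table(), maf, maf)[1] - h2

    lo, hi = 1e-9, 1.0
    while h2_gap(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError(
                f"cannot reach h2={h2} for family {family} at MAF {maf}, "
                f"prevalence {prevalence}")
    theta = float(optimize.brentq(h2_gap, lo, hi, xtol=1e-12))
    spec = OddsModelSpec(family, alpha_for(theta), theta)
    got = prevalence_and_h2(spec.penetrance_table(), maf, maf)
    if abs(got[0] - prevalence) > 1e-8 or abs(got[1] - h2) > 1e-8:
        raise RuntimeError(f"calibration failed to converge for {family}: {got}")
    return spec


def pathological_p11(p10: float, p01: float, p00: float,
                     model2: DiseaseModel, maf: float) -> float:
    """Penetrance p11 that equalizes case-control ratios across pair 1.

    In the two-pair scenario, choosing

        p11 = p01 - (sum_{j not risky} v_j / sum_{j risky} v_j) (p10 - p00)

    -- with ``v_j`` the HWE genotype probabilities of the second pair --
    makes the case-control ratio identical for all nine genotype cells
    of the first pair, so ratio-based model selection carries no signal.
    """
    for name, v in (("p10", p10), ("p01", p01), ("p00", p00)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if model2.is_trivial:
        raise ValueError("second pair's model must be non-trivial")
    pi = np.outer(hwe_probs(maf), hwe_probs(maf))
    risky = float((pi * model2.cells).sum())
    if risky <= 0:
        raise ValueError("second pair has zero risky genotype mass")
    nonrisky = 1.0 - risky
    p11 = p01 - (nonrisky / risky) * (p10 - p00)
    if not 0.0 <= p11 <= 1.0:
        raise ValueError(
            f"implied p11={p11:.4g} falls outside [0, 1]; "
            "choose different penetrances")
    return float(p11)


def combine_independent(pen1: np.ndarray, pen2: np.ndarray) -> np.ndarray:
    """Joint penetrance of two independently acting mechanisms.

    Disease occurs if either mechanism triggers it:
    ``1 - (1 - f1(g1)) (1 - f2(g2))``; returns a (3,3,3,3) table.
    """
    f1 = PenetranceModelSpec(pen1).table
    f2 = PenetranceModelSpec(pen2).table
    return 1.0 - (1.0 - f1)[:, :, None, None] * (1.0 - f2)[None, None, :, :]


def _causal_prior(mafs: Sequence[float]) -> np.ndarray:
    vecs = [np.array(hwe_probs(q)) for q in mafs]
    return reduce(np.multiply.outer, vecs)


def causal_conditionals(pen: np.ndarray, mafs: Sequence[float]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Exact genotype distributions given case / control status.

    Bayes over the causal-genotype states with HWE priors:
    ``P(g | case) prop pi_g f_g`` and ``P(g | control) prop pi_g (1 - f_g)``.
    Returned flattened row-major (first causal SNP varies slowest).
    """
    f = np.asarray(pen, dtype=float).ravel()
    pi = _causal_prior(mafs).ravel()
    case_mass = pi * f
    ctrl_mass = pi * (1.0 - f)
    if case_mass.sum() <= 0:
        raise ValueError("penetrance is identically zero: cannot produce cases")
    if ctrl_mass.sum() <= 0:
        raise ValueError("penetrance is identically one: cannot produce controls")
    return case_mass / case_mass.sum(), ctrl_mass / ctrl_mass.sum()


def _decode_states(states: np.ndarray, k: int) -> np.ndarray:
    """Map flat base-3 state indices to (n, k) genotype counts."""
    out = np.empty((states.size, k), dtype=np.int8)
    for axis in range(k):
        out[:, axis] = (states // 3 ** (k - 1 - axis)) % 3
    return out


def simulate_dataset(spec: SimulationSpec) -> GenotypeDataset:
    """Draw a case-control dataset by retrospective sampling."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.causal_mafs)
    case_p, ctrl_p = causal_conditionals(spec.causal_penetrance, spec.causal_mafs)
    n_states = 3 ** k
    case_states = rng.choice(n_states, size=spec.n_cases, p=case_p)
    ctrl_states = rng.choice(n_states, size=spec.n_controls, p=ctrl_p)
    causal = np.vstack([_decode_states(case_states, k),
                        _decode_states(ctrl_states, k)])

    n = spec.n_cases + spec.n_controls
    n_noise = spec.n_snps - k
    if isinstance(spec.noise_maf, tuple):
        kind, lo, hi = spec.noise_maf
        if kind != "uniform":
            raise ValueError(f"unknown noise MAF rule {spec.noise_maf!r}")
        noise_mafs = rng.uniform(lo, hi, size=n_noise)
    else:
        noise_mafs = np.full(n_noise, float(spec.noise_maf))
    noise = rng.binomial(2, noise_mafs[None, :], size=(n, n_noise)).astype(np.int8)

    genotypes = np.hstack([causal, noise])
    phenotype = np.concatenate([np.ones(spec.n_cases, dtype=np.int8),
                                np.zeros(spec.n_controls, dtype=np.int8)])
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


def null_dataset(maf: float, n: int, n_snps: int, seed: int) -> GenotypeDataset:
    """All SNPs HWE at ``maf``; phenotype half cases, half controls,
    independent of every genotype."""
    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, maf, size=(n, n_snps)).astype(np.int8)
    n_cases = n // 2
    phenotype = np.concatenate([np.ones(n_cases, dtype=np.int8),
                                np.zeros(n - n_cases, dtype=np.int8)])
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


# ---------------------------------------------------------------------------
# named presets for every study condition


@dataclass(frozen=True)
class ScenarioPreset:
    """A registered study condition: a spec builder plus its metadata."""

    name: str
    kind: str  # 'null' | 'single' | 'two-pair'
    n: int
    n_snps: int
    true_pairs: tuple[tuple[int, int], ...]
    builder: Callable[[int], SimulationSpec] | None
    description: str = ""
    null_maf: float | None = None

    def spec(self, seed: int) -> SimulationSpec:
        if self.builder is None:
            raise ValueError(f"preset {self.name} has no simulation spec")
        return self.builder(seed)

    def dataset(self, seed: int) -> GenotypeDataset:
        if self.kind == "null":
            return null_dataset(self.null_maf, self.n, self.n_snps, seed)
        return simulate_dataset(self.spec(seed))


def _single_pair_preset(name, pen_fn, maf, n, desc, n_snps=100):
    def builder(seed: int) -> SimulationSpec:
        return SimulationSpec(
            n_cases=n // 2, n_controls=n - n // 2, n_snps=n_snps,
            causal_penetrance=pen_fn(), causal_mafs=(maf, maf),
            noise_maf=maf, seed=seed)
    return ScenarioPreset(name=name, kind="single", n=n, n_snps=n_snps,
                          true_pairs=((0, 1),), builder=builder, description=desc)


def _pathological_scenario(example: int, p11: float | None = None) -> TwoPairScenario:
    """The two-pair equal-ratio scenarios; p11 defaults to the exact
    pathological value."""
    if example == 1:
        m1 = m2 = DiseaseModel.from_id("001010100")
        p10, p01, p00, maf = 0.1, 0.28, 0.01, 0.3
    elif example == 2:
        m1 = DiseaseModel.from_id("000011011")
        m2 = DiseaseModel.from_id("011100100")
        p10, p01, p00, maf = 0.09, 0.12, 0.001, 0.2
    else:
        raise ValueError("example must be 1 or 2")
    if p11 is None:
        p11 = pathological_p11(p10, p01, p00, m2, maf)
    return TwoPairScenario(model1=m1, model2=m2, p11=p11, p10=p10,
                           p01=p01, p00=p00)


def pathological_spec(example: int, seed: int, p11: float | None = None,
                      n: int = 800, n_snps: int = 100) -> SimulationSpec:
    """Simulation spec for the equal-ratio two-pair scenarios.

    ``p11`` may be overridden to explore near-pathological settings.
    """
    maf = 0.3 if example == 1 else 0.2
    scen = _pathological_scenario(example, p11)
    return SimulationSpec(
        n_cases=n // 2, n_controls=n - n // 2, n_snps=n_snps,
        causal_penetrance=scen.joint_penetrance(),
        causal_mafs=(maf,) * 4, noise_maf=maf, seed=seed)


def _spurious_spec(seed: int, n: int = 200, n_snps: int = 100) -> SimulationSpec:
    joint = combine_independent(ADDITIVE_TABLE, ADDITIVE_TABLE)
    return SimulationSpec(
        n_cases=n // 2, n_controls=n - n // 2, n_snps=n_snps,
        causal_penetrance=joint, causal_mafs=(0.5, 0.3, 0.5, 0.3),
        noise_maf=("uniform", 0.05, 0.5), seed=seed)


def _build_presets() -> dict[str, ScenarioPreset]:
    presets: dict[str, ScenarioPreset] = {}

    for maf in (0.05, 0.10, 0.40):
        name = f"null-{maf:.2f}"
        presets[name] = ScenarioPreset(
            name=name, kind="null", n=400, n_snps=100, true_pairs=(),
            builder=None, null_maf=maf,
            description=f"100 unrelated SNPs at MAF {maf}, n=400 balanced")

    main_effect = {"T": 0.02, "DD": 0.02, "MOD": 0.02, "XOR": 0.02,
                   "ME": 0.015, "MET": 0.015}
    for family, h2 in main_effect.items():
        for maf, n in ((0.1, 600), (0.4, 300)):
            name = f"{family.lower()}-maf{maf:.1f}".replace("0.", "0")
            pen_fn = (lambda family=family, maf=maf, h2=h2:
                      solve_alpha_theta(family, maf, 0.02, h2).penetrance_table())
            presets[name] = _single_pair_preset(
                name, pen_fn, maf, n,
                f"{family} odds model calibrated to P(D)=0.02, h2={h2} at MAF {maf}")

    dmn_maf = {"DMN1": 0.25, "DMN2": 0.25, "DMN3": 0.1, "DMN4": 0.1}
    for dmn, maf in dmn_maf.items():
        name = dmn.lower()
        pen_fn = (lambda dmn=dmn: dmn_generation_table(dmn))
        presets[name] = _single_pair_preset(
            name, pen_fn, maf, 600,
            f"pure-epistasis table {dmn} at allele-A frequency {maf}")

    for ex in (1, 2):
        name = f"ex21-{ex}"
        presets[name] = ScenarioPreset(
            name=name, kind="two-pair", n=800, n_snps=100,
            true_pairs=((0, 1), (2, 3)),
            builder=(lambda seed, ex=ex: pathological_spec(ex, seed)),
            description=f"equal-ratio two-pair scenario, example {ex}")

    presets["ex22"] = ScenarioPreset(
        name="ex22", kind="two-pair", n=200, n_snps=100,
        true_pairs=((0, 1), (2, 3)), builder=_spurious_spec,
        description="two independent additive pairs (MAFs 0.5/0.3), "
                    "spurious-effect scenario")
    return presets


PRESETS: dict[str, ScenarioPreset] = _build_presets()
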