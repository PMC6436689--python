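"""Similarity metric: closed form, identities, and the sampling oracle."""

import numpy as np
import pytest

from epiproto.disease_models import DiseaseModel, reduced_set
from epiproto.model_metric import (
    EmpiricalConcordance,
    InfeasibleModelError,
    PopulationContext,
    distance,
    distance_matrix,
    feasible_mask,
    genotype_probs,
    hwe_probs,
    joint_weights,
    phi,
    phi_empirical,
    solve_penetrance,
    symmetrized_distance,
)

ANTI_DIAG = DiseaseModel.from_id("001010100")


def mc_phi(m_proto, m_true, ctx, n=1_000_000, seed=0):
    """Simulation oracle: retrospective case-control sample of a two-level
    penetrance model, cross-classified by the two risk assignments."""
    rng = np.random.default_rng(seed)
    p = genotype_probs(ctx.maf_a, ctx.maf_b)
    t = m_true.bits.astype(bool)
    s = m_proto.bits.astype(bool)
    pen = solve_penetrance(float(p[t].sum()), ctx.prevalence, ctx.heritability)
    f = np.where(t, pen.p1, pen.p0)
    n1 = int(round(n * ctx.sample_ratio / (1 + ctx.sample_ratio)))
    case_p = p * f / (p * f).sum()
    ctrl_p = p * (1 - f) / (p * (1 - f)).sum()
    g = np.concatenate([rng.choice(9, n1, p=case_p),
                       rng.choice(9, n - n1, p=ctrl_p)])
    truth, prot = t[g], s[g]
    c = EmpiricalConcordance(
        n11=int((truth & prot).sum()), n10=int((~truth & prot).sum()),
        n01=int((truth & ~prot).sum()), n00=int((~truth & ~prot).sum()))
    return phi_empirical(c)


def feasible_models(ctx):
    ms = reduced_set()
    return [m for m, ok in zip(ms, feasible_mask(ms, ctx)) if ok]


def test_hwe_probs():
    assert hwe_probs(0.3) == pytest.approx((0.49, 0.42, 0.09))
    assert hwe_probs(0.5) == pytest.approx((0.25, 0.5, 0.25))
    for q in (0.01, 0.17, 0.5):
        assert sum(hwe_probs(q)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hwe_probs(0.6)


def test_joint_weights_self_and_risk_mass():
    m = DiseaseModel.from_id("011001100")
    w = joint_weights(m, m, 0.3, 0.2)
    assert w.w10 == w.w01 == 0.0
    assert w.w11 + w.w10 + w.w01 + w.w00 == pytest.approx(1.0, abs=1e-12)
    # anti-diagonal risk mass at MAF 0.3: 0.49*0.09 + 0.42*0.42 + 0.09*0.49
    w2 = joint_weights(ANTI_DIAG, ANTI_DIAG, 0.3, 0.3)
    assert w2.w1dot == pytest.approx(0.2646, abs=1e-12)


def test_solve_penetrance():
    flat = solve_penetrance(0.3, prevalence=0.05, h2=0.0)
    assert flat.p1 == flat.p0 == pytest.approx(0.05)
    pen = solve_penetrance(0.2646, prevalence=0.02, h2=0.02)
    assert pen.p1 == pytest.approx(0.0530, abs=5e-4)
    assert pen.p0 == pytest.approx(0.0081, abs=5e-4)
    # substituting back recovers prevalence and h2
    w1 = 0.2646
    prev = w1 * pen.p1 + (1 - w1) * pen.p0
    h2 = (w1 * (pen.p1 - prev) ** 2 + (1 - w1) * (pen.p0 - prev) ** 2) / (
        prev * (1 - prev))
    assert prev == pytest.approx(0.02, abs=1e-10)
    assert h2 == pytest.approx(0.02, abs=1e-10)
    with pytest.raises(InfeasibleModelError):
        solve_penetrance(0.9, prevalence=0.02, h2=0.02)


def test_phi_fixed_points():
    ctx = PopulationContext(0.25, 0.3)
    for mid in ("001010100", "000000111", "010010001"):
        m = DiseaseModel.from_id(mid)
        assert phi(m, m, ctx) == pytest.approx(1.0, abs=1e-9)
        assert phi(m.complement(), m, ctx) == pytest.approx(-1.0, abs=1e-9)
        assert distance(m, m, ctx) == pytest.approx(0.0, abs=1e-9)
        assert distance(m.complement(), m, ctx) == pytest.approx(2.0, abs=1e-9)


def test_distance_bounds_over_reduced_set():
    ctx = PopulationContext(0.2, 0.2)
    models = feasible_models(ctx)
    d = distance_matrix(models, ctx)
    assert d.min() >= -1e-9 and d.max() <= 2.0 + 1e-9
    assert np.allclose(np.diag(d), 0.0, atol=1e-9)


def test_distance_matrix_matches_scalar_and_swap_identity(rng):
    ctx = PopulationContext(0.15, 0.35)
    models = feasible_models(ctx)
    d = distance_matrix(models, ctx)
    for _ in range(10):
        i, j = rng.integers(len(models), size=2)
        assert d[i, j] == pytest.approx(distance(models[i], models[j], ctx),
                                        abs=1e-10)
    # simultaneous locus swap of both models with swapped MAFs
    ctx_swap = PopulationContext(0.35, 0.15)
    for _ in range(10):
        i, j = rng.integers(len(models), size=2)
        got = distance(models[i].transpose(), models[j].transpose(), ctx_swap)
        assert got == pytest.approx(d[i, j], abs=1e-10)


def test_symmetrized_distance_is_symmetric():
    ctx = PopulationContext(0.2, 0.2)
    m1 = DiseaseModel.from_id("000011011")
    m2 = DiseaseModel.from_id("001010100")
    assert symmetrized_distance(m1, m2, ctx) == pytest.approx(
        symmetrized_distance(m2, m1, ctx))
    assert symmetrized_distance(m1, m1, ctx) == pytest.approx(0.0, abs=1e-9)


def test_case_enrichment_identities(rng):
    """U/V equals (r0+(r-r0)P1)/(r0+(r-r0)P0) and the denominator factors
    expand into the four-term variance decomposition."""
    from epiproto.model_metric import _uv

    for _ in range(25):
        w1 = rng.uniform(0.05, 0.45)
        prev = rng.uniform(0.005, 0.2)
        h2 = rng.uniform(0.0, 0.05)
        r = rng.uniform(0.2, 5.0)
        try:
            pen = solve_penetrance(w1, prev, h2)
        except InfeasibleModelError:
            continue
        ctx = PopulationContext(0.2, 0.2, prevalence=prev, heritability=h2,
                                sample_ratio=r)
        u, v = _uv(pen, ctx)
        r0 = prev / (1 - prev)
        lhs = u / v
        rhs = (r0 + (r - r0) * pen.p1) / (r0 + (r - r0) * pen.p0)
        assert lhs == pytest.approx(rhs, abs=1e-12 * max(1, abs(rhs)))
        # four-term expansion of the two denominator factors
        w11, w10, w01, w00 = rng.dirichlet(np.ones(4))
        prod = (lhs * w11 + w01) * (w10 + w00 / lhs)
        expanded = (lhs * w11 * w10 + w01 * w10 + w11 * w00
                    + w01 * w00 / lhs)
        assert prod == pytest.approx(expanded, rel=1e-12)


def test_population_ratio_limit_reduces_to_plain_phi():
    """At r = r0 the weighting disappears: the denominator is the product
    of the four marginal masses, i.e. the plain phi-coefficient form."""
    prev = 0.1
    ctx = PopulationContext(0.3, 0.3, prevalence=prev, heritability=0.01,
                            sample_ratio=prev / (1 - prev))
    m_true = DiseaseModel.from_id("000011011")
    m_proto = DiseaseModel.from_id("000001111")
    w = joint_weights(m_true, m_proto, 0.3, 0.3)
    expected = (w.w11 * w.w00 - w.w10 * w.w01) / np.sqrt(
        w.w1dot * w.w0dot * w.wdot1 * w.wdot0)
    assert phi(m_proto, m_true, ctx) == pytest.approx(expected, abs=1e-12)


def test_phi_empirical():
    assert phi_empirical(EmpiricalConcordance(30, 10, 10, 30)) == pytest.approx(0.5)
    assert phi_empirical(EmpiricalConcordance(20, 0, 0, 50)) == pytest.approx(1.0)
    # independence: counts proportional to products of margins
    assert phi_empirical(EmpiricalConcordance(12, 28, 18, 42)) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        phi_empirical(EmpiricalConcordance(5, 5, 0, 0))


def test_phi_matches_sampling_oracle(rng):
    """Closed form agrees with the case-control sampling oracle across
    random model pairs and contexts (within Monte-Carlo error)."""
    models = reduced_set()
    checked = 0
    k = 0
    while checked < 20:
        k += 1
        i, j = rng.integers(len(models), size=2)
        r = float(rng.choice([0.5, 1.0, 2.0]))
        ctx = PopulationContext(float(rng.choice([0.1, 0.2, 0.3, 0.4])),
                                float(rng.choice([0.1, 0.2, 0.3, 0.4])),
                                sample_ratio=r)
        try:
            expected = phi(models[i], models[j], ctx)
        except InfeasibleModelError:
            continue
        got = mc_phi(models[i], models[j], ctx, n=400_000, seed=k)
        assert got == pytest.approx(expected, abs=0.01)
        checked += 1


def test_infeasible_context_raises():
    ctx = PopulationContext(0.45, 0.45)
    heavy = DiseaseModel.from_id("011111111")
    with pytest.raises(InfeasibleModelError):
        phi(heavy, heavy, ctx)
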