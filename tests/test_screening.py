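"""Pair screening: contingency building, the chi-square convention,
the three model-selection rules, and both procedures."""

import numpy as np
import pytest
from sklearn.base import clone

from epiproto.dataset import GenotypeDataset
from epiproto.disease_models import DiseaseModel, enumerate_nontrivial
from epiproto.screening import (
    EpistasisScreener,
    PairContingency,
    chi2_test,
    marginal_screen,
    pair_contingency,
    select_model_mdr,
    select_model_pty,
    select_model_rs,
    sequential_screen,
)
from epiproto.screening import _pty_candidates
from epiproto.simulation import PRESETS, SimulationSpec, simulate_dataset


def contingency_from_counts(case_cells, control_cells):
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    counts[:, :, 1] = np.asarray(case_cells).reshape(3, 3)
    counts[:, :, 0] = np.asarray(control_cells).reshape(3, 3)
    return PairContingency(counts=counts)


def test_pair_contingency_matches_loop_oracle(small_dataset):
    ds = small_dataset
    c = pair_contingency(ds, 1, 4)
    expected = np.zeros((3, 3, 2), dtype=int)
    for row, y in zip(ds.genotypes, ds.phenotype):
        if row[1] >= 0 and row[4] >= 0:
            expected[row[1], row[4], y] += 1
    assert np.array_equal(c.counts, expected)
    assert c.total == int(expected.sum())
    # no missing data at this pair -> total = n
    c2 = pair_contingency(ds, 0, 2)
    assert c2.total == ds.n_individuals
    with pytest.raises(ValueError):
        pair_contingency(ds, 2, 2)


def test_chi2_test_conventions():
    # independence
    risk = np.repeat([1, 0, 1, 0], 25)
    status = np.repeat([1, 1, 0, 0], 25)
    assert chi2_test(risk, status)[0] == pytest.approx(0.0)
    # plain Pearson value for a (30,10;10,30) table
    risk = np.repeat([1, 0, 1, 0], [30, 10, 10, 30])
    status = np.repeat([1, 0], [40, 40])
    assert chi2_test(risk, status, correction=False)[0] == pytest.approx(20.0)
    # continuity correction shrinks the statistic
    chi_c, p_c = chi2_test(risk, status)
    assert chi_c == pytest.approx(80 * (800 - 40) ** 2 / 40 ** 4)
    assert 0 < p_c < 1
    # degenerate margins
    assert chi2_test(np.ones(50), status[:50]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        chi2_test([1, 0], [1])


def test_chi2_invariant_under_risk_complement(rng):
    for _ in range(30):
        risk = rng.integers(0, 2, 80)
        status = rng.integers(0, 2, 80)
        assert chi2_test(risk, status)[0] == pytest.approx(
            chi2_test(1 - risk, status)[0], abs=1e-10)


def test_mdr_threshold_rule():
    case = [5, 0, 0, 0, 0, 0, 0, 0, 7]
    ctrl = [5, 3, 0, 0, 0, 0, 0, 0, 4]
    model, chi, p = select_model_mdr(contingency_from_counts(case, ctrl))
    # equal case/control counts on a balanced table -> high risk (ratio 1 >= 1)
    assert model.cells[0, 0] == 1
    # cases with zero controls -> high; zero cases with controls -> low;
    # empty cells -> low
    assert model.cells[2, 2] == 1 and model.cells[0, 1] == 0
    assert model.cells[1, 1] == 0
    # all cells below threshold -> trivial model, chi2 = 0 by convention
    model2, chi2_, p2 = select_model_mdr(
        contingency_from_counts(np.zeros(9), np.full(9, 4)))
    assert model2.is_trivial and chi2_ == 0.0 and p2 == 1.0


def test_rs_maximizes_over_nested_candidates(rng):
    case = rng.integers(0, 20, 9)
    ctrl = rng.integers(1, 20, 9)
    c = contingency_from_counts(case, ctrl)
    model, chi, _ = select_model_rs(c)
    # oracle: enumerate the 8 nested top-x splits by descending ratio
    ratio = case / ctrl
    order = np.argsort(-ratio, kind="stable")
    best = 0.0
    for x in range(1, 9):
        bits = np.zeros(9, dtype=np.int8)
        bits[order[:x]] = 1
        risk = np.concatenate([np.repeat(bits, case), np.repeat(bits, ctrl)])
        status = np.concatenate([np.ones(case.sum(), int), np.zeros(ctrl.sum(), int)])
        best = max(best, chi2_test(risk, status)[0])
    assert chi == pytest.approx(best)


def test_mdr_and_rs_recover_strong_partition():
    """Simulated data with penetrance 0.9 vs 0.01 and large n: both
    baselines recover the generating risk partition."""
    truth = DiseaseModel.from_id("000011011")
    pen = np.where(truth.cells == 1, 0.9, 0.01)
    spec = SimulationSpec(n_cases=5000, n_controls=5000, n_snps=2,
                          causal_penetrance=pen, causal_mafs=(0.3, 0.3),
                          noise_maf=0.3, seed=7)
    ds = simulate_dataset(spec)
    c = pair_contingency(ds, 0, 1)
    for select in (select_model_mdr, select_model_rs):
        model, chi, p = select(c)
        assert model == truth
        assert p < 1e-100


def test_pty_candidates_and_bound(library, rng):
    protos = library.entry(0.2, 0.2).prototypes()
    bits, cands = _pty_candidates(protos)
    # asymmetric prototypes contribute both orientations, symmetric one each
    expected = len(protos) + sum(1 for m in protos if not m.is_symmetric)
    assert len(cands) == expected
    assert len({m.id for m in cands}) == len(cands)

    all_models = enumerate_nontrivial()
    for _ in range(100):
        case = rng.integers(0, 15, 9)
        ctrl = rng.integers(0, 15, 9)
        if case.sum() == 0 or ctrl.sum() == 0:
            continue
        c = contingency_from_counts(case, ctrl)
        model, chi, _ = select_model_pty(c, protos)
        # brute-force oracle over every non-trivial model
        risk_all = np.array([m.bits for m in all_models], dtype=float)
        a = risk_all @ case
        co = risk_all @ ctrl
        from epiproto.screening import _chi2_from_highs
        brute = _chi2_from_highs(a, co, float(case.sum()), float(ctrl.sum())).max()
        assert chi <= brute + 1e-9
    with pytest.raises(ValueError):
        select_model_pty(c, [])


def test_marginal_screen_shape_and_order(library):
    ds = PRESETS["null-0.10"].dataset(3)
    scores = marginal_screen(ds, "pty", library=library)
    assert len(scores) == 100 * 99 // 2 == 4950
    assert (scores["chi2"].values[:-1] >= scores["chi2"].values[1:] - 1e-12).all()
    assert scores["pvalue"].between(0, 1).all()
    assert (scores["rank"] == np.arange(1, 4951)).all()


def test_marginal_screen_invariant_to_snp_order(rng, library):
    # dense tables (no empty cells) so ratio tie-breaking cannot differ
    # between the two pair orientations
    geno = rng.integers(0, 3, size=(400, 8)).astype(np.int8)
    pheno = np.array([1, 0] * 200, dtype=np.int8)
    ds = GenotypeDataset(genotypes=geno, phenotype=pheno, orient=False)
    perm = rng.permutation(8)
    ds_p = GenotypeDataset(genotypes=geno[:, perm], phenotype=pheno, orient=False)
    for method in ("mdr", "rs"):
        s1 = marginal_screen(ds, method)
        s2 = marginal_screen(ds_p, method)
        key1 = {(min(i, j), max(i, j)): c for i, j, c in
                zip(s1.snp_i, s1.snp_j, s1.chi2)}
        key2 = {(min(perm[i], perm[j]), max(perm[i], perm[j])): c for i, j, c in
                zip(s2.snp_i, s2.snp_j, s2.chi2)}
        for pair, chi in key1.items():
            assert key2[pair] == pytest.approx(chi, abs=1e-9)


def test_sequential_first_round_equals_marginal_top(library):
    ds = PRESETS["dmn1"].dataset(5)
    marg = marginal_screen(ds, "pty", library=library)
    sel, hist = sequential_screen(ds, "pty", 3, library=library)
    assert (sel.iloc[0].snp_i, sel.iloc[0].snp_j) == (
        marg.iloc[0].snp_i, marg.iloc[0].snp_j)
    pairs = list(zip(sel.snp_i, sel.snp_j))
    assert len(set(pairs)) == 3
    assert hist.pairs == pairs
    assert hist.risk.dtype == bool


@pytest.mark.parametrize("method", ["pty", "mdr", "rs"])
def test_pathological_scenario_strong_pair_always_found(method, library):
    """In the equal-ratio two-pair scenario the stronger pair {C,D} is
    selected within the first two sequential picks."""
    hits = 0
    reps = 12
    for seed in range(reps):
        ds = PRESETS["ex21-1"].dataset(seed + 100)
        sel, _ = sequential_screen(ds, method, 2, library=library)
        chosen = {tuple(sorted((i, j))) for i, j in zip(sel.snp_i, sel.snp_j)}
        hits += (2, 3) in chosen
    assert hits == reps


def test_screener_estimator_interface(library):
    ds = PRESETS["null-0.05"].dataset(2)
    scr = EpistasisScreener(method="rs", alpha=1e-5)
    assert clone(scr).get_params()["method"] == "rs"
    scr.fit(ds)
    assert scr.n_pairs_ == 4950
    assert isinstance(scr.detected_pairs(), set)
    # fit from raw arrays
    scr2 = EpistasisScreener(method="mdr").fit(ds.genotypes, ds.phenotype)
    assert len(scr2.scores_) == 4950
    with pytest.raises(ValueError):
        EpistasisScreener(method="pty").fit(ds)  # library required
    with pytest.raises(ValueError):
        EpistasisScreener(method="mdr", procedure="sequential").fit(ds)
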