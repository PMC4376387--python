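import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from clskinetics.kinetic_core import (
    DeceleratorSpec,
    LinearFractional,
    OligomerSpec,
    ReactionChain,
    ReactionStep,
    activity_from_solution,
    check_cls_conditions,
    closed_form_dose_response,
    hill_fit,
    hit_and_run_steady_state,
    oligomer_effective_step,
    solve_equilibrium_numeric,
)

from conftest import random_cls_chain


# ---------------------------------------------------------------------------
# numeric equilibrium oracle
# ---------------------------------------------------------------------------


class TestSolveEquilibrium:
    def test_one_step_symmetric(self):
        chain = ReactionChain([ReactionStep(1, 1.0, 1.0)], cls_index=1)
        sol = solve_equilibrium_numeric(chain, y0=1.0)
        x1, y1 = sol[1]
        assert y1 == pytest.approx(0.5, abs=1e-10)
        assert x1 == pytest.approx(0.5, abs=1e-10)

    def test_zero_inducer(self, three_step_chain):
        sol = solve_equilibrium_numeric(three_step_chain, y0=0.0)
        for i, step in enumerate(three_step_chain.steps, start=1):
            assert sol[i][1] == 0.0
            assert sol[i][0] == pytest.approx(float(step.X_total))

    def test_three_step_matches_closed_form(self, three_step_chain):
        # q2*X2 = 0.01 sits exactly at the regime threshold, so the CLS
        # approximation error is O(1e-2), not the naive 1e-3
        lf = closed_form_dose_response(three_step_chain)
        sol = solve_equilibrium_numeric(three_step_chain, y0=1.0)
        a_numeric = activity_from_solution(three_step_chain, sol)
        assert a_numeric == pytest.approx(lf(1.0), rel=2e-2)
        assert a_numeric == pytest.approx(0.004878745431762185, rel=1e-9)

    def test_mass_conservation_residual(self, three_step_chain):
        sol = solve_equilibrium_numeric(three_step_chain, y0=2.0)
        # exact sums: [X_i] + sum_{j>=i}[Y_j] = X_i^T
        ys = [sol[i][1] for i in (1, 2, 3)]
        for i, step in enumerate(three_step_chain.steps, start=1):
            total = sol[i][0] + sum(ys[i - 1 :])
            assert total == pytest.approx(float(step.X_total), rel=1e-9)

    def test_negative_inducer_rejected(self, three_step_chain):
        with pytest.raises(ValueError):
            solve_equilibrium_numeric(three_step_chain, y0=-1.0)


# ---------------------------------------------------------------------------
# closed-form dose-response
# ---------------------------------------------------------------------------


class TestClosedForm:
    def test_printed_three_reaction_formulas(self, three_step_chain):
        # independent oracle: the printed A_max/EC50 expressions evaluated
        # directly with q=(1, 0.01, 1), X_total=(1,1,1)
        q1, q2, q3 = 1.0, 0.01, 1.0
        x1, x2, x3 = 1.0, 1.0, 1.0
        amax_expected = (q1 * x1 * q2 * x2 * q3 * x3) / (
            q1 + q2 * (1 + q3 * x3) * q1 * x1
        )
        ec50_expected = 1.0 / (q1 + q2 * (1 + q3 * x3) * q1 * x1)
        lf = closed_form_dose_response(three_step_chain)
        assert lf.b / lf.d == pytest.approx(amax_expected, rel=1e-12)
        assert 1.0 / lf.d == pytest.approx(ec50_expected, rel=1e-12)
        assert amax_expected == pytest.approx(0.01 / 1.02)

    def test_competitive_decelerator_scales_v_and_w(self, three_step_chain):
        base = closed_form_dose_response(three_step_chain)
        dec = DeceleratorSpec(step=1, conc=1.0, q_prime=1.0,
                              alpha=0.0, beta=0.0, gamma=1.0)
        mod = closed_form_dose_response(three_step_chain, [dec])
        # q'[D] = 1 divides V and W by 2: A_max unchanged, EC50 doubled
        assert mod.b == pytest.approx(base.b / 2)
        assert mod.d == pytest.approx(base.d / 2)
        assert mod.b / mod.d == pytest.approx(base.b / base.d)

    def test_diverting_post_cls_step_represses(self):
        def activity(x4_total):
            chain = ReactionChain(
                [
                    ReactionStep(1, 1.0, 1.0),
                    ReactionStep(2, 0.01, 1.0),
                    ReactionStep(3, 1.0, 1.0),
                    ReactionStep(4, 1.0, x4_total),
                ],
                cls_index=2,
                activity_weights={2: 1.0, 3: 1.0, 4: 0.0},
            )
            return closed_form_dose_response(chain)(1.0)

        acts = [activity(x) for x in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(acts, acts[1:]))

    def test_all_zero_weights_error(self):
        chain = ReactionChain(
            [ReactionStep(1, 1.0, 1.0), ReactionStep(2, 0.01, 1.0)],
            cls_index=2,
            activity_weights={2: 0.0},
        )
        with pytest.raises(ValueError):
            closed_form_dose_response(chain)

    def test_decelerator_on_undefined_step_error(self, three_step_chain):
        bad = DeceleratorSpec(step=7, conc=1.0, q_prime=1.0)
        with pytest.raises(ValueError):
            closed_form_dose_response(three_step_chain, [bad])

    def test_weight_on_pre_cls_product_rejected(self):
        with pytest.raises(ValueError):
            ReactionChain(
                [ReactionStep(1, 1.0, 1.0), ReactionStep(2, 0.01, 1.0)],
                cls_index=2,
                activity_weights={1: 1.0},
            ).weights()


class TestOracleEquivalence:
    def test_random_cls_chains(self):
        rng = np.random.default_rng(7)
        checked = 0
        for trial in range(12):
            chain, decels = random_cls_chain(rng, with_decels=trial % 3 == 0)
            lf = closed_form_dose_response(chain, decels)
            for y0 in np.logspace(-2, 2, 5):
                sol = solve_equilibrium_numeric(chain, decels, y0=float(y0))
                a_num = activity_from_solution(chain, sol)
                if a_num <= 0:
                    continue
                assert abs(lf(y0) - a_num) / a_num <= 1e-2
                checked += 1
        assert checked >= 40


# ---------------------------------------------------------------------------
# CLS regime checks
# ---------------------------------------------------------------------------


class TestCheckCLS:
    def test_valid_cls(self):
        chain = ReactionChain(
            [ReactionStep(1, 1.0, 1.0), ReactionStep(2, 1e-4, 1.0),
             ReactionStep(3, 1.0, 1.0)],
            cls_index=2,
        )
        rep = check_cls_conditions(chain)
        assert rep.valid
        assert rep.roles == {1: "pre", 2: "cls", 3: "post"}
        assert rep.limited_margin[2] == pytest.approx(1e-4)

    def test_all_order_one_flagged(self):
        chain = ReactionChain(
            [ReactionStep(1, 1.0, 1.0), ReactionStep(2, 1.0, 1.0),
             ReactionStep(3, 1.0, 1.0)],
            cls_index=2,
        )
        rep = check_cls_conditions(chain)
        assert not rep.valid
        assert any("step 2" in v for v in rep.violations)

    def test_two_cls_block_structure(self):
        # pre, CLS, post, pre, CLS, post per the multi-block layout
        chain = ReactionChain(
            [
                ReactionStep(1, 1.0, 1.0),
                ReactionStep(2, 1e-4, 1.0),   # CLS 1
                ReactionStep(3, 1.0, 1.0),    # post (not limited)
                ReactionStep(4, 1e-4, 1.0),   # pre of block 2 (limited)
                ReactionStep(5, 1e-4, 1.0),   # CLS 2
                ReactionStep(6, 1.0, 1.0),
            ],
            cls_index=[2, 5],
        )
        rep = check_cls_conditions(chain)
        assert rep.roles == {1: "pre", 2: "cls", 3: "post", 4: "pre",
                             5: "cls", 6: "post"}
        assert rep.valid


# ---------------------------------------------------------------------------
# Hill fit
# ---------------------------------------------------------------------------


class TestHillFit:
    def test_michaelis_menten_is_unit_hill(self):
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
        y = 100.0 * x / (10.0 + x)
        h, k, lo, hi = hill_fit(x, y)
        assert h == pytest.approx(1.0, abs=1e-6)
        assert k == pytest.approx(10.0, rel=1e-6)

    def test_constructed_n2(self):
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
        y = 100.0 * x**2 / (10.0**2 + x**2)
        h, *_ = hill_fit(x, y)
        assert h == pytest.approx(2.0, abs=0.01)

    def test_cls_chain_output_is_unit_hill(self, three_step_chain):
        lf = closed_form_dose_response(three_step_chain)
        x = np.logspace(-2, 2, 12)
        y = lf(x)
        h, *_ = hill_fit(np.concatenate([[0.0], x]), np.concatenate([[0.0], y]))
        assert 0.99 <= h <= 1.01

    def test_flat_data_flagged(self):
        with pytest.raises(ValueError, match="flat"):
            hill_fit(np.array([0.0, 1, 10, 100]), np.full(4, 5.0))


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_unit_hill_property_on_random_cls_chains(seed):
    rng = np.random.default_rng(seed)
    chain, decels = random_cls_chain(rng)
    lf = closed_form_dose_response(chain, decels)
    ec50 = 1.0 / lf.d
    x = np.concatenate([[0.0], ec50 * np.logspace(-2, 2, 11)])
    y = lf(x) / (lf.b / lf.d)  # scale to the plateau so tiny chains stay fittable
    h, *_ = hill_fit(x, y)
    assert 0.99 <= h <= 1.01


# ---------------------------------------------------------------------------
# hit-and-run irreversible equivalence
# ---------------------------------------------------------------------------


class TestHitAndRun:
    def test_post_cls_like_closed_form(self):
        # oracle: integrate d[P']/dt = kf (PT - P') XT - kr P' directly
        kf, kr, xt, pt = 2.0, 1.0, 3.0, 1.0
        sol = solve_ivp(
            lambda t, s: [kf * (pt - s[0]) * xt - kr * s[0]],
            (0, 50), [0.0], rtol=1e-12, atol=1e-12,
        )
        oracle = sol.y[0, -1]
        got = hit_and_run_steady_state(
            "post-CLS-like", kf, kr, {"X": xt, "P": pt}, 0.0
        )
        assert got == pytest.approx(oracle, rel=1e-8)
        assert got == pytest.approx(6.0 / 7.0, rel=1e-8)

    def test_fast_relaxation_limit(self):
        got = hit_and_run_steady_state(
            "post-CLS-like", 1.0, 1e8, {"X": 1.0, "P": 1.0}, 0.0
        )
        assert got < 1e-6

    def test_cls_like_without_second_reaction(self):
        q, xt, p = 2.0, 3.0, 1.0
        got = hit_and_run_steady_state("CLS-like", 2.0, 1.0, {"X": xt}, p)
        assert got == pytest.approx(q * xt * p / (1 + q * p), rel=1e-8)

    def test_cls_like_with_downstream_modifier(self):
        q, qp, xt, ut, p = 2.0, 0.5, 3.0, 2.0, 1.0
        got = hit_and_run_steady_state(
            "CLS-like", 2.0, 1.0, {"X": xt, "U": ut}, p, kf2=1.0, kr2=2.0
        )
        expected = q * xt * p / (1 + q * p + q * qp * ut * p)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_nonpositive_rates_error(self):
        with pytest.raises(ValueError):
            hit_and_run_steady_state("post-CLS-like", 0.0, 1.0, {"X": 1, "P": 1}, 0.0)


# ---------------------------------------------------------------------------
# oligomeric accelerator
# ---------------------------------------------------------------------------


class TestOligomer:
    def test_no_partner_no_product(self):
        assert oligomer_effective_step(OligomerSpec(1.0, 0.0), 1.0, 1.0, 1.0) == 0.0

    def test_saturation_reduces_to_plain_step(self):
        olig = OligomerSpec(r=1.0, Z_total=1e9)
        q, xt, y = 0.7, 2.0, 1.3
        plain = q * xt * y / (1 + q * y)
        assert oligomer_effective_step(olig, q, xt, y) == pytest.approx(plain, rel=1e-6)

    def test_printed_value(self):
        got = oligomer_effective_step(OligomerSpec(1.0, 1.0), 1.0, 1.0, 1.0)
        assert got == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_monotone_in_partner(self):
        vals = [
            oligomer_effective_step(OligomerSpec(1.0, z), 1.0, 1.0, 1.0)
            for z in (0.1, 0.5, 1.0, 5.0, 50.0)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# linear-fractional algebra
# ---------------------------------------------------------------------------


finite = st.floats(-10, 10, allow_nan=False)


@settings(max_examples=80, deadline=None)
@given(
    c1=st.tuples(finite, finite, finite, finite),
    c2=st.tuples(finite, finite, finite, finite),
    x=st.floats(-5, 5, allow_nan=False),
)
def test_composition_closure(c1, c2, x):
    for c in (c1, c2):
        if abs(c[2]) + abs(c[3]) < 1e-3:
            return
    outer = LinearFractional(*c1)
    inner = LinearFractional(*c2)
    try:
        comp = outer.compose(inner)
    except ValueError:
        return
    den_inner = inner.c + inner.d * x
    den_comp = comp.c + comp.d * x
    if abs(den_inner) < 1e-6 or abs(den_comp) < 1e-6:
        return
    u = inner(x)
    if abs(outer.c + outer.d * u) < 1e-6:
        return
    assert comp(x) == pytest.approx(outer(u), rel=1e-6, abs=1e-8)


def test_lf_degenerate_rejected():
    with pytest.raises(ValueError):
        LinearFractional(1.0, 2.0, 0.0, 0.0)


def test_lf_canonical():
    lf = LinearFractional(2.0, 4.0, 2.0, 6.0).canonical()
    assert lf.c == 1.0
    assert lf.coefficients() == (1.0, 2.0, 1.0, 3.0)


# ---------------------------------------------------------------------------
# decelerator direction
# ---------------------------------------------------------------------------


def test_decelerator_never_increases_activity_when_alphabeta_le_gamma():
    # the guaranteed-monotone regime: product-bound productivity cannot
    # exceed accelerator sequestration (alpha*beta <= gamma); the partial
    # uncompetitive corner genuinely amplifies and is excluded
    rng = np.random.default_rng(3)
    for _ in range(40):
        chain, _ = random_cls_chain(rng)
        lf0 = closed_form_dose_response(chain)
        step = int(rng.integers(1, chain.n_steps + 1))
        gamma = float(10 ** rng.uniform(-2, 2))
        beta = float(rng.uniform(0, 1))
        alpha = float(rng.uniform(0, gamma / max(beta, 1e-9)))
        dec = DeceleratorSpec(step=step, conc=float(10 ** rng.uniform(-1, 1)),
                              q_prime=float(10 ** rng.uniform(-1, 1)),
                              alpha=alpha, beta=beta, gamma=gamma)
        lf1 = closed_form_dose_response(chain, [dec])
        for y0 in np.logspace(-2, 2, 5):
            assert lf1(y0) <= lf0(y0) * (1 + 1e-12)


def test_partial_uncompetitive_can_amplify():
    # documented model behaviour: alpha*beta > gamma = 0 pulls extra product
    chain = ReactionChain(
        [ReactionStep(1, 1.0, 1.0), ReactionStep(2, 1e-3, 1.0),
         ReactionStep(3, 1.0, 1.0)],
        cls_index=2,
    )
    dec = DeceleratorSpec(step=1, conc=10.0, q_prime=1.0,
                          alpha=5.0, beta=0.9, gamma=0.0)
    lf0 = closed_form_dose_response(chain)
    lf1 = closed_form_dose_response(chain, [dec])
    assert lf1(0.01) > lf0(0.01)
    # the independent numeric oracle agrees: this is the model, not a bug
    s0 = solve_equilibrium_numeric(chain, None, y0=0.01)
    s1 = solve_equilibrium_numeric(chain, [dec], y0=0.01)
    assert activity_from_solution(chain, s1) > activity_from_solution(chain, s0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_chain_json_round_trip(three_step_chain):
    s = three_step_chain.to_json()
    back = ReactionChain.from_json(s)
    assert back.cls_index == three_step_chain.cls_index
    assert back.activity_weights == {3: 1.0}
    assert [(st.index, st.q, st.X_total) for st in back.steps] == [
        (st.index, st.q, st.X_total) for st in three_step_chain.steps
    ]
    assert json.loads(s)["inducer_conc"] == 1.0


def test_mechanism_labels():
    assert DeceleratorSpec(1, 1.0, 1.0, alpha=0.0, beta=0.0, gamma=1.0).mechanism == "LC"
    assert DeceleratorSpec(1, 1.0, 1.0, alpha=1.0, beta=0.5, gamma=0.0).mechanism == "PU"
    assert DeceleratorSpec(1, 1.0, 1.0, alpha=2.0, beta=0.0, gamma=2.0).mechanism == "LN"
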