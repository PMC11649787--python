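"""Variational engine: likelihood values, penalty, gradients, fits, RT handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ddmcrowd import (
    AnnotatorDDM,
    RTSummary,
    Schedule,
    VariationalState,
    annotate_dataset,
    constraint_penalty,
    data_log_likelihood,
    elbo_objective,
    estimate_supports,
    fit_variational,
    generate_items,
    mean_decision_time,
    predicted_labels,
    rescale_by_rt,
    rt_regularizer,
    rt_summary_from_matrix,
)
from ddmcrowd.inference import _objective_and_grads


def make_state(q, f, mu0, sigma0, mu1, sigma1, positive_branch=False):
    return VariationalState(
        q=np.asarray(q, float), f=np.asarray(f, float),
        mu0=np.asarray(mu0, float), sigma0=np.asarray(sigma0, float),
        mu1=np.asarray(mu1, float), sigma1=np.asarray(sigma1, float),
        positive_branch=positive_branch,
    )


def random_state(rng, n, k):
    return make_state(
        rng.uniform(0.15, 0.85, n), rng.normal(0, 1.5, n),
        rng.uniform(0.15, 0.85, k), rng.uniform(0.3, 0.9, k),
        rng.uniform(0.15, 0.85, k), rng.uniform(0.3, 0.9, k),
    )


# ---------------------------------------------------------------- likelihood

def test_likelihood_single_perfect_annotator():
    """k=1, y=0, near-perfect specificity: per-item term ln(1) = 0."""
    state = make_state([1.0], [0.0], [500.0], [1.0], [0.5], [0.5])
    for form in ("product", "printed"):
        assert data_log_likelihood([[0]], state, form) == pytest.approx(0.0, abs=1e-12)


def test_likelihood_uninformative_annotator():
    """Zero drift makes every response probability 1/2: ln 0.5 per item."""
    state = make_state([0.5], [0.0], [0.0], [1.0], [0.0], [1.0])
    for form in ("product", "printed"):
        assert data_log_likelihood([[1]], state, form) == pytest.approx(np.log(0.5))


def test_likelihood_printed_form_matches_scalar_arithmetic(rng):
    """n=1, k=2: the sum-inside-log form against direct scalar evaluation."""
    state = random_state(rng, 1, 2)
    y = np.array([[1, 0]])
    A = expit(2 * state.mu0 / state.sigma0**2)
    B = expit(2 * state.mu1 / state.sigma1**2)
    q = state.q[0]
    total = 0.0
    for j in range(2):
        u = (1 - A[j]) if y[0, j] == 1 else A[j]
        v = B[j] if y[0, j] == 1 else (1 - B[j])
        total += q * u + (1 - q) * v
    assert data_log_likelihood(y, state, "printed") == pytest.approx(
        np.log(total), abs=1e-12
    )


def test_likelihood_product_form_matches_scalar_arithmetic(rng):
    state = random_state(rng, 1, 2)
    y = np.array([[1, 0]])
    A = expit(2 * state.mu0 / state.sigma0**2)
    B = expit(2 * state.mu1 / state.sigma1**2)
    q = state.q[0]
    pu = np.prod(np.where(y[0] == 0, A, 1 - A))
    pv = np.prod(np.where(y[0] == 1, B, 1 - B))
    assert data_log_likelihood(y, state, "product") == pytest.approx(
        np.log(q * pu + (1 - q) * pv), abs=1e-12
    )


def test_forms_coincide_for_single_annotator(rng):
    state = random_state(rng, 8, 1)
    y = rng.integers(0, 2, (8, 1))
    assert data_log_likelihood(y, state, "printed") == pytest.approx(
        data_log_likelihood(y, state, "product"), abs=1e-12
    )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_label_swap_symmetry(seed):
    """y -> 1-y with branches swapped and q -> 1-q leaves the likelihood fixed."""
    rng = np.random.default_rng(seed)
    state = random_state(rng, 5, 3)
    y = rng.integers(0, 2, (5, 3))
    swapped = make_state(
        1 - state.q, state.f, state.mu1, state.sigma1, state.mu0, state.sigma0
    )
    for form in ("product", "printed"):
        assert data_log_likelihood(y, state, form) == pytest.approx(
            data_log_likelihood(1 - y, swapped, form), abs=1e-10
        )


def test_likelihood_input_validation(rng):
    state = random_state(rng, 2, 2)
    with pytest.raises(ValueError):
        data_log_likelihood(np.array([[0, 2], [1, 0]]), state)
    with pytest.raises(ValueError):
        data_log_likelihood(np.empty((0, 0)), state)
    bad = make_state(state.q, state.f, state.mu0, [0.5, -0.1], state.mu1, state.sigma1)
    with pytest.raises(ValueError):
        data_log_likelihood(np.zeros((2, 2), dtype=int), bad)


# ------------------------------------------------------------------- penalty

def test_constraint_penalty_values():
    assert constraint_penalty([0.5]) == pytest.approx(-2 * np.exp(-15.0), rel=1e-12)
    assert constraint_penalty([0.0]) == pytest.approx(-np.exp(-30.0) - 1.0, rel=1e-12)
    assert constraint_penalty([0.5], beta=30.0, base=2.0) == pytest.approx(
        -(2.0 ** (-15.0)) - np.exp(-15.0), rel=1e-12
    )


def test_constraint_penalty_monotone_past_one():
    vals = [constraint_penalty([0.2, m]) for m in (1.0, 1.1, 1.5, 2.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_constraint_penalty_empty_rejected():
    with pytest.raises(ValueError):
        constraint_penalty([])


# ----------------------------------------------------------------- objective

def test_elbo_cross_entropy_cancellation(rng):
    """At q = S(f) the cross-entropy and entropy terms cancel exactly."""
    n, k = 6, 3
    f = rng.normal(0, 1.5, n)
    state = make_state(
        expit(f), f,
        rng.uniform(0.2, 0.8, k), rng.uniform(0.3, 0.9, k),
        rng.uniform(0.2, 0.8, k), rng.uniform(0.3, 0.9, k),
    )
    y = rng.integers(0, 2, (n, k))
    for form in ("product", "printed"):
        bare = elbo_objective(y, state, beta=None, likelihood_form=form)
        assert bare == pytest.approx(data_log_likelihood(y, state, form), abs=1e-9)


def test_coordinate_optimal_q_matches_grid_search(rng):
    state = random_state(rng, 4, 3)
    y = rng.integers(0, 2, (4, 3))
    i = 2
    grid = np.linspace(1e-6, 1 - 1e-6, 100_001)
    vals = []
    q = state.q.copy()
    for g in grid:
        q[i] = g
        vals.append(elbo_objective(y, make_state(q, state.f, state.mu0,
                                                 state.sigma0, state.mu1,
                                                 state.sigma1)))
    best = grid[int(np.argmax(vals))]
    assert best == pytest.approx(expit(state.f[i]), abs=1e-4)


def test_objective_drops_when_parameter_leaves_unit_interval(rng):
    state = random_state(rng, 5, 3)
    y = rng.integers(0, 2, (5, 3))
    base = elbo_objective(y, state)
    pushed = make_state(state.q, state.f, state.mu0, state.sigma0,
                        np.r_[state.mu1[:-1], 1.6], state.sigma1)
    assert elbo_objective(y, pushed) < base - 1e6


def test_analytic_gradients_match_finite_differences(rng):
    """Central differences (h = 1e-6) agree to relative 1e-4 on random states."""
    n, k = 6, 3
    y = rng.integers(0, 2, (n, k))
    base = {
        "q": rng.uniform(0.2, 0.8, n), "f": rng.normal(0, 1.5, n),
        "mu0": rng.uniform(0.2, 0.8, k), "sigma0": rng.uniform(0.3, 0.9, k),
        "mu1": rng.uniform(0.2, 0.8, k), "sigma1": rng.uniform(0.3, 0.9, k),
    }
    rtm = rng.uniform(0.5, 3.0, (k, 2))
    for form in ("product", "printed"):
        for lam, rt_means in ((0.0, None), (1.3, rtm)):
            def value(**kw):
                s = {**base, **kw}
                v, _ = _objective_and_grads(
                    y, s["q"], s["f"], s["mu0"], s["sigma0"], s["mu1"], s["sigma1"],
                    likelihood_form=form, rt_means=rt_means, lam=lam,
                )
                return v

            _, grads = _objective_and_grads(
                y, **base, likelihood_form=form, rt_means=rt_means, lam=lam
            )
            h = 1e-6
            for name, vec in base.items():
                for i in range(len(vec)):
                    e = np.zeros_like(vec)
                    e[i] = h
                    fd = (value(**{name: vec + e}) - value(**{name: vec - e})) / (2 * h)
                    assert grads[name][i] == pytest.approx(
                        fd, rel=1e-4, abs=1e-7
                    ), f"{form} lam={lam} block {name}[{i}]"


# ---------------------------------------------------------------------- fits

def test_perfect_annotator_recovers_truth_exactly():
    x, z = generate_items(50, seed=4)
    ds = annotate_dataset(x, z, [AnnotatorDDM(50, 0.5, 50, 0.5)], 0.01, seed=5)
    state = fit_variational(ds.y)
    assert np.array_equal(predicted_labels(state), z)


def test_elbo_trace_ascends(small_fit):
    _, state = small_fit
    assert state.elbo_trace[-1] >= state.elbo_trace[0] - 1e-6
    assert len(state.elbo_trace) >= 300


def test_penalty_keeps_parameters_interior(small_fit):
    _, state = small_fit
    for name in ("mu0", "sigma0", "mu1", "sigma1"):
        vec = getattr(state, name)
        assert np.all(vec > 0) and np.all(vec < 1), name
    assert np.all(state.q > 0) and np.all(state.q < 1)


def test_fit_is_deterministic(small_world):
    _, ds, _ = small_world
    a = fit_variational(ds.y, rt=ds.rt, method=2)
    b = fit_variational(ds.y, rt=ds.rt, method=2)
    for name in ("q", "f", "mu0", "sigma0", "mu1", "sigma1", "elbo_trace"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))


def test_plain_gradient_ascent_on_product_form_aborts_with_block_name(small_world):
    _, ds, _ = small_world
    with pytest.raises(FloatingPointError, match="block"):
        fit_variational(ds.y, schedule=Schedule(optimizer="gd"),
                        likelihood_form="product")


def test_methods_require_reaction_times(small_world):
    _, ds, _ = small_world
    for method in (1, 2):
        with pytest.raises(ValueError, match="reaction times"):
            fit_variational(ds.y, method=method)
    with pytest.raises(ValueError):
        fit_variational(ds.y, method=7)


def test_stop_rule_runs_past_minimum_when_elbo_still_moving(small_world):
    _, ds, _ = small_world
    state = fit_variational(ds.y, schedule=Schedule(min_iters=5, elbo_tol=0.1,
                                                    max_iters=4000))
    # with tol 0.1 the run must continue beyond 5 iterations while the
    # objective still moves by more than the tolerance
    assert len(state.elbo_trace) > 6
    assert abs(state.elbo_trace[-1] - state.elbo_trace[-2]) < 0.1


# ------------------------------------------------------------ reaction times

def test_rt_regularizer_zero_when_matched(rng):
    state = random_state(rng, 4, 3)
    matched = RTSummary(
        mean_rt=np.column_stack([
            mean_decision_time(state.mu0, state.sigma0),
            mean_decision_time(state.mu1, state.sigma1),
        ]),
        count=np.full((3, 2), 5),
    )
    assert rt_regularizer(state, matched, lam=2.0) == 0.0
    off = RTSummary(mean_rt=matched.mean_rt + 0.5, count=matched.count)
    assert rt_regularizer(state, off, lam=2.0) < 0
    assert rt_regularizer(state, off, lam=0.0) == 0.0
    with pytest.raises(ValueError):
        rt_regularizer(state, off, lam=-1.0)


def test_lambda_zero_reduces_to_plain_elbo(rng):
    state = random_state(rng, 4, 2)
    y = rng.integers(0, 2, (4, 2))
    summary = RTSummary(mean_rt=np.full((2, 2), 1.5), count=np.full((2, 2), 2))
    assert elbo_objective(y, state, rt=summary, lam=0.0) == pytest.approx(
        elbo_objective(y, state)
    )


def test_rt_regularized_fit_improves_drift_recovery():
    """With matched-RT information the drift estimates move towards truth."""
    err0, err1 = [], []
    for s in range(10):
        x, z = generate_items(150, seed=100 + s)
        ds = annotate_dataset(x, z, [AnnotatorDDM(0.3, 0.7, 0.3, 0.7)], 0.01,
                              seed=200 + s)
        plain = fit_variational(ds.y, method=0)
        reg = fit_variational(ds.y, rt=ds.rt, method=1)
        err0.append(abs(plain.mu0[0] - 0.3) + abs(plain.mu1[0] - 0.3))
        err1.append(abs(reg.mu0[0] - 0.3) + abs(reg.mu1[0] - 0.3))
    assert np.mean(err1) < np.mean(err0)


def test_rescale_matches_observed_rt_and_preserves_accuracy(small_world):
    _, ds, _ = small_world
    state = fit_variational(ds.y)
    summary = rt_summary_from_matrix(ds.rt, predicted_labels(state))
    rescaled = rescale_by_rt(state, summary)
    np.testing.assert_allclose(
        mean_decision_time(rescaled.mu0, rescaled.sigma0), summary.mean_rt[:, 0],
        rtol=1e-12,
    )
    np.testing.assert_allclose(
        mean_decision_time(rescaled.mu1, rescaled.sigma1), summary.mean_rt[:, 1],
        rtol=1e-12,
    )
    np.testing.assert_allclose(rescaled.sensitivities(), state.sensitivities(),
                               rtol=1e-12)
    np.testing.assert_allclose(rescaled.specificities(), state.specificities(),
                               rtol=1e-12)
    np.testing.assert_array_equal(predicted_labels(rescaled), predicted_labels(state))


def test_rescale_identity_when_already_matched(rng):
    state = random_state(rng, 4, 3)
    matched = RTSummary(
        mean_rt=np.column_stack([
            mean_decision_time(state.mu0, state.sigma0),
            mean_decision_time(state.mu1, state.sigma1),
        ]),
        count=np.full((3, 2), 5),
    )
    out = rescale_by_rt(state, matched)
    np.testing.assert_allclose(out.mu0, state.mu0, rtol=1e-12)
    np.testing.assert_allclose(out.sigma1, state.sigma1, rtol=1e-12)


def test_rescale_rejects_nonpositive_rt(rng):
    state = random_state(rng, 4, 2)
    with pytest.raises(ValueError):
        RTSummary(mean_rt=np.array([[1.0, -0.2], [1.0, 1.0]]),
                  count=np.full((2, 2), 3))


def test_rt_summary_conditions_and_fallback():
    rt = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    summary = rt_summary_from_matrix(rt, np.array([0, 0, 1]))
    np.testing.assert_allclose(summary.mean_rt[:, 0], [2.0, 3.0])
    np.testing.assert_allclose(summary.mean_rt[:, 1], [5.0, 6.0])
    assert summary.count.tolist() == [[2, 1], [2, 1]]
    # a condition with no items falls back to the overall annotator mean
    lone = rt_summary_from_matrix(rt, np.array([0, 0, 0]))
    np.testing.assert_allclose(lone.mean_rt[:, 1], rt.mean(axis=0))


# ------------------------------------------------------------------ supports

def test_support_estimates():
    state = make_state([0.5], [0.0], [0.2, 0.4, 0.3], [0.5, 0.6, 0.7],
                       [0.25, 0.35, 0.3], [0.6, 0.8, 0.7])
    sup = estimate_supports(state)
    assert sup.mu0 == (0.2, 0.4)
    assert sup.sigma0 == (0.5, 0.7)
    assert sup.mu1 == (0.25, 0.35)
    single = estimate_supports(make_state([0.5], [0.0], [0.3], [0.5], [0.2], [0.6]))
    assert single.mu0[0] == single.mu0[1]


def test_supports_overlap_generating_boxes(small_world):
    _, ds, _ = small_world
    state = fit_variational(ds.y, rt=ds.rt, method=2)
    sup = estimate_supports(state)
    for est, (lo, hi) in ((sup.mu0, (0.1, 0.5)), (sup.mu1, (0.1, 0.5)),
                          (sup.sigma0, (0.5, 0.9)), (sup.sigma1, (0.5, 0.9))):
        assert est[0] <= hi and est[1] >= lo


# ---------------------------------------------------------------- convention

def test_positive_branch_flip_is_consistent(small_world):
    _, ds, _ = small_world
    a = fit_variational(ds.y, rt=ds.rt, method=2)
    b = fit_variational(ds.y, rt=ds.rt, method=2, positive_branch=True)
    za, zb = predicted_labels(a), predicted_labels(b)
    # the flipped run reads q as P(z=1); decisions agree up to trajectory
    # differences caused by the (asymmetric) all-0.5 initialisation
    assert np.mean(za == zb) >= 0.95
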