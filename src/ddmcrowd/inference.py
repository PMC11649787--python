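"""Mean-field variational inference for drift-diffusion crowdsourcing.

The generative model: each item i has hidden class z_i produced by a logistic
link on a latent function value f_i; annotator j labels the item through one
of two drift-diffusion processes selected by z_i, so the probability of a
correct label is the logistic ``S(2 mu / sigma^2)`` of the matching
(drift, diffusion) pair.  Mean-field inference keeps a per-item posterior
probability q_i, a latent point value f_i, and point estimates of the four
per-annotator parameter vectors (mu0, sigma0, mu1, sigma1), and maximises an
evidence lower bound by full-batch ascent with analytic gradients.

The objective is

    sum_i ln [ w_i * prod_j a_ij + (1 - w_i) * prod_j b_ij ]     (data term)
    + sum_i [ q_i ln S(f_i) + (1 - q_i) ln (1 - S(f_i)) ]        (cross-entropy)
    - sum_i [ q_i ln q_i + (1 - q_i) ln (1 - q_i) ]              (negative entropy)
    + penalties                                                   (see below)

with w_i = S(f_i), a_ij the probability of the observed label under the
condition-0 process of annotator j (A_j = S(2 mu0_j / sigma0_j^2) if
y_ij = 0 else 1 - A_j) and b_ij the same under the condition-1 process.
The default data term is the mixture of products of per-annotator label
probabilities, the likelihood of conditionally independent annotators;
``likelihood_form="printed"`` selects a variant with the sum over annotators
moved inside the logarithm, whose per-item gradients are O(1/k)-damped (it
is retained for comparison but converges far more slowly).  Under the
default convention the w_i weight is paired with the condition-0 branch,
i.e. S(f_i) = P(z_i = 0); a global ``positive_branch`` flag flips the
pairing (S(f_i) = P(z_i = 1)).

Every bounded block (q and the four annotator vectors) carries a soft
containment penalty ``c(v) = -e^{beta (max v - 1)} - e^{-beta min v}``
(beta = 30 by default) that vanishes well inside (0, 1) and dominates the
objective as entries approach 0 or 1.  Latent values f are unconstrained by
default.

Reaction times enter in one of two ways.  Method 1 adds a regulariser
``-lambda * sum (E[tau](mu, sigma) - observed mean RT)^2`` over annotators
and conditions, where E[tau] is the Wald identity ``(2 S(2 mu/sigma^2)-1)/mu``
and items are assigned to conditions by thresholding the current q at 0.5
(the RT means are constants with respect to the gradient).  Method 2 runs
plain ascent and then rescales each (mu, sigma) by the accuracy-preserving
map (mu, sigma) -> (c mu, sqrt(c) sigma), with c chosen so the model-implied
mean decision time matches the observed one.

Optimisation is full-batch ascent from the all-0.5 start with step size
0.01, stopping at the later of 300 iterations and an ELBO change below 0.1.
The default update is Adam-style (moment-normalised, so each parameter moves
at most about one step size per iteration); plain gradient ascent
(``optimizer="gd"``) is available but is either divergent (product form:
early 1/probability gradient spikes overrun the containment penalty) or very
slow (printed form) at this step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .ddm import hit_probability, mean_decision_time

__all__ = [
    "Schedule",
    "VariationalState",
    "SupportEstimates",
    "RTSummary",
    "constraint_penalty",
    "data_log_likelihood",
    "elbo_objective",
    "rt_regularizer",
    "rt_summary_from_matrix",
    "fit_variational",
    "rescale_by_rt",
    "estimate_supports",
    "predicted_labels",
]

_EPS = 1e-9          # clipping for q inside logs / logits
_SIGMA_FLOOR = 1e-6  # hard guard: diffusion estimates stay positive

DEFAULT_LIKELIHOOD_FORM = "product"


@dataclass(frozen=True)
class Schedule:
    """Full-batch ascent schedule with a fixed step size.

    Ascent stops at the *later* of ``min_iters`` iterations and the first
    iteration where the ELBO changes by less than ``elbo_tol``; ``max_iters``
    is a hard cap guarding against non-termination.  ``optimizer`` is
    ``"adam"`` (moment-normalised updates, the default) or ``"gd"`` (plain
    gradient steps).
    """

    learning_rate: float = 0.01
    min_iters: int = 300
    elbo_tol: float = 0.1
    max_iters: int = 5000
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class VariationalState:
    """Posterior summaries: per-item (q_i, f_i) and per-annotator parameters.

    ``q`` is the posterior probability of the branch paired with the
    (mu0, sigma0) terms: P(z_i = 0) under the default convention,
    P(z_i = 1) when ``positive_branch`` is set.
    """

    q: np.ndarray
    f: np.ndarray
    mu0: np.ndarray
    sigma0: np.ndarray
    mu1: np.ndarray
    sigma1: np.ndarray
    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    positive_branch: bool = False

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_annotators(self) -> int:
        return self.mu0.shape[0]

    def sensitivities(self) -> np.ndarray:
        """Analytic per-annotator sensitivity S(2 mu1 / sigma1^2)."""
        return hit_probability(self.mu1, self.sigma1)

    def specificities(self) -> np.ndarray:
        """Analytic per-annotator specificity S(2 mu0 / sigma0^2)."""
        return hit_probability(self.mu0, self.sigma0)


@dataclass(frozen=True)
class SupportEstimates:
    """Recovered uniform-prior supports: per-family (min, max) over annotators."""

    mu0: tuple[float, float]
    mu1: tuple[float, float]
    sigma0: tuple[float, float]
    sigma1: tuple[float, float]


@dataclass(frozen=True)
class RTSummary:
    """Observed mean reaction time and item count per annotator x condition.

    ``mean_rt[j, c]`` is the mean RT of annotator j over the items assigned
    to condition c (0 or 1); ``count[j, c]`` the number of such items.
    """

    mean_rt: np.ndarray  # (k, 2)
    count: np.ndarray    # (k, 2)

    def __post_init__(self) -> None:
        if np.any(~(self.mean_rt > 0)):
            raise ValueError("observed mean reaction times must be positive")


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 2 or y.size == 0:
        raise ValueError("label matrix must be a non-empty (n, k) array")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return y.astype(np.int64)


def constraint_penalty(v, beta: float = 30.0, base: float = np.e) -> float:
    """Soft containment penalty ``-base^{beta (max v - 1)} - e^{-beta min v}``.

    Approximately zero when all entries sit well inside (0, 1); diverges to
    -inf as any entry approaches or crosses the interval ends.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("penalty requires a non-empty vector")
    return float(-base ** (beta * (np.max(v) - 1.0)) - np.exp(-beta * np.min(v)))


def _penalty_and_grad(v: np.ndarray, beta: float, base: float) -> tuple[float, np.ndarray]:
    # exponents capped at 700 so extreme excursions yield a huge finite
    # penalty/gradient instead of overflowing to inf
    g = np.zeros_like(v)
    upper = np.exp(min(np.log(base) * beta * (np.max(v) - 1.0), 700.0))
    lower = np.exp(min(-beta * np.min(v), 700.0))
    g[np.argmax(v)] -= np.log(base) * beta * upper
    g[np.argmin(v)] += beta * lower
    return float(-upper - lower), g


def _branch_probs(mu0, sigma0, mu1, sigma1) -> tuple[np.ndarray, np.ndarray]:
    for s in (sigma0, sigma1):
        if np.any(~(np.asarray(s) > 0)):
            raise ValueError("diffusion estimates must be strictly positive")
    A = expit(2.0 * np.asarray(mu0) / np.asarray(sigma0) ** 2)  # P(y=0 | z=0)
    B = expit(2.0 * np.asarray(mu1) / np.asarray(sigma1) ** 2)  # P(y=1 | z=1)
    return A, B


def _label_probs(y: np.ndarray, A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # u[i,j]: probability of the observed label under the condition-0 process
    # v[i,j]: same under the condition-1 process
    u = np.where(y == 0, A, 1.0 - A)
    v = np.where(y == 1, B, 1.0 - B)
    return u, v


def _mixture_term(w, u, v, form: str, positive_branch: bool):
    """Data term and partials wrt (w, u, v).

    Returns (value, dw, du, dv) where value = sum_i L_i.  ``w`` is the (n,)
    mixture weight paired with the condition-0 branch by default (condition-1
    branch when ``positive_branch``).
    """
    a, b = (v, u) if positive_branch else (u, v)
    wa = w[:, None]
    if form == "printed":
        # L_i = ln sum_j [w a_ij + (1-w) b_ij]
        T = np.sum(wa * a + (1.0 - wa) * b, axis=1)
        T = np.maximum(T, 1e-300)
        value = float(np.sum(np.log(T)))
        dw = np.sum(a - b, axis=1) / T
        da = wa / T[:, None]
        db = (1.0 - wa) / T[:, None]
    elif form == "product":
        # L_i = ln [w prod_j a_ij + (1-w) prod_j b_ij]
        la = np.sum(np.log(np.maximum(a, 1e-300)), axis=1)
        lb = np.sum(np.log(np.maximum(b, 1e-300)), axis=1)
        wc = np.clip(w, 1e-300, 1.0 - 1e-16)
        ta = np.log(wc) + la
        tb = np.log1p(-wc) + lb
        value = float(np.sum(np.logaddexp(ta, tb)))
        r = expit(ta - tb)  # posterior weight of branch a per item
        dw = r / wc - (1.0 - r) / (1.0 - wc)
        da = r[:, None] / np.maximum(a, 1e-300)
        db = (1.0 - r)[:, None] / np.maximum(b, 1e-300)
    else:
        raise ValueError(f"unknown likelihood_form {form!r}")
    du, dv = (db, da) if positive_branch else (da, db)
    return value, dw, du, dv


def data_log_likelihood(
    y: np.ndarray,
    state: VariationalState,
    likelihood_form: str = DEFAULT_LIKELIHOOD_FORM,
) -> float:
    """Log-likelihood of the label matrix with the state's q as mixture weights.

    ``likelihood_form="printed"`` keeps the sum over annotators inside the
    logarithm; ``"product"`` uses the conventional per-item mixture of
    per-annotator products.
    """
    y = _check_labels(y)
    A, B = _branch_probs(state.mu0, state.sigma0, state.mu1, state.sigma1)
    u, v = _label_probs(y, A, B)
    value, *_ = _mixture_term(
        np.asarray(state.q, dtype=float), u, v, likelihood_form, state.positive_branch
    )
    return value


def rt_summary_from_matrix(rt: np.ndarray, z_hat: np.ndarray) -> RTSummary:
    """Per annotator x condition observed RT means, conditions from ``z_hat``.

    A condition with no assigned items falls back to the annotator's overall
    mean RT (the regulariser then pulls towards the marginal rather than
    being undefined).
    """
    rt = np.asarray(rt, dtype=float)
    if np.any(~(rt > 0)):
        raise ValueError("reaction times must be strictly positive")
    z_hat = np.asarray(z_hat)
    k = rt.shape[1]
    mean_rt = np.empty((k, 2))
    count = np.zeros((k, 2), dtype=np.int64)
    overall = rt.mean(axis=0)
    for c in (0, 1):
        mask = z_hat == c
        count[:, c] = mask.sum()
        mean_rt[:, c] = rt[mask].mean(axis=0) if mask.any() else overall
    return RTSummary(mean_rt=mean_rt, count=count)


def _wald_time_and_grads(mu, sigma):
    """E[tau] = (2 S(2 mu/sigma^2) - 1)/mu and its partials wrt mu, sigma."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    sigma2 = sigma**2
    p = expit(2.0 * mu / sigma2)
    pq = p * (1.0 - p)
    small = np.abs(mu) < 1e-8
    safe_mu = np.where(small, 1.0, mu)
    t = np.where(small, 1.0 / sigma2, (2.0 * p - 1.0) / safe_mu)
    # d/dmu [(2p-1)/mu] = (4 pq / sigma^2) / mu - (2p-1)/mu^2; -> -4/(3 sigma^4) * ... at mu->0
    dt_dmu = np.where(
        small,
        0.0,  # limit is -(4/3) mu / sigma^6 * ... -> 0 only at mu=0 exactly; treated as 0
        (4.0 * pq / sigma2) / safe_mu - (2.0 * p - 1.0) / safe_mu**2,
    )
    dt_dsigma = np.where(
        small,
        -2.0 / sigma**3,
        (2.0 / safe_mu) * pq * (-4.0 * mu / sigma**3),
    )
    return t, dt_dmu, dt_dsigma


def rt_regularizer(state: VariationalState, rt: RTSummary, lam: float = 1.0) -> float:
    """Squared-error pull of model-implied mean decision times towards data.

    ``-lam * sum_{j,c} (E[tau](mu_c_j, sigma_c_j) - mean_rt[j, c])^2``; zero
    when the Wald-implied and observed means coincide.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    t0 = mean_decision_time(state.mu0, state.sigma0)
    t1 = mean_decision_time(state.mu1, state.sigma1)
    return float(-lam * (np.sum((t0 - rt.mean_rt[:, 0]) ** 2) + np.sum((t1 - rt.mean_rt[:, 1]) ** 2)))


def _objective_and_grads(
    y: np.ndarray,
    q: np.ndarray,
    f: np.ndarray,
    mu0: np.ndarray,
    sigma0: np.ndarray,
    mu1: np.ndarray,
    sigma1: np.ndarray,
    *,
    beta: float | None = 30.0,
    penalty_base: float = np.e,
    likelihood_form: str = DEFAULT_LIKELIHOOD_FORM,
    positive_branch: bool = False,
    penalize_f: bool = False,
    rt_means: np.ndarray | None = None,
    lam: float = 0.0,
):
    """ELBO (+ penalties, + optional RT regulariser) and analytic gradients."""
    s = expit(f)
    A, B = _branch_probs(mu0, sigma0, mu1, sigma1)
    u, v = _label_probs(y, A, B)
    ll, dw, du, dv = _mixture_term(s, u, v, likelihood_form, positive_branch)

    qc = np.clip(q, _EPS, 1.0 - _EPS)
    log_s = -np.logaddexp(0.0, -f)       # ln S(f)
    log_1ms = -np.logaddexp(0.0, f)      # ln (1 - S(f))
    cross = float(np.sum(qc * log_s + (1.0 - qc) * log_1ms))
    entropy = float(-np.sum(qc * np.log(qc) + (1.0 - qc) * np.log(1.0 - qc)))

    value = ll + cross + entropy
    g_f = dw * s * (1.0 - s) + (qc - s)
    g_q = f - (np.log(qc) - np.log(1.0 - qc))

    # chain rule through A = S(2 mu0 / sigma0^2), B = S(2 mu1 / sigma1^2)
    dL_dA = np.sum(du * np.where(y == 0, 1.0, -1.0), axis=0)
    dL_dB = np.sum(dv * np.where(y == 1, 1.0, -1.0), axis=0)
    Apq, Bpq = A * (1.0 - A), B * (1.0 - B)
    g_mu0 = dL_dA * Apq * 2.0 / sigma0**2
    g_sigma0 = dL_dA * Apq * (-4.0 * mu0 / sigma0**3)
    g_mu1 = dL_dB * Bpq * 2.0 / sigma1**2
    g_sigma1 = dL_dB * Bpq * (-4.0 * mu1 / sigma1**3)

    blocks = {"q": (qc, g_q), "mu0": (mu0, g_mu0), "sigma0": (sigma0, g_sigma0),
              "mu1": (mu1, g_mu1), "sigma1": (sigma1, g_sigma1)}
    if penalize_f:
        blocks["f"] = (f, g_f)
    grads = {"q": g_q, "f": g_f, "mu0": g_mu0, "sigma0": g_sigma0,
             "mu1": g_mu1, "sigma1": g_sigma1}
    if beta is not None:
        for name, (vec, g) in blocks.items():
            pen, gpen = _penalty_and_grad(np.asarray(vec, dtype=float), beta, penalty_base)
            value += pen
            g += gpen

    if rt_means is not None and lam > 0:
        t0, dt0_dmu, dt0_dsigma = _wald_time_and_grads(mu0, sigma0)
        t1, dt1_dmu, dt1_dsigma = _wald_time_and_grads(mu1, sigma1)
        r0 = t0 - rt_means[:, 0]
        r1 = t1 - rt_means[:, 1]
        value += float(-lam * (np.sum(r0**2) + np.sum(r1**2)))
        grads["mu0"] += -2.0 * lam * r0 * dt0_dmu
        grads["sigma0"] += -2.0 * lam * r0 * dt0_dsigma
        grads["mu1"] += -2.0 * lam * r1 * dt1_dmu
        grads["sigma1"] += -2.0 * lam * r1 * dt1_dsigma

    return value, grads


def elbo_objective(
    y: np.ndarray,
    state: VariationalState,
    *,
    beta: float | None = 30.0,
    penalty_base: float = np.e,
    likelihood_form: str = DEFAULT_LIKELIHOOD_FORM,
    penalize_f: bool = False,
    rt: RTSummary | None = None,
    lam: float = 0.0,
) -> float:
    """Evaluate the full ascent objective at a state.

    ``beta=None`` drops the containment penalties (the bare ELBO); supplying
    an :class:`RTSummary` with ``lam > 0`` adds the Method-1 regulariser.
    """
    y = _check_labels(y)
    value, _ = _objective_and_grads(
        y, np.asarray(state.q, float), np.asarray(state.f, float),
        np.asarray(state.mu0, float), np.asarray(state.sigma0, float),
        np.asarray(state.mu1, float), np.asarray(state.sigma1, float),
        beta=beta,
        penalty_base=penalty_base,
        likelihood_form=likelihood_form,
        positive_branch=state.positive_branch,
        penalize_f=penalize_f,
        rt_means=None if rt is None else rt.mean_rt,
        lam=lam,
    )
    return value


def predicted_labels(state: VariationalState) -> np.ndarray:
    """Hard labels from q thresholded at 0.5; ties resolve to class 0."""
    p1 = state.q if state.positive_branch else 1.0 - state.q
    return (p1 > 0.5).astype(np.int64)


def fit_variational(
    y: np.ndarray,
    rt: np.ndarray | RTSummary | None = None,
    method: int = 0,
    schedule: Schedule = Schedule(),
    *,
    beta: float = 30.0,
    penalty_base: float = np.e,
    lam: float = 1.0,
    likelihood_form: str = DEFAULT_LIKELIHOOD_FORM,
    positive_branch: bool = False,
    penalize_f: bool = False,
) -> VariationalState:
    """Full-batch gradient ascent on the ELBO from the all-0.5 start.

    ``method=0`` ignores reaction times; ``method=1`` adds the RT
    regulariser (requires ``rt``); ``method=2`` runs plain ascent and then
    rescales the annotator parameters to match observed mean RTs (requires
    ``rt``).  ``rt`` may be the raw (n, k) reaction-time matrix (condition
    means recomputed each iteration from the current q for method 1) or a
    fixed :class:`RTSummary`.
    """
    y = _check_labels(y)
    n, k = y.shape
    if method not in (0, 1, 2):
        raise ValueError(f"method must be 0, 1 or 2, got {method!r}")
    rt_matrix: np.ndarray | None = None
    rt_fixed: RTSummary | None = None
    if isinstance(rt, RTSummary):
        rt_fixed = rt
    elif rt is not None:
        rt_matrix = np.asarray(rt, dtype=float)
        if rt_matrix.shape != y.shape:
            raise ValueError("rt matrix must match the label matrix shape")
        if np.any(~(rt_matrix > 0)):
            raise ValueError("reaction times must be strictly positive")
    if method in (1, 2) and rt_fixed is None and rt_matrix is None:
        raise ValueError(f"method {method} requires reaction times")

    q = np.full(n, 0.5)
    f = np.full(n, 0.5)
    mu0 = np.full(k, 0.5)
    sigma0 = np.full(k, 0.5)
    mu1 = np.full(k, 0.5)
    sigma1 = np.full(k, 0.5)
    lr = schedule.learning_rate
    trace: list[float] = []

    # Adam moment buffers (ignored under optimizer="gd")
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    m1 = {name: 0.0 for name in ("q", "f", "mu0", "sigma0", "mu1", "sigma1")}
    m2 = dict(m1)

    def step(name: str, value: np.ndarray, g: np.ndarray, it: int) -> np.ndarray:
        if schedule.optimizer == "gd":
            return value + lr * g
        m1[name] = b1 * m1[name] + (1.0 - b1) * g
        m2[name] = b2 * m2[name] + (1.0 - b2) * g**2
        mhat = m1[name] / (1.0 - b1 ** (it + 1))
        vhat = m2[name] / (1.0 - b2 ** (it + 1))
        return value + lr * mhat / (np.sqrt(vhat) + adam_eps)

    for it in range(schedule.max_iters + 1):
        rt_means = None
        use_lam = 0.0
        if method == 1:
            if rt_fixed is not None:
                rt_means = rt_fixed.mean_rt
            else:
                p1 = q if positive_branch else 1.0 - q
                rt_means = rt_summary_from_matrix(rt_matrix, (p1 > 0.5).astype(int)).mean_rt
            use_lam = lam
        with np.errstate(over="ignore", invalid="ignore"):
            value, grads = _objective_and_grads(
                y, q, f, mu0, sigma0, mu1, sigma1,
                beta=beta, penalty_base=penalty_base,
                likelihood_form=likelihood_form, positive_branch=positive_branch,
                penalize_f=penalize_f, rt_means=rt_means, lam=use_lam,
            )
        for name, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    f"non-finite gradient in block {name!r} at iteration {it}"
                )
        trace.append(value)
        if len(trace) >= 2 and it >= schedule.min_iters and \
                abs(trace[-1] - trace[-2]) < schedule.elbo_tol:
            break
        if it == schedule.max_iters:
            break
        q = np.clip(step("q", q, grads["q"], it), _EPS, 1.0 - _EPS)
        f = step("f", f, grads["f"], it)
        mu0 = step("mu0", mu0, grads["mu0"], it)
        mu1 = step("mu1", mu1, grads["mu1"], it)
        sigma0 = np.maximum(step("sigma0", sigma0, grads["sigma0"], it), _SIGMA_FLOOR)
        sigma1 = np.maximum(step("sigma1", sigma1, grads["sigma1"], it), _SIGMA_FLOOR)

    state = VariationalState(
        q=q, f=f, mu0=mu0, sigma0=sigma0, mu1=mu1, sigma1=sigma1,
        elbo_trace=np.asarray(trace), positive_branch=positive_branch,
    )
    if method == 2:
        summary = rt_fixed
        if summary is None:
            summary = rt_summary_from_matrix(rt_matrix, predicted_labels(state))
        state = rescale_by_rt(state, summary)
    return state


def rescale_by_rt(state: VariationalState, rt: RTSummary) -> VariationalState:
    """Match observed mean RTs by the accuracy-preserving map (mu, sigma) -> (c mu, sqrt(c) sigma).

    Under that map the hit probability S(2 mu / sigma^2) is exactly invariant
    while the expected decision time scales by 1/c, so c is chosen per
    annotator and condition as model-implied E[tau] / observed mean RT.
    """
    if np.any(~(rt.mean_rt > 0)):
        raise ValueError("observed mean reaction times must be positive")
    c0 = mean_decision_time(state.mu0, state.sigma0) / rt.mean_rt[:, 0]
    c1 = mean_decision_time(state.mu1, state.sigma1) / rt.mean_rt[:, 1]
    return replace(
        state,
        mu0=state.mu0 * c0, sigma0=state.sigma0 * np.sqrt(c0),
        mu1=state.mu1 * c1, sigma1=state.sigma1 * np.sqrt(c1),
    )


def estimate_supports(state: VariationalState) -> SupportEstimates:
    """Recovered uniform-prior supports: per-family min/max of the estimates."""
    return SupportEstimates(
        mu0=(float(np.min(state.mu0)), float(np.max(state.mu0))),
        mu1=(float(np.min(state.mu1)), float(np.max(state.mu1))),
        sigma0=(float(np.min(state.sigma0)), float(np.max(state.sigma0))),
        sigma1=(float(np.min(state.sigma1)), float(np.max(state.sigma1))),
    )
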