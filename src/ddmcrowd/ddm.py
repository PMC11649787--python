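"""Closed-form quantities for the symmetric-boundary drift-diffusion model.

The evidence process is ``dX = mu dt + sigma dW`` started at the offset 0 with
absorbing boundaries at +1 and -1.  For this symmetric geometry the probability
of absorption at the upper boundary and the expected absorption time have
closed forms:

* ``P(hit +1 before -1) = S(2 mu / sigma^2)`` with ``S`` the logistic function,
* ``E[tau] = (2 P - 1) / mu`` for ``mu != 0`` (optional-stopping / Wald
  identity ``E[X(tau)] = mu E[tau]``), with the zero-drift limit
  ``E[tau] = 1 / sigma^2`` (Brownian absorption time ``a^2 / sigma^2``, a = 1).

An annotator is a pair of such processes, one per ground-truth condition:
``(mu1, sigma1)`` generates labels when the true class is 1 (its hit
probability is the annotator's sensitivity) and ``(mu0, sigma0)`` when the
true class is 0 (specificity).

These are pure functions consumed by the simulator, the variational engine
and the evaluation code.  Scalar wrappers operate on the frozen dataclasses;
the ``hit_probability`` / ``mean_decision_time`` helpers broadcast over numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DDMParams",
    "AnnotatorDDM",
    "hit_probability",
    "mean_decision_time",
    "correct_probability",
    "expected_decision_time",
    "annotator_sensitivity_specificity",
]


@dataclass(frozen=True)
class DDMParams:
    """Drift and diffusion of one conditional decision process.

    Parameters
    ----------
    drift : float
        Mean evidence accumulation rate (evidence units per second).  Any
        sign is legal; positive drift favours the upper (+1) boundary.
    diffusion : float
        Noise scale of the evidence process (evidence units per sqrt-second);
        strictly positive.
    """

    drift: float
    diffusion: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.drift):
            raise ValueError("drift must be finite")
        if not (np.isfinite(self.diffusion) and self.diffusion > 0):
            raise ValueError(f"diffusion must be strictly positive, got {self.diffusion}")


@dataclass(frozen=True)
class AnnotatorDDM:
    """One annotator: a conditional decision process per ground-truth class."""

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float

    def __post_init__(self) -> None:
        if not (self.sigma0 > 0 and self.sigma1 > 0):
            raise ValueError("annotator diffusion rates must be strictly positive")

    @property
    def condition0(self) -> DDMParams:
        return DDMParams(self.mu0, self.sigma0)

    @property
    def condition1(self) -> DDMParams:
        return DDMParams(self.mu1, self.sigma1)


def _check_diffusion(diffusion: np.ndarray) -> None:
    if np.any(~(np.asarray(diffusion) > 0)):
        raise ValueError("diffusion must be strictly positive")


def hit_probability(drift, diffusion):
    """Probability of absorption at +1 before -1, ``S(2 mu / sigma^2)``.

    Broadcasts over array inputs.  ``expit`` evaluates the logistic in a
    branch-stable way, so arguments of any magnitude are safe.
    """
    drift = np.asarray(drift, dtype=float)
    diffusion = np.asarray(diffusion, dtype=float)
    _check_diffusion(diffusion)
    return expit(2.0 * drift / diffusion**2)


def mean_decision_time(drift, diffusion):
    """Expected absorption time ``(2 P - 1) / mu``; zero-drift limit ``1/sigma^2``.

    Continuous at ``mu -> 0``: ``(2 S(2 mu / sigma^2) - 1)/mu -> 1/sigma^2``.
    Broadcasts over array inputs.
    """
    drift = np.asarray(drift, dtype=float)
    diffusion = np.asarray(diffusion, dtype=float)
    _check_diffusion(diffusion)
    sigma2 = diffusion**2
    small = np.abs(drift) < 1e-10
    safe_drift = np.where(small, 1.0, drift)
    p = expit(2.0 * drift / sigma2)
    with np.errstate(invalid="ignore"):
        t = (2.0 * p - 1.0) / safe_drift
    return np.where(small, 1.0 / sigma2, t)


def correct_probability(params: DDMParams) -> float:
    """Probability that the process hits +1 (the correct boundary) first."""
    return float(hit_probability(params.drift, params.diffusion))


def expected_decision_time(params: DDMParams) -> float:
    """Expected first-passage (decision) time in seconds."""
    return float(mean_decision_time(params.drift, params.diffusion))


def annotator_sensitivity_specificity(a: AnnotatorDDM) -> tuple[float, float]:
    """Analytic (sensitivity, specificity) of an annotator.

    Sensitivity is the condition-1 hit probability ``S(2 mu1 / sigma1^2)``;
    specificity the condition-0 one ``S(2 mu0 / sigma0^2)``.
    """
    sens = float(hit_probability(a.mu1, a.sigma1))
    spec = float(hit_probability(a.mu0, a.sigma0))
    return sens, spec
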