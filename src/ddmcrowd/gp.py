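"""Gaussian-process classification from inferred latent function values.

Rather than fitting a classification likelihood directly, a zero-mean GP
*regressor* is trained from item features to the latent values f_i produced
by variational inference, and new points are classified by thresholding the
predicted latent through the logistic link.  The kernel is an RBF
(amplitude * exp(-||x - x'||^2 / (2 l^2))) plus a white-noise term;
hyperparameters are selected by marginal-likelihood maximisation with the
length scale constrained to [0.001, 1000] and the white-noise variance to
[0.001, 10].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = ["GPClassifierModel", "fit_gp", "predict_label", "predict_labels"]

LENGTH_SCALE_BOUNDS = (1e-3, 1e3)
NOISE_BOUNDS = (1e-3, 10.0)


@dataclass
class GPClassifierModel:
    """A fitted latent-value GP with the decision convention attached.

    ``positive_branch=False`` (default) means the training latents encode
    P(z = 0) = S(f), so positive predicted latents map to class 0;
    ``positive_branch=True`` flips the mapping (S(f) = P(z = 1), the Eq.-5
    style convention).  ``p_star`` is always reported on the P(z = 1) scale.
    """

    regressor: GaussianProcessRegressor
    x_train: np.ndarray
    f_train: np.ndarray
    positive_branch: bool = False

    @property
    def kernel_params(self) -> dict:
        k = self.regressor.kernel_
        return {
            "amplitude": float(k.k1.k1.constant_value),
            "length_scale": float(k.k1.k2.length_scale),
            "noise_level": float(k.k2.noise_level),
        }

    def to_files(self, json_path, csv_path) -> None:
        """Persist hyperparameters (JSON) and training data (CSV)."""
        payload = {
            "schema_version": 1,
            "kind": "ddmcrowd.gp_classifier",
            "positive_branch": self.positive_branch,
            "kernel": self.kernel_params,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        df = pd.DataFrame(
            {"x1": self.x_train[:, 0], "x2": self.x_train[:, 1], "f": self.f_train}
        )
        df.to_csv(csv_path, index=False, float_format="%.17g")

    @classmethod
    def from_files(cls, json_path, csv_path) -> "GPClassifierModel":
        payload = json.loads(Path(json_path).read_text())
        kp = payload["kernel"]
        kernel = (
            ConstantKernel(kp["amplitude"], "fixed")
            * RBF(kp["length_scale"], "fixed")
            + WhiteKernel(kp["noise_level"], "fixed")
        )
        df = pd.read_csv(csv_path, float_precision="round_trip")
        x = df[["x1", "x2"]].to_numpy()
        f = df["f"].to_numpy()
        reg = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        reg.fit(x, f)
        return cls(
            regressor=reg, x_train=x, f_train=f,
            positive_branch=bool(payload["positive_branch"]),
        )


def fit_gp(
    x: np.ndarray,
    f: np.ndarray,
    *,
    seed: int = 0,
    n_restarts: int = 5,
    positive_branch: bool = False,
) -> GPClassifierModel:
    """Fit the RBF + white-noise GP regressor to (features, latents).

    Hyperparameters maximise the log marginal likelihood within the module
    bounds, with ``n_restarts`` seeded restarts of the optimiser.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if x.ndim != 2 or x.shape[0] != f.shape[0]:
        raise ValueError("x must be (n, d) with one latent target per row")
    if x.shape[0] < 2:
        raise ValueError("at least two training points are required")
    if not (np.isfinite(x).all() and np.isfinite(f).all()):
        raise ValueError("inputs and latent targets must be finite")
    if np.unique(x, axis=0).shape[0] == 1:
        raise ValueError(
            "degenerate training inputs: all points coincide, so the kernel "
            "matrix is singular up to the noise term and the GP cannot be "
            "conditioned"
        )
    kernel = (
        ConstantKernel(1.0, (1e-5, 1e5))
        * RBF(1.0, LENGTH_SCALE_BOUNDS)
        + WhiteKernel(1e-2, NOISE_BOUNDS)
    )
    reg = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
        normalize_y=False,
    )
    # noiseless latents legitimately pin the white-noise variance at its
    # lower bound; sklearn's advisory warning about that is expected
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        reg.fit(x, f)
    return GPClassifierModel(
        regressor=reg, x_train=x, f_train=f, positive_branch=positive_branch
    )


def predict_labels(model: GPClassifierModel, x_star: np.ndarray):
    """Predict latents, hard labels and P(z = 1) for an array of points.

    Returns ``(f_star, z_star, p_star)``.  Under the active convention
    ``z_star = 1`` iff P(z = 1 | f_star) > 0.5; an exact tie (f_star = 0)
    resolves to class 0 for determinism.
    """
    if not hasattr(model.regressor, "X_train_"):
        raise ValueError("model has not been fitted")
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    f_star = model.regressor.predict(x_star)
    p_star = expit(f_star) if model.positive_branch else expit(-f_star)
    z_star = (p_star > 0.5).astype(np.int64)
    return f_star, z_star, p_star


def predict_label(model: GPClassifierModel, x_star) -> tuple[float, int, float]:
    """Single-point convenience wrapper: (f_star, z_star, p_star)."""
    f_star, z_star, p_star = predict_labels(model, np.asarray(x_star, dtype=float).reshape(1, -1))
    return float(f_star[0]), int(z_star[0]), float(p_star[0])
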