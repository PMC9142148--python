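"""The decoder families benchmarked for grip-force regression.

Five families share one small interface (``fit``/``predict``):

* Wiener filter — multivariable linear model over lagged band-power features
  y(n) = sum_j sum_i w_ij x_i(n-j), solved in closed form via the normal
  equation (tiny ridge jitter for conditioning).
* Elastic net — the l1/l2-regularized linear model,
  min_w 1/(2n) ||Xw - y||^2 + a*r*||w||_1 + a*(1-r)/2*||w||^2,
  via scikit-learn's coordinate descent (max_iter 1000); a=0 falls back to
  ordinary least squares.
* MLP — 1-3 dense hidden layers of 1-10 units, sigmoid/tanh, linear output,
  Adam (b1=0.9, b2=0.999), MSE loss, batch 100, up to 1000 epochs with
  early stopping on an inner 80/20 validation split (patience 10).
* Gradient-boosted trees — 10 boosting rounds; tree depth, learning rate eta
  and minimum splitting loss gamma are hyperparameters. gamma follows the
  n-scaled gain convention of boosting frameworks, hence the mapping
  min_impurity_decrease = gamma / n_samples.
* SPoC — source power comodulation: a spatial filter maximizing the
  comodulation of projected band power with a continuous z-scored target
  (generalized eigenvalue problem); one filter per band, features are the
  log-variance of the projected signal per epoch.

``r2_score`` implements the coefficient of determination with an optional
floor at zero (negative values are reported as 0 for comparability, the raw
value is what the function returns without the flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as sla
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import ElasticNet
from sklearn.neural_network import MLPRegressor

FAMILIES = ("WIENER", "ENET", "MLP", "GBT", "SPOC_ENET", "SPOC_GBT")


@dataclass
class WienerFilter:
    """Closed-form least-squares linear decoder over lagged features."""

    ridge_jitter: float = 1e-8
    coef_: np.ndarray = field(default=None, repr=False)
    intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WienerFilter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        xm, ym = X.mean(axis=0), y.mean()
        Xc, yc = X - xm, y - ym
        gram = Xc.T @ Xc
        p = X.shape[1]
        jitter = self.ridge_jitter * np.trace(gram) / max(p, 1)
        try:
            w = sla.solve(gram + jitter * np.eye(p), Xc.T @ yc, assume_a="pos")
        except sla.LinAlgError:
            import warnings

            warnings.warn("WienerFilter: rank-deficient design, using pseudo-inverse")
            w = np.linalg.pinv(Xc) @ yc
        self.coef_ = w
        self.intercept_ = ym - xm @ w
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def fit_wiener(X: np.ndarray, y: np.ndarray) -> WienerFilter:
    return WienerFilter().fit(X, y)


def fit_elastic_net(X: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float):
    """Elastic net at (alpha, rho); alpha=0 reduces to ordinary least squares."""
    if alpha < 0 or not 0 <= l1_ratio <= 1:
        raise ValueError("require alpha >= 0 and l1_ratio in [0, 1]")
    if alpha == 0:
        return WienerFilter(ridge_jitter=0.0).fit(X, y)
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=1000)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    n_layers: int = 1,
    units: int = 10,
    activation: str = "tanh",
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> MLPRegressor:
    """Small fully-connected regressor with early stopping (patience 10)."""
    if not 1 <= n_layers <= 3 or not 1 <= units <= 10:
        raise ValueError("MLP: n_layers in 1..3 and units in 1..10")
    act = {"sigmoid": "logistic", "logistic": "logistic", "tanh": "tanh"}[activation]
    model = MLPRegressor(
        hidden_layer_sizes=(units,) * n_layers,
        activation=act,
        solver="adam",
        learning_rate_init=learning_rate,
        beta_1=0.9,
        beta_2=0.999,
        batch_size=min(100, len(y)),
        max_iter=1000,
        early_stopping=True,
        validation_fraction=0.2,
        n_iter_no_change=10,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    if not np.all(np.isfinite(model.loss_curve_)):
        raise RuntimeError(
            f"MLP training diverged; last finite epoch {int(np.sum(np.isfinite(model.loss_curve_)))}"
        )
    return model


def fit_gbt(
    X: np.ndarray,
    y: np.ndarray,
    depth: int = 3,
    eta: float = 0.3,
    gamma: float = 1.0,
    n_rounds: int = 10,
    seed: int = 0,
) -> GradientBoostingRegressor:
    """Gradient-boosted regression trees, 10 boosting rounds by default."""
    n = len(y)
    model = GradientBoostingRegressor(
        n_estimators=n_rounds,
        max_depth=int(depth),
        learning_rate=eta,
        min_impurity_decrease=gamma / max(n, 1),
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


# ---------------------------------------------------------------------------
# SPoC


@dataclass
class SpocFilter:
    w: np.ndarray  # (channels,)
    eigenvalue: float
    comodulation_sign: float  # sign of training covariance(feature, target)

    def project(self, epochs: np.ndarray) -> np.ndarray:
        """Log-variance of the projected signal per epoch.

        ``epochs``: (n_epochs, n_channels, n_times).
        """
        proj = np.einsum("c,ect->et", self.w, epochs)
        return np.log(np.var(proj, axis=1) + 1e-30)


def spoc_fit(epochs: np.ndarray, z: np.ndarray, shrinkage: float = 1e-6) -> SpocFilter:
    """Fit the single best SPoC spatial filter.

    Solves the generalized eigenvalue problem Cz w = lambda C w with
    Cz = mean_e z_e C_e (target-weighted covariance) and C = mean_e C_e, and
    keeps the eigenvector of largest |lambda|, i.e. strongest power
    comodulation with the (z-scored) target. A scaled identity is added to C
    when it is ill-conditioned.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[1] < 2:
        raise ValueError("epochs must be (n_epochs, n_channels>=2, n_times)")
    z = np.asarray(z, dtype=float)
    z = (z - z.mean()) / z.std()
    covs = np.einsum("ect,edt->ecd", epochs, epochs) / epochs.shape[2]
    C = covs.mean(axis=0)
    Cz = np.tensordot(z, covs, axes=1) / len(z)
    C = C + shrinkage * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
    evals, evecs = sla.eigh(Cz, C)
    k = int(np.argmax(np.abs(evals)))
    w = evecs[:, k]
    filt = SpocFilter(w=w, eigenvalue=float(evals[k]), comodulation_sign=1.0)
    feats = filt.project(epochs)
    filt.comodulation_sign = float(np.sign(np.cov(feats, z)[0, 1]) or 1.0)
    return filt


def spoc_features(epochs: np.ndarray, filt: SpocFilter) -> np.ndarray:
    """Log-variance feature series for a fitted filter (one value per epoch)."""
    return filt.project(np.asarray(epochs, dtype=float))


# ---------------------------------------------------------------------------


def r2_score(y: np.ndarray, y_hat: np.ndarray, floor_at_zero: bool = False) -> float:
    """Coefficient of determination R2 = 1 - SS_res / SS_tot.

    With ``floor_at_zero`` negative values (worse than predicting the mean)
    are reported as 0.0 for comparability across channels and models.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2:
        raise ValueError("r2_score needs n >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("r2_score undefined for constant y")
    r2 = 1.0 - np.sum((y - y_hat) ** 2) / ss_tot
    return max(0.0, r2) if floor_at_zero else float(r2)
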