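"""Nested cross-validation with Bayesian hyperparameter search, channel
selection, coefficient maps, lag sweeps, and the permutation statistics.

The evaluation scheme mirrors a strict no-leakage protocol for
autocorrelated neural time series: an outer threefold split over contiguous
time blocks (2/3 train, 1/3 test), and, per outer fold, 10 rounds of
Bayesian optimization (Gaussian process with a Matern-5/2 kernel, expected
improvement acquisition, 5 random + 5 model-guided points) scored by inner
cross-validation on the training block only (three contiguous 80/20 splits;
a single 80/20 split for the MLP, whose inner CV is skipped). The winner is
refit on the whole training block and the test block is predicted exactly
once, so the out-of-fold prediction trace covers every retained row once.

Significance testing is two-sided Monte-Carlo permutation throughout: index
shuffling for exchangeable pairs, autocorrelation-preserving circular label
shifts (minimum offset 10 s) for time-series decoding nulls. Multiple
comparisons are adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from statsmodels.stats.multitest import multipletests

from . import models as _models
from .features import FeatureSeries
from .models import r2_score

# ---------------------------------------------------------------------------
# hyperparameter spaces

#: distribution spec: ("uniform", lo, hi) | ("loguniform", lo, hi)
#: | ("randint", lo, hi incl.) | ("choice", [values])
SpaceSpec = dict[str, tuple]


def hyperparameter_space(family: str) -> SpaceSpec:
    if family == "ENET":
        return {"alpha": ("uniform", 0.0, 1.0), "l1_ratio": ("uniform", 0.0, 1.0)}
    if family == "MLP":
        return {
            "n_layers": ("randint", 1, 3),
            "units": ("randint", 1, 10),
            "activation": ("choice", ["sigmoid", "tanh"]),
            "learning_rate": ("loguniform", 1e-4, 1e-2),
        }
    if family == "GBT":
        return {
            "depth": ("randint", 1, 100),
            "eta": ("loguniform", 1e-5, 1.0),
            "gamma": ("uniform", 1.0, 10.0),
        }
    if family in ("WIENER",):
        return {}
    raise ValueError(f"unknown model family {family!r}")


def _sample(space: SpaceSpec, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "randint":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "choice":
            out[name] = spec[1][int(rng.integers(len(spec[1]))) ]
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    return out


def _encode(space: SpaceSpec, params: dict) -> np.ndarray:
    v = []
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            v.append((params[name] - spec[1]) / (spec[2] - spec[1]))
        elif kind == "loguniform":
            v.append(
                (np.log(params[name]) - np.log(spec[1]))
                / (np.log(spec[2]) - np.log(spec[1]))
            )
        elif kind == "randint":
            v.append((params[name] - spec[1]) / max(spec[2] - spec[1], 1))
        elif kind == "choice":
            v.append(spec[1].index(params[name]) / max(len(spec[1]) - 1, 1))
    return np.asarray(v)


def bayes_optimize(
    space: SpaceSpec,
    objective: Callable[[dict], float],
    rounds: int = 10,
    seed: int = 0,
    n_init: int = 5,
    n_candidates: int = 256,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize ``objective`` over ``space`` in at most ``rounds`` evaluations.

    First ``n_init`` points are random; the rest maximize expected
    improvement under a Gaussian process (Matern-5/2) fit to the evaluated
    points. Non-finite objective values are scored as worst-so-far and the
    search continues. Returns (best params, evaluation history).
    """
    rng = np.random.default_rng(seed)
    if not space:
        return {}, []
    history: list[tuple[dict, float]] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []

    def record(params: dict) -> None:
        val = objective(params)
        if not np.isfinite(val):
            finite = [v for v in y_obs if np.isfinite(v)]
            val = (max(finite) + 1.0) if finite else 1e6
        history.append((params, float(val)))
        X_obs.append(_encode(space, params))
        y_obs.append(float(val))

    for _ in range(min(n_init, rounds)):
        record(_sample(space, rng))
    for _ in range(rounds - min(n_init, rounds)):
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(len(space), 0.5)),
            alpha=1e-6,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(X_obs), np.asarray(y_obs))
        cands = [_sample(space, rng) for _ in range(n_candidates)]
        Xc = np.vstack([_encode(space, c) for c in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = min(y_obs)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu) / sd
            ei = (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
        ei[sd <= 0] = 0.0
        record(cands[int(np.argmax(ei))])
    best_idx = int(np.argmin(y_obs))
    return history[best_idx][0], history


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class DecodingResult:
    family: str
    channel: Optional[str]
    fold_r2_raw: list[float]
    fold_r2_floored: list[float]
    fold_params: list[dict]
    prediction: np.ndarray  # out-of-fold trace, one value per retained row
    seed: int

    @property
    def mean_r2(self) -> float:
        """Mean raw test-set R2 across outer folds (the performance measure)."""
        return float(np.mean(self.fold_r2_raw))

    @property
    def mean_r2_floored(self) -> float:
        return float(np.mean(self.fold_r2_floored))


def _fit_family(family: str, X: np.ndarray, y: np.ndarray, params: dict, seed: int):
    if family == "WIENER":
        return _models.fit_wiener(X, y)
    if family == "ENET":
        return _models.fit_elastic_net(X, y, params["alpha"], params["l1_ratio"])
    if family == "MLP":
        return _models.fit_mlp(
            X, y, n_layers=params["n_layers"], units=params["units"],
            activation=params["activation"], learning_rate=params["learning_rate"],
            seed=seed,
        )
    if family == "GBT":
        return _models.fit_gbt(
            X, y, depth=params["depth"], eta=params["eta"], gamma=params["gamma"],
            seed=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def _inner_splits(n: int, family: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous 80/20 train/validation splits inside an outer-train block.

    Three splits with the validation fifth at the start, middle and end; a
    single end split for the MLP (whose inner CV is skipped by design).
    """
    v = max(1, n // 5)
    offsets = [n - v] if family == "MLP" else [0, (n - v) // 2, n - v]
    idx = np.arange(n)
    out = []
    for o in offsets:
        val = idx[o : o + v]
        train = np.concatenate([idx[:o], idx[o + v :]])
        out.append((train, val))
    return out


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "WIENER",
    seed: int = 0,
    n_outer: int = 3,
    bo_rounds: int = 10,
    space: Optional[SpaceSpec] = None,
    channel: Optional[str] = None,
) -> DecodingResult:
    """Outer contiguous k-fold with per-fold Bayesian hyperparameter search.

    ``X`` (rows x features) and ``y`` must already exclude burn-in rows.
    No test-block sample influences any training statistic: hyperparameters
    are chosen on inner splits of the training block only, the winner is
    refit on the training block, and the test block is predicted once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < n_outer * 10:
        raise ValueError(f"only {X.shape[0]} rows for {n_outer} outer folds")
    space = hyperparameter_space(family) if space is None else space
    blocks = np.array_split(np.arange(X.shape[0]), n_outer)
    prediction = np.empty(X.shape[0])
    fold_r2, fold_r2f, fold_params = [], [], []
    for k, test_idx in enumerate(blocks):
        train_idx = np.concatenate([b for j, b in enumerate(blocks) if j != k])
        Xtr, ytr = X[train_idx], y[train_idx]
        model_seed = seed * 1000 + k

        if space:
            splits = _inner_splits(len(train_idx), family)

            def objective(params: dict) -> float:
                scores = []
                for tr, va in splits:
                    m = _fit_family(family, Xtr[tr], ytr[tr], params, model_seed)
                    scores.append(r2_score(ytr[va], m.predict(Xtr[va])))
                return 1.0 - float(np.mean(scores))

            best, _hist = bayes_optimize(space, objective, rounds=bo_rounds, seed=model_seed)
        else:
            best = {}
        final = _fit_family(family, Xtr, ytr, best, model_seed)
        pred = final.predict(X[test_idx])
        prediction[test_idx] = pred
        fold_r2.append(r2_score(y[test_idx], pred))
        fold_r2f.append(r2_score(y[test_idx], pred, floor_at_zero=True))
        fold_params.append(best)
    return DecodingResult(
        family=family, channel=channel,
        fold_r2_raw=fold_r2, fold_r2_floored=fold_r2f, fold_params=fold_params,
        prediction=prediction, seed=seed,
    )


def decode_channel(
    fs: FeatureSeries,
    y10: np.ndarray,
    channel: str,
    family: str = "WIENER",
    n_lags: int = 5,
    seed: int = 0,
    **cv_kwargs,
) -> DecodingResult:
    """Single-channel decoding: lag-concatenate, drop burn-in, run nested CV."""
    from .features import concatenate_lags

    lagged = concatenate_lags(fs, n_lags) if len(fs.lags_ms) == 1 and n_lags > 1 else fs
    keep = ~lagged.burn_in
    X = lagged.channel_matrix(channel)[keep]
    y = np.asarray(y10)[-lagged.n_rows :][keep]
    return nested_cv(X, y, family=family, seed=seed, channel=channel, **cv_kwargs)


def select_best_channel(results: dict[str, DecodingResult]) -> str:
    """Channel with maximal mean test R2; ties go to the earliest channel."""
    if not results:
        raise ValueError("no decoding results to select from")
    best, best_score = None, -np.inf
    for label, res in results.items():
        if res.mean_r2 > best_score:
            best, best_score = label, res.mean_r2
    return best


def combine_channels(fs: FeatureSeries, subset: Sequence[str]) -> np.ndarray:
    """Horizontally concatenate per-channel feature blocks (series channel
    order, then band, then lag) into one design matrix."""
    if not subset:
        raise ValueError("channel subset must be non-empty")
    for label in subset:
        if label not in fs.channel_labels:
            raise KeyError(f"unknown channel {label!r}")
    order = [label for label in fs.channel_labels if label in set(subset)]
    return np.concatenate([fs.channel_matrix(label) for label in order], axis=1)


def spoc_nested_cv(
    rec,
    y_z: np.ndarray,
    family: str = "ENET",
    bands=None,
    epoch_s: float = 1.0,
    seed: int = 0,
    n_outer: int = 3,
    bo_rounds: int = 10,
) -> DecodingResult:
    """Spatial-pattern decoding: SPoC features feeding a regressor.

    The multichannel referenced recording is band-pass filtered per band
    (causal), cut into non-overlapping ``epoch_s`` epochs, and, within each
    outer training fold only, one SPoC filter per band is fit against the
    epoch-mean z-scored force. Log-variance features of the projected signal
    (one per band) then feed the requested regressor family through the same
    Bayesian-optimized inner loop as the channel pipeline. ``y_z`` is the
    z-scored force at the recording rate.
    """
    from scipy import signal as _sig

    from .features import default_bands
    from .io import ECOG, LFP
    from .models import spoc_features, spoc_fit

    bands = list(bands) if bands is not None else default_bands()
    neural = [i for i, c in enumerate(rec.channels) if c.kind in (ECOG, LFP)]
    n_per = int(round(epoch_s * rec.fs))
    E = rec.n_samples // n_per
    y_z = np.asarray(y_z, dtype=float)
    y_epoch = y_z[: E * n_per].reshape(E, n_per).mean(axis=1)

    band_epochs = []
    for band in bands:
        filt = _sig.sosfilt(band.sos(rec.fs), rec.samples[neural], axis=1)
        band_epochs.append(
            filt[:, : E * n_per].reshape(len(neural), E, n_per).transpose(1, 0, 2)
        )

    blocks = np.array_split(np.arange(E), n_outer)
    prediction = np.empty(E)
    fold_r2, fold_r2f, fold_params = [], [], []
    base_family = {"SPOC_ENET": "ENET", "SPOC_GBT": "GBT"}.get(family, family)
    space = hyperparameter_space(base_family)
    for k, test_idx in enumerate(blocks):
        train_idx = np.concatenate([b for j, b in enumerate(blocks) if j != k])
        filters = [spoc_fit(ep[train_idx], y_epoch[train_idx]) for ep in band_epochs]
        feats = np.column_stack(
            [spoc_features(ep, f) for ep, f in zip(band_epochs, filters)]
        )
        Xtr, ytr = feats[train_idx], y_epoch[train_idx]
        model_seed = seed * 1000 + k
        if space:
            splits = _inner_splits(len(train_idx), base_family)

            def objective(params: dict) -> float:
                scores = []
                for tr, va in splits:
                    m = _fit_family(base_family, Xtr[tr], ytr[tr], params, model_seed)
                    scores.append(r2_score(ytr[va], m.predict(Xtr[va])))
                return 1.0 - float(np.mean(scores))

            best, _ = bayes_optimize(space, objective, rounds=bo_rounds, seed=model_seed)
        else:
            best = {}
        final = _fit_family(base_family, Xtr, ytr, best, model_seed)
        pred = final.predict(feats[test_idx])
        prediction[test_idx] = pred
        fold_r2.append(r2_score(y_epoch[test_idx], pred))
        fold_r2f.append(r2_score(y_epoch[test_idx], pred, floor_at_zero=True))
        fold_params.append(best)
    return DecodingResult(
        family=f"SPOC_{base_family}", channel=None,
        fold_r2_raw=fold_r2, fold_r2_floored=fold_r2f, fold_params=fold_params,
        prediction=prediction, seed=seed,
    )


# ---------------------------------------------------------------------------
# coefficient maps and lag sweep


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - x[:, nz].mean(axis=0)) / sd[nz]
    return out


def coefficient_maps(
    band_values: np.ndarray, y: np.ndarray, n_lags: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Interpretability maps for one channel.

    Returns (a) the multivariable linear-model coefficients over all bands at
    lag 0 and (b) the univariate per-(band, lag) coefficient map, normalized
    by its largest absolute entry. ``band_values`` is (time, n_bands) on the
    feature clock; inputs and target are standardized, so univariate
    coefficients are correlations. Constant columns get coefficient 0.
    """
    Xs = _zscore_cols(band_values)
    y = np.asarray(y, dtype=float)
    ys = (y - y.mean()) / y.std()
    multi = _models.fit_wiener(Xs, ys).coef_
    T, B = Xs.shape
    uni = np.zeros((B, n_lags))
    for j in range(n_lags):
        xl = Xs[: T - j]
        yl = ys[j:]
        uni[:, j] = xl.T @ yl / len(yl)
    peak = np.abs(uni).max()
    return multi, uni / peak if peak > 0 else uni


def lag_saturation_sweep(
    band_values: np.ndarray,
    y: np.ndarray,
    max_lags: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Wiener-filter nested-CV mean R2 as a function of lag count 1..max_lags."""
    band_values = np.asarray(band_values, dtype=float)
    y = np.asarray(y, dtype=float)
    T, B = band_values.shape
    curve = np.empty(max_lags)
    for n_lags in range(1, max_lags + 1):
        X = np.empty((T - n_lags + 1, B * n_lags))
        for j in range(n_lags):
            X[:, j::n_lags] = band_values[n_lags - 1 - j : T - j]
        res = nested_cv(X, y[n_lags - 1 :], family="WIENER", seed=seed)
        curve[n_lags - 1] = res.mean_r2
    return curve


# ---------------------------------------------------------------------------
# permutation statistics


def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    scheme: str = "shuffle",
    min_shift_s: float = 10.0,
    rate_hz: float = 10.0,
) -> float:
    """Two-sided Monte-Carlo permutation p-value for statistic_fn(x, y).

    ``scheme="shuffle"`` permutes y (exchangeable pairs);
    ``scheme="circular"`` circularly shifts y by a random offset of at least
    ``min_shift_s`` seconds, preserving autocorrelation — the null for
    time-series decoding. p = (1 + #{|s_perm| >= |s_obs|}) / (1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("permutation test needs n >= 5")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    rng = np.random.default_rng(seed)
    obs = abs(float(statistic_fn(x, y)))
    count = 0
    n = y.size
    if scheme == "circular":
        min_shift = int(round(min_shift_s * rate_hz))
        if 2 * min_shift >= n:
            raise ValueError("series too short for the minimum circular shift")
        for _ in range(n_perm):
            off = int(rng.integers(min_shift, n - min_shift))
            if abs(float(statistic_fn(x, np.roll(y, off)))) >= obs:
                count += 1
    elif scheme == "shuffle":
        for _ in range(n_perm):
            if abs(float(statistic_fn(x, rng.permutation(y)))) >= obs:
                count += 1
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return (1 + count) / (1 + n_perm)


def decoding_permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    n_outer: int = 3,
    min_shift_s: float = 10.0,
    rate_hz: float = 10.0,
) -> tuple[float, float]:
    """Is decoding performance above chance? Monte-Carlo p by label shifting.

    The out-of-fold prediction is a function of the labels (the decoder was
    trained on them), so shared slow confounds survive in it and a surrogate
    that only shifts the final label trace is miscalibrated. The correct
    decoding null re-runs the entire train/test procedure on circularly
    shifted labels (autocorrelation-preserving, minimum offset 10 s) and
    compares mean test R2. One-sided by construction: chance-level decoders
    produce surrogate-like performance, real decoders exceed it.

    Returns (observed mean R2, p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    min_shift = int(round(min_shift_s * rate_hz))
    if 2 * min_shift >= y.size:
        raise ValueError("series too short for the minimum circular shift")

    def mean_cv_r2(labels: np.ndarray) -> float:
        blocks = np.array_split(np.arange(len(labels)), n_outer)
        scores = []
        for k, test_idx in enumerate(blocks):
            train_idx = np.concatenate([b for j, b in enumerate(blocks) if j != k])
            m = _models.fit_wiener(X[train_idx], labels[train_idx])
            scores.append(r2_score(labels[test_idx], m.predict(X[test_idx])))
        return float(np.mean(scores))

    obs = mean_cv_r2(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        off = int(rng.integers(min_shift, y.size - min_shift))
        if mean_cv_r2(np.roll(y, off)) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


def percentage_bend_correlation(x: np.ndarray, y: np.ndarray, beta: float = 0.2) -> float:
    """Wilcox's percentage-bend correlation (bend constant beta=0.2).

    A robust correlation that downweights the most extreme (1 - beta)
    fraction of deviations from a bent M-estimate of location.
    """
    X = np.column_stack((np.asarray(x, float), np.asarray(y, float)))
    n = X.shape[0]
    med = np.median(X, axis=0)
    W = np.sort(np.abs(X - med), axis=0)
    m = int(np.floor((1 - beta) * n + 0.5))
    omega = W[m - 1, :]
    a = np.zeros((2, n))
    for c in (0, 1):
        if omega[c] == 0:
            raise ValueError("percentage-bend correlation undefined for (near-)constant input")
        psi = (X[:, c] - med[c]) / omega[c]
        i1 = int(np.sum(psi < -1))
        i2 = int(np.sum(psi > 1))
        s = X[:, c].copy()
        s[psi < -1] = 0.0
        s[psi > 1] = 0.0
        pbos = (s.sum() + omega[c] * (i2 - i1)) / (n - i1 - i2)
        a[c] = (X[:, c] - pbos) / omega[c]
    a = np.clip(a, -1.0, 1.0)
    u, v = a
    return float((u * v).sum() / np.sqrt((u**2).sum() * (v**2).sum()))


@dataclass
class CorrelationReport:
    method: str
    rho: float
    p: float
    n: int
    n_permutations: int
    seed: int


def correlation(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "spearman",
    seed: int = 0,
    n_perm: int = 5000,
) -> CorrelationReport:
    """Spearman or percentage-bend correlation with a permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("correlation needs equal-length vectors with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        fn = lambda a, b: stats.spearmanr(a, b).statistic
    elif method == "percentage_bend":
        fn = percentage_bend_correlation
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rho = float(fn(x, y))
    p = permutation_pvalue(fn, x, y, n_perm=n_perm, seed=seed, scheme="shuffle")
    return CorrelationReport(method=method, rho=rho, p=p, n=x.size, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# sample-wise cluster-corrected correlation


@dataclass
class ClusterResult:
    r: np.ndarray  # correlation per time sample
    clusters: list[tuple[int, int, float, bool]]  # (start, stop_excl, mass, significant)
    r_threshold: float
    mass_threshold: float

    @property
    def significant(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, _m, sig in self.clusters if sig]


def _cluster_masses(r: np.ndarray, r_crit: float) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs of |r| > r_crit with their |r| mass."""
    out = []
    above = np.abs(r) > r_crit
    sign = np.sign(r)
    i, n = 0, r.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j] and sign[j] == sign[i]:
                j += 1
            out.append((i, j, float(np.abs(r[i:j]).sum())))
            i = j
        else:
            i += 1
    return out


def samplewise_cluster_correlation(
    traces: np.ndarray,
    scores: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected time-resolved correlation of traces with scores.

    Per time sample, the Spearman correlation across subjects between trace
    value and score; clusters of consecutive samples beyond the two-sided
    p < alpha threshold are scored by their |r| mass and compared with the
    null distribution of maximum cluster mass under score permutations.
    """
    traces = np.asarray(traces, dtype=float)
    scores = np.asarray(scores, dtype=float)
    S, T = traces.shape
    if S < 6:
        raise ValueError("need at least 6 subjects")
    if n_perm < 1000:
        warnings.warn(f"n_perm={n_perm} < 1000; cluster threshold will be coarse")
    rng = np.random.default_rng(seed)
    # rank-transform -> Pearson on ranks = Spearman
    rt = stats.rankdata(traces, axis=0)
    rt = (rt - rt.mean(axis=0)) / np.where(rt.std(axis=0) == 0, 1.0, rt.std(axis=0))
    rs = stats.rankdata(scores)
    rs = (rs - rs.mean()) / rs.std()
    r_obs = rs @ rt / S
    t_crit = stats.t.ppf(1 - alpha / 2, df=S - 2)
    r_crit = t_crit / np.sqrt(S - 2 + t_crit**2)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        r_b = rng.permutation(rs) @ rt / S
        masses = _cluster_masses(r_b, r_crit)
        null_max[b] = max((m for *_ij, m in masses), default=0.0)
    mass_thr = float(np.quantile(null_max, 0.95))
    clusters = [
        (a, b, m, m > mass_thr) for a, b, m in _cluster_masses(r_obs, r_crit)
    ]
    return ClusterResult(r=r_obs, clusters=clusters, r_threshold=float(r_crit), mass_threshold=mass_thr)


def fdr_adjust(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject
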