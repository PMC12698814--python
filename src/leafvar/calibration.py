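"""Spectra-to-trait calibration, prediction filtering and imputation.

A calibration set of leaves with both spectra and laboratory trait values is
split 75/25 into train and test sets (stratified by species).  A regression
model maps augmented spectral features to each trait; two families are
provided with the same estimator interface:

* :class:`ConvNetTraitCalibrator` -- a compact 1-D convolutional network
  (one convolutional layer, batch normalization, mean pooling, three dense
  layers) trained with Adam on a mean-squared-error loss, implemented in
  numpy.
* :class:`PLSTraitCalibrator` -- partial-least-squares regression, the fast
  latent-variable family used throughout the test suite.

Predicted trait values are screened per species and trait against a
median +/- k*MAD interval, and the resulting missing cells are imputed per
species by iterative low-rank (PCA) reconstruction.
"""

from __future__ import annotations

import pickle
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .synthetic import TRAITS


# ---------------------------------------------------------------------------
# Train/test split and evaluation
# ---------------------------------------------------------------------------


def split_calibration(
    samples: pd.DataFrame,
    train_frac: float = 0.75,
    seed: int = 0,
    stratify_col: str = "species_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, species-stratified train/test split."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if len(samples) < 8:
        raise ValueError("need at least 8 calibration samples")
    strat = samples[stratify_col] if stratify_col in samples else None
    train, test = train_test_split(
        samples, train_size=train_frac, random_state=seed, stratify=strat
    )
    return train, test


def evaluate_model(model, X_test: np.ndarray, Y_test: np.ndarray, traits=TRAITS) -> pd.DataFrame:
    """Held-out R^2 (= 1 - SSE/SST) and RMSE per trait, in trait units."""
    Y_test = np.asarray(Y_test, float)
    if Y_test.size == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(X_test), float).reshape(Y_test.shape)
    rows = []
    for j, t in enumerate(traits):
        err = pred[:, j] - Y_test[:, j]
        rows.append(
            {
                "trait": t,
                "r2": r2_score(Y_test[:, j], pred[:, j]),
                "rmse": float(np.sqrt(np.mean(err**2))),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# PLS family
# ---------------------------------------------------------------------------


class PLSTraitCalibrator(RegressorMixin, BaseEstimator):
    """Partial-least-squares calibration of traits on spectral features.

    Targets are standardized per trait before fitting and back-transformed
    on prediction, so component selection is not dominated by trait units.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, float)
        Y = np.asarray(y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if not np.isfinite(X).all() or not np.isfinite(Y).all():
            raise ValueError("non-finite values in calibration data")
        self.y_mean_ = Y.mean(axis=0)
        sd = Y.std(axis=0)
        self.y_sd_ = np.where(sd > 0, sd, 1.0)
        self.degenerate_targets_ = sd == 0
        n_comp = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self.pls_ = PLSRegression(n_components=n_comp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pls_.fit(X, (Y - self.y_mean_) / self.y_sd_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        z = self.pls_.predict(np.asarray(X, float))
        out = z * self.y_sd_ + self.y_mean_
        out[:, self.degenerate_targets_] = self.y_mean_[self.degenerate_targets_]
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "PLSTraitCalibrator":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# ---------------------------------------------------------------------------
# Conv-net family (numpy)
# ---------------------------------------------------------------------------


def _adam_update(state, key, grad, lr, t, b1=0.9, b2=0.999, eps=1e-8):
    m, v = state.setdefault(key, (np.zeros_like(grad), np.zeros_like(grad)))
    m = b1 * m + (1 - b1) * grad
    v = b2 * v + (1 - b2) * grad**2
    state[key] = (m, v)
    mhat = m / (1 - b1**t)
    vhat = v / (1 - b2**t)
    return lr * mhat / (np.sqrt(vhat) + eps)


class ConvNetTraitCalibrator(RegressorMixin, BaseEstimator):
    """Small 1-D convolutional network for trait calibration, in numpy.

    Architecture: valid 1-D convolution (``n_filters`` filters of width
    ``kernel_size``) -> batch normalization -> ReLU -> non-overlapping mean
    pooling (``pool_size``) -> dense ``hidden`` stack with ReLU -> linear
    output, one unit per trait.  Trained with Adam on the MSE of
    standardized targets; inputs are standardized per feature.  Deterministic
    given ``seed``.
    """

    def __init__(
        self,
        n_filters: int = 16,
        kernel_size: int = 25,
        pool_size: int = 8,
        hidden: tuple[int, ...] = (256, 64),
        lr: float = 1e-3,
        epochs: int = 60,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- forward pieces -----------------------------------------------------

    def _conv(self, X):
        # X: (n, p) -> (n, f, p - k + 1) via strided windows
        k = self.kernel_size
        win = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (n, p-k+1, k)
        return np.einsum("npk,fk->nfp", win, self.W_conv_) + self.b_conv_[None, :, None]

    def _forward(self, X, train: bool = False):
        cache = {}
        c = self._conv(X)  # (n, f, L)
        if train:
            mu = c.mean(axis=(0, 2))
            var = c.var(axis=(0, 2))
            self.bn_mean_ = 0.9 * self.bn_mean_ + 0.1 * mu
            self.bn_var_ = 0.9 * self.bn_var_ + 0.1 * var
        else:
            mu, var = self.bn_mean_, self.bn_var_
        std = np.sqrt(var + 1e-5)
        chat = (c - mu[None, :, None]) / std[None, :, None]
        a = self.bn_gamma_[None, :, None] * chat + self.bn_beta_[None, :, None]
        relu1 = np.maximum(a, 0.0)
        n, f, L = relu1.shape
        Lp = L // self.pool_size
        pooled = relu1[:, :, : Lp * self.pool_size].reshape(n, f, Lp, self.pool_size).mean(axis=3)
        h = pooled.reshape(n, -1)
        cache.update(c=c, chat=chat, mu=mu, std=std, relu_mask=a > 0, pooled_shape=(n, f, Lp), h0=h)
        acts = [h]
        for i, (W, b) in enumerate(zip(self.W_dense_, self.b_dense_)):
            h = h @ W + b
            if i < len(self.W_dense_) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        cache["acts"] = acts
        return h, cache

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, float)
        Y = np.asarray(y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if not np.isfinite(X).all() or not np.isfinite(Y).all():
            raise ValueError("non-finite values in calibration data")
        rng = np.random.default_rng(self.seed)
        n, p = X.shape
        if p < self.kernel_size:
            raise ValueError("fewer features than convolution kernel width")

        self.x_mean_ = X.mean(axis=0)
        xsd = X.std(axis=0)
        self.x_sd_ = np.where(xsd > 0, xsd, 1.0)
        self.y_mean_ = Y.mean(axis=0)
        ysd = Y.std(axis=0)
        self.y_sd_ = np.where(ysd > 0, ysd, 1.0)
        Xs = (X - self.x_mean_) / self.x_sd_
        Ys = (Y - self.y_mean_) / self.y_sd_
        n_out = Ys.shape[1]

        f, k = self.n_filters, self.kernel_size
        L = p - k + 1
        Lp = L // self.pool_size
        if Lp < 1:
            raise ValueError("pool_size too large for input length")
        self.W_conv_ = rng.normal(0, np.sqrt(2.0 / k), (f, k))
        self.b_conv_ = np.zeros(f)
        self.bn_gamma_ = np.ones(f)
        self.bn_beta_ = np.zeros(f)
        self.bn_mean_ = np.zeros(f)
        self.bn_var_ = np.ones(f)
        dims = [f * Lp, *self.hidden, n_out]
        self.W_dense_ = [
            rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b_dense_ = [np.zeros(d) for d in dims[1:]]

        state: dict = {}
        t = 0
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], Ys[idx]
                pred, cache = self._forward(xb, train=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                epoch_loss += loss * len(idx)
                t += 1
                self._backward(xb, err, cache, state, t)
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = p
        return self

    def _backward(self, xb, err, cache, state, t):
        acts = cache["acts"]
        grad = 2.0 * err / err.size
        gW, gb = [], []
        for i in range(len(self.W_dense_) - 1, -1, -1):
            a_in = acts[i]
            gW.append(a_in.T @ grad)
            gb.append(grad.sum(axis=0))
            grad = grad @ self.W_dense_[i].T
            if i > 0:
                grad = grad * (acts[i] > 0)  # ReLU mask of the layer input
        gW.reverse()
        gb.reverse()

        # through pooling and batchnorm back to conv weights
        n, f, Lp = cache["pooled_shape"]
        gh = grad  # (n, f*Lp) gradient at flattened pooled activations
        gpool = gh.reshape(n, f, Lp)
        L = cache["c"].shape[2]
        grelu = np.zeros((n, f, L))
        used = Lp * self.pool_size
        grelu[:, :, :used] = np.repeat(gpool / self.pool_size, self.pool_size, axis=2)
        ga = grelu * cache["relu_mask"]
        chat = cache["chat"]
        g_gamma = (ga * chat).sum(axis=(0, 2))
        g_beta = ga.sum(axis=(0, 2))
        # batchnorm backward (per filter over batch x positions)
        gchat = ga * self.bn_gamma_[None, :, None]
        gc = (
            gchat
            - gchat.mean(axis=(0, 2), keepdims=True)
            - chat * (gchat * chat).mean(axis=(0, 2), keepdims=True)
        ) / cache["std"][None, :, None]
        win = np.lib.stride_tricks.sliding_window_view(xb, self.kernel_size, axis=1)
        gWc = np.einsum("nfp,npk->fk", gc, win)
        gbc = gc.sum(axis=(0, 2))

        self.W_conv_ -= _adam_update(state, "Wc", gWc, self.lr, t)
        self.b_conv_ -= _adam_update(state, "bc", gbc, self.lr, t)
        self.bn_gamma_ -= _adam_update(state, "g", g_gamma, self.lr, t)
        self.bn_beta_ -= _adam_update(state, "b", g_beta, self.lr, t)
        for i, (gw, gbi) in enumerate(zip(gW, gb)):
            self.W_dense_[i] -= _adam_update(state, f"W{i}", gw, self.lr, t)
            self.b_dense_[i] -= _adam_update(state, f"b{i}", gbi, self.lr, t)

    def predict(self, X):
        Xs = (np.asarray(X, float) - self.x_mean_) / self.x_sd_
        out, _ = self._forward(Xs, train=False)
        return out * self.y_sd_ + self.y_mean_

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ConvNetTraitCalibrator":
        with open(path, "rb") as fh:
            return pickle.load(fh)


MODEL_FAMILIES = {"convnet": ConvNetTraitCalibrator, "pls": PLSTraitCalibrator}


def fit_calibration(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    family: str = "convnet",
    seed: int = 0,
    **params,
):
    """Fit a calibration model of the requested family on augmented features."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    cls = MODEL_FAMILIES[family]
    if family == "convnet":
        params.setdefault("seed", seed)
    model = cls(**params)
    return model.fit(X_train, Y_train)


def learning_curve(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    fractions=(0.25, 0.5, 0.75, 1.0),
    seeds=(0,),
    family: str = "pls",
    traits=TRAITS,
    **params,
) -> pd.DataFrame:
    """Held-out R^2 as a function of training-set completeness.

    For each fraction and seed a random subset of the training set is used
    to refit the model; fraction 1.0 reproduces the full fit.
    """
    X_train = np.asarray(X_train, float)
    Y_train = np.asarray(Y_train, float)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        n_sub = int(round(frac * len(X_train)))
        if n_sub < 2:
            raise ValueError(f"fraction {frac} yields fewer than 2 samples")
        for seed in seeds:
            rng = np.random.default_rng(seed)
            idx = (
                np.arange(len(X_train))
                if frac == 1.0
                else rng.choice(len(X_train), n_sub, replace=False)
            )
            model = fit_calibration(
                X_train[idx], Y_train[idx], family=family, seed=seed, **params
            )
            ev = evaluate_model(model, X_test, Y_test, traits=traits)
            for t in traits:
                rows.append(
                    {
                        "fraction": frac,
                        "seed": seed,
                        "trait": t,
                        "r2": ev.loc[t, "r2"],
                        "rmse": ev.loc[t, "rmse"],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction screening and imputation
# ---------------------------------------------------------------------------


def mad_filter(
    table: pd.DataFrame,
    trait_cols=TRAITS,
    group_col: str = "species_id",
    k: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set implausible predictions to missing per group and trait.

    A cell is excluded iff |x - median| > k * MAD, where the median and the
    (unscaled) median absolute deviation are computed over the cell's group
    for that trait.  Returns (filtered table, boolean exclusion mask).
    """
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=list(trait_cols))
    for g, sub in table.groupby(group_col):
        for t in trait_cols:
            x = sub[t]
            obs = x.dropna()
            if len(obs) < 3:
                raise ValueError(f"group {g!r} has < 3 values for {t}")
            med = obs.median()
            mad = (obs - med).abs().median()
            bad = (x - med).abs() > k * mad
            bad = bad.fillna(False)
            mask.loc[bad[bad].index, t] = True
    for t in trait_cols:
        out.loc[mask[t], t] = np.nan
    return out, mask


def _iterative_pca_impute(X: np.ndarray, ncp: int, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Iterative rank-``ncp`` SVD reconstruction of standardized data."""
    X = np.asarray(X, float)
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing; cannot impute")
    col_mean = np.nanmean(X, axis=0)
    filled = np.where(miss, col_mean, X)
    converged = False
    for _ in range(max_iter):
        mean = filled.mean(axis=0)
        sd = filled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (filled - mean) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        recon = (u[:, :ncp] * s[:ncp]) @ vt[:ncp]
        new_vals = recon * sd + mean
        delta = np.max(np.abs(new_vals[miss] - filled[miss])) if miss.any() else 0.0
        filled[miss] = new_vals[miss]
        if delta < tol:
            converged = True
            break
    return filled, converged


def impute_pca(
    table: pd.DataFrame,
    trait_cols=TRAITS,
    group_col: str = "species_id",
    ncp: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Impute missing trait cells per group by iterative PCA reconstruction.

    Missing cells are initialized at the group column means and refined by
    alternating rank-``ncp`` SVD reconstruction of the (re)standardized data
    until the largest change falls below ``tol``.  Observed cells are never
    modified.  Non-convergence raises a warning, not an error.
    """
    if ncp >= len(trait_cols):
        raise ValueError("ncp must be smaller than the number of traits")
    out = table.copy()
    if not out[list(trait_cols)].isna().any().any():
        return out
    for g, sub in table.groupby(group_col):
        X = sub[list(trait_cols)].to_numpy(float)
        if not np.isnan(X).any():
            continue
        filled, converged = _iterative_pca_impute(X, ncp, tol, max_iter)
        if not converged:
            warnings.warn(
                f"PCA imputation did not converge for group {g!r} "
                f"within {max_iter} iterations"
            )
        out.loc[sub.index, list(trait_cols)] = filled
    return out
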