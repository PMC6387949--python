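"""Vector autoregressive (VAR) models: representation, simulation, ridge fitting.

A VAR(p) model expresses each channel at time t as a linear combination of
the p previous samples of every channel plus Gaussian innovation noise:

    x(t) = A_1 x(t-1) + ... + A_p x(t-p) + e(t),   e(t) ~ N(0, Sigma)

Stability is assessed through the spectral radius of the companion matrix;
a model is stationary iff that radius is strictly below one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VarModel",
    "companion_matrix",
    "spectral_radius",
    "simulate_var",
    "fit_var_ridge",
]


@dataclass
class VarModel:
    """Fitted or constructed VAR(p) model.

    Attributes
    ----------
    coeffs : ndarray, shape (p, n_channels, n_channels)
        Lag coefficient matrices A_1 ... A_p.
    sigma : ndarray, shape (n_channels, n_channels)
        Innovation covariance (symmetric PSD).
    fs : float
        Sampling rate in Hz.
    ridge : float
        Relative ridge penalty used during fitting (0 for constructed models).
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    fs: float
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, n_channels, n_channels)")
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != self.coeffs.shape[1:]:
            raise ValueError("sigma shape does not match channel count")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if self.order < 1:
            raise ValueError("model order must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)

    def is_stable(self, tol: float = 0.0) -> bool:
        return self.spectral_radius < 1.0 - tol


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Stack lag matrices into the (p*n) x (p*n) companion form."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((p * n, p * n))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    """Largest eigenvalue magnitude of the companion matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


def simulate_var(
    model: VarModel,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    n_trials: int = 1,
    burn_in: int | None = None,
) -> np.ndarray:
    """Simulate realizations of a stable VAR model.

    Innovations are drawn from N(0, Sigma); a burn-in of ``10 * order``
    samples (by default) is discarded so the output is approximately
    stationary from its first sample.

    Returns
    -------
    ndarray
        Shape (n_channels, n_samples) if ``n_trials == 1``, else
        (n_channels, n_samples, n_trials). Independent innovation streams
        per trial.
    """
    if not model.is_stable():
        raise ValueError(
            f"VAR model is unstable (spectral radius {model.spectral_radius:.4f} >= 1)"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    p, n = model.order, model.n_channels
    if burn_in is None:
        burn_in = 10 * p
    total = n_samples + burn_in
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.sigma + 1e-15 * np.eye(n))
    e = rng.standard_normal(size=(total, n, n_trials))
    e = np.einsum("ij,tjk->tik", chol, e)
    x = np.zeros((total, n, n_trials))
    # Stack coefficients as (n, n*p) for one matmul per time step.
    a_stack = np.concatenate(list(model.coeffs), axis=1)
    for t in range(total):
        if t == 0:
            x[t] = e[t]
            continue
        k = min(p, t)
        # lag block: (n*k, n_trials), most recent lag first
        lags = x[t - k : t][::-1].reshape(k * n, n_trials)
        x[t] = a_stack[:, : k * n] @ lags + e[t]
    out = np.moveaxis(x[burn_in:], 0, 1)  # (n, n_samples, n_trials)
    if n_trials == 1:
        return out[:, :, 0]
    return out


def fit_var_ridge(
    data: np.ndarray,
    order: int,
    ridge: float = 1e-3,
    fs: float = 1.0,
) -> VarModel:
    """Fit a VAR(p) model by ridge-penalized least squares.

    Parameters
    ----------
    data : ndarray
        Either (n_channels, n_samples) for a single segment or
        (n_channels, n_samples, n_trials); trials are pooled by stacking
        their lagged regression rows (no regression across trial
        boundaries). Each channel is demeaned per trial before fitting.
    order : int
        Model order p.
    ridge : float
        Relative L2 penalty: the absolute penalty is
        ``ridge * trace(Z'Z) / n_cols`` applied to every coefficient.
        With ``ridge == 0`` a rank-deficient design raises an error
        advising a positive penalty.
    fs : float
        Sampling rate recorded on the returned model.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("data must be 2-D or 3-D (channels x samples [x trials])")
    n_ch, n_samp, n_trials = data.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if n_samp <= order:
        raise ValueError(
            f"need more than order={order} samples per trial (got {n_samp})"
        )
    data = data - data.mean(axis=1, keepdims=True)
    if np.allclose(data, 0.0):
        raise ValueError("constant input: zero-variance design cannot be fit")

    rows_per_trial = n_samp - order
    n_rows = rows_per_trial * n_trials
    n_cols = n_ch * order
    if n_rows <= n_cols and ridge == 0.0:
        raise ValueError(
            f"underdetermined design ({n_rows} rows, {n_cols} columns) with "
            "ridge=0; supply a positive ridge penalty"
        )
    # Build pooled design: rows are time points t = order..n_samp-1 of each
    # trial; predictor blocks ordered lag-1 first.
    Z = np.empty((n_rows, n_cols))
    Y = np.empty((n_rows, n_ch))
    for tr in range(n_trials):
        sl = slice(tr * rows_per_trial, (tr + 1) * rows_per_trial)
        Y[sl] = data[:, order:, tr].T
        for k in range(1, order + 1):
            Z[sl, (k - 1) * n_ch : k * n_ch] = data[:, order - k : n_samp - k, tr].T

    gram = Z.T @ Z
    scale = np.trace(gram) / n_cols
    if scale == 0.0:
        raise ValueError("constant input: zero-variance design cannot be fit")
    lam = ridge * scale
    if lam > 0:
        coef = np.linalg.solve(gram + lam * np.eye(n_cols), Z.T @ Y)
    else:
        rank = np.linalg.matrix_rank(gram)
        if rank < n_cols:
            raise ValueError(
                "rank-deficient design with ridge=0; supply a positive ridge penalty"
            )
        coef = np.linalg.solve(gram, Z.T @ Y)
    resid = Y - Z @ coef
    dof = max(n_rows - n_cols, 1)
    sigma = resid.T @ resid / dof
    sigma = 0.5 * (sigma + sigma.T)
    coeffs = np.stack(
        [coef[(k - 1) * n_ch : k * n_ch].T for k in range(1, order + 1)]
    )
    return VarModel(coeffs=coeffs, sigma=sigma, fs=fs, ridge=ridge)
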