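"""Brain -> HRV predictive modeling: Monte-Carlo cross-validated LASSO
with robustness counting.

For each crossing of laboratory condition (attend, reinterpret), EEG band
(delta, theta, alpha, beta), simulation condition (low, high stress) and
HRV band (LF, HF) — 32 models in all — the 132 directed connectivity
features predict the participant-level HRV band power. Robustness is
assessed with Monte-Carlo cross-validation: repeated random 20/5
train/test splits, a 25-point geometric lambda grid from 0.032 to 1, and
the out-of-sample R^2 per split and lambda. A model is flagged when the
fraction of splits with positive R^2 at its best lambda reaches 0.95.
Robust connections are those selected (nonzero coefficient) in at least a
threshold fraction of the positive-R^2 splits, each carrying the sign of
the majority of its coefficients.

Coefficients live on the standardized-feature scale; standardization
parameters are always computed on the training split only.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, lasso_path
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "LassoModelSpec",
    "McCvResult",
    "lambda_grid",
    "fit_lasso",
    "mc_cross_validate",
    "run_model_grid",
    "robust_connections",
    "correlate_edges_with_behavior",
]

LAB_CONDITIONS = ("attend", "reinterpret")
EEG_BANDS = ("delta", "theta", "alpha", "beta")
SIM_CONDITIONS = ("low", "high")
HRV_BANDS = ("LF", "HF")


@dataclass(frozen=True)
class LassoModelSpec:
    """One cell of the 2 x 4 x 2 x 2 model crossing."""

    lab_condition: str
    eeg_band: str
    sim_condition: str
    hrv_band: str

    def __post_init__(self) -> None:
        if self.lab_condition not in LAB_CONDITIONS:
            raise ValueError(f"unknown lab condition {self.lab_condition!r}")
        if self.eeg_band not in EEG_BANDS:
            raise ValueError(f"unknown EEG band {self.eeg_band!r}")
        if self.sim_condition not in SIM_CONDITIONS:
            raise ValueError(f"unknown simulation condition {self.sim_condition!r}")
        if self.hrv_band not in HRV_BANDS:
            raise ValueError(f"unknown HRV band {self.hrv_band!r}")

    @classmethod
    def all_specs(cls) -> list["LassoModelSpec"]:
        return [
            cls(lc, eb, sc, hb)
            for lc, eb, sc, hb in itertools.product(
                LAB_CONDITIONS, EEG_BANDS, SIM_CONDITIONS, HRV_BANDS
            )
        ]

    def __str__(self) -> str:
        return f"{self.lab_condition}/{self.eeg_band}->{self.sim_condition}/{self.hrv_band}"


@dataclass
class McCvResult:
    """Aggregated Monte-Carlo cross-validation output for one model.

    ``r2`` holds the raw out-of-sample R^2 per (split, lambda);
    ``sel_count`` / ``pos_sign`` / ``neg_sign`` are per-(lambda, feature)
    tallies accumulated over the splits with positive R^2 at that lambda.
    Split membership is stored so any robust-edge list is exactly
    reproducible from the seed.
    """

    lambdas: np.ndarray                # (n_lambda,), ascending
    r2: np.ndarray                     # (n_iter, n_lambda)
    sel_count: np.ndarray              # (n_lambda, n_features)
    pos_sign: np.ndarray               # (n_lambda, n_features)
    neg_sign: np.ndarray               # (n_lambda, n_features)
    seed: int | None
    test_indices: np.ndarray           # (n_iter, n_test)
    feature_names: list[str] | None = None

    @property
    def mean_r2(self) -> np.ndarray:
        return self.r2.mean(axis=0)

    @property
    def frac_positive(self) -> np.ndarray:
        return (self.r2 > 0).mean(axis=0)

    @property
    def n_positive(self) -> np.ndarray:
        return (self.r2 > 0).sum(axis=0)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.mean_r2))

    @property
    def best_lambda(self) -> float:
        return float(self.lambdas[self.best_index])

    def is_significant(self, threshold: float = 0.95) -> bool:
        return bool(self.frac_positive[self.best_index] >= threshold)


def lambda_grid(n: int = 25, lo: float = 0.032, hi: float = 1.0) -> np.ndarray:
    """Geometric grid with inclusive endpoints, ascending."""
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    return np.geomspace(lo, hi, n)


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning("dropping %d zero-variance feature(s)", int(dead.sum()))
    sd_safe = np.where(dead, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, dead] = 0.0
    return Xs, mean, np.where(dead, np.nan, sd)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """L1-penalized least squares: (1/2n)||y - Xb||^2 + lam ||b||_1.

    X is column-standardized internally and y centered; returned
    coefficients are on the standardized scale and the intercept is the
    mean of y. ``lam = 0`` falls back to ordinary least squares.
    Zero-variance columns are dropped (coefficient 0) with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _, sd = _standardize_train(X)
    inter = float(y.mean())
    yc = y - inter
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=500_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yc)
        beta = model.coef_.copy()
    beta[np.isnan(sd)] = 0.0
    return beta, inter


def _oos_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Out-of-sample R^2 with the test-split mean in the denominator."""
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mc_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 500,
    n_train: int = 20,
    n_test: int = 5,
    grid: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    feature_names: list[str] | None = None,
) -> McCvResult:
    """Monte-Carlo cross-validation of the LASSO over a lambda grid.

    Per split: random disjoint train/test partition, train-only
    standardization, LASSO path over the grid, out-of-sample R^2 per
    lambda (SS_tot about the test mean). Selection and sign tallies are
    accumulated over splits with positive R^2 at each lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_train + n_test != n:
        raise ValueError(
            f"n_train + n_test must equal the number of participants ({n})"
        )
    if grid is None:
        grid = lambda_grid()
    grid = np.asarray(grid, dtype=float)
    desc = grid[::-1]  # coordinate-descent path wants decreasing penalties
    rng = np.random.default_rng(seed)
    n_lam = len(grid)
    r2 = np.full((n_iter, n_lam), np.nan)
    sel = np.zeros((n_lam, p), dtype=int)
    pos = np.zeros((n_lam, p), dtype=int)
    neg = np.zeros((n_lam, p), dtype=int)
    test_idx_all = np.empty((n_iter, n_test), dtype=int)
    for it in range(n_iter):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        test_idx_all[it] = np.sort(te)
        Xtr, mean, sd = _standardize_train(X[tr])
        sd_safe = np.where(np.isnan(sd), 1.0, sd)
        Xte = (X[te] - mean) / sd_safe
        Xte[:, np.isnan(sd)] = 0.0
        ytr_mean = y[tr].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Xtr, y[tr] - ytr_mean, alphas=desc)
        coefs = coefs[:, ::-1]                       # (p, n_lam) ascending grid
        preds = Xte @ coefs + ytr_mean               # (n_test, n_lam)
        for k in range(n_lam):
            r2[it, k] = _oos_r2(y[te], preds[:, k])
        good = r2[it] > 0
        nz = coefs.T != 0                            # (n_lam, p)
        sel[good] += nz[good]
        pos[good] += (coefs.T > 0)[good]
        neg[good] += (coefs.T < 0)[good]
    return McCvResult(
        lambdas=grid,
        r2=r2,
        sel_count=sel,
        pos_sign=pos,
        neg_sign=neg,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        test_indices=test_idx_all,
        feature_names=feature_names,
    )


def run_model_grid(
    features: dict[tuple[str, str], np.ndarray],
    hrv: dict[tuple[str, str], np.ndarray],
    n_iter: int = 500,
    n_train: int = 20,
    n_test: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    significance: float = 0.95,
    feature_names: list[str] | None = None,
) -> dict[LassoModelSpec, McCvResult]:
    """Evaluate all 32 lab x band x sim x HRV models.

    ``features`` maps (lab_condition, eeg_band) to a participants x 132
    matrix; ``hrv`` maps (sim_condition, hrv_band) to a participants
    vector. Each model gets its own child seed derived from ``seed``.
    """
    specs = LassoModelSpec.all_specs()
    children = np.random.SeedSequence(seed).spawn(len(specs))
    results: dict[LassoModelSpec, McCvResult] = {}
    for spec, child in zip(specs, children):
        X = features[(spec.lab_condition, spec.eeg_band)]
        y = hrv[(spec.sim_condition, spec.hrv_band)]
        res = mc_cross_validate(
            X, y, n_iter=n_iter, n_train=n_train, n_test=n_test,
            grid=grid, seed=child, feature_names=feature_names,
        )
        results[spec] = res
        if res.is_significant(significance):
            logger.info(
                "model %s flagged (frac positive R2 = %.3f at lambda %.4f)",
                spec, res.frac_positive[res.best_index], res.best_lambda,
            )
    return results


def robust_connections(
    result: McCvResult,
    min_count_fraction: float = 0.5,
    lam_index: int | None = None,
) -> pd.DataFrame:
    """Connections selected in >= ``min_count_fraction`` of the
    positive-R^2 splits at the chosen lambda (default: best mean R^2).

    Returns a table with feature index/name, count fraction, and majority
    coefficient sign (+1 / -1; exact ties give 0 with a logged warning).
    """
    k = result.best_index if lam_index is None else lam_index
    n_pos = int(result.n_positive[k])
    if n_pos == 0:
        logger.warning("robust_connections: no positive-R2 splits at this lambda")
        return pd.DataFrame(columns=["feature", "name", "count_fraction", "sign"])
    frac = result.sel_count[k] / n_pos
    keep = np.flatnonzero(frac >= min_count_fraction)
    rows = []
    for j in keep:
        diff = result.pos_sign[k, j] - result.neg_sign[k, j]
        sign = int(np.sign(diff))
        if sign == 0:
            logger.warning("robust_connections: sign tie on feature %d", j)
        rows.append({
            "feature": int(j),
            "name": result.feature_names[j] if result.feature_names else str(j),
            "count_fraction": float(frac[j]),
            "sign": sign,
        })
    df = pd.DataFrame(rows, columns=["feature", "name", "count_fraction", "sign"])
    return df.sort_values("count_fraction", ascending=False).reset_index(drop=True)


def correlate_edges_with_behavior(
    edge_features: pd.DataFrame,
    behavior: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and two-sided p per (edge, behavioral measure) pair.

    Rows are participants in both tables; pairwise-complete observations
    are used and the n per cell is reported. Constant columns yield
    missing r with a warning. BH-FDR adjusted p-values across the whole
    table are reported alongside the raw ones.
    """
    rows = []
    for edge in edge_features.columns:
        for measure in behavior.columns:
            sub = pd.concat(
                [edge_features[edge], behavior[measure]], axis=1
            ).dropna()
            n = len(sub)
            x = sub.iloc[:, 0].to_numpy(dtype=float)
            yv = sub.iloc[:, 1].to_numpy(dtype=float)
            if n < 3 or np.std(x) == 0 or np.std(yv) == 0:
                logger.warning(
                    "correlation undefined for (%s, %s): constant or too few values",
                    edge, measure,
                )
                rows.append({"edge": edge, "measure": measure,
                             "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = sps.pearsonr(x, yv)
            rows.append({"edge": edge, "measure": measure,
                         "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = multipletests(
            out.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out
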