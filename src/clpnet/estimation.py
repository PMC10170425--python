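"""Cross-lagged panel network estimation via node-wise LASSO regressions.

For one wave pair (t, t+1) the network is assembled from 13 separate
penalized regressions: each wave-(t+1) item is regressed on all 13
wave-t items, so every cross-lagged path is adjusted for the outcome's
autoregressive effect and all other symptoms. The penalty for each node
is chosen by k-fold cross-validation over a descending log-spaced grid;
predictors and outcomes are z-standardized on the estimation sample so
edge weights are comparable across items with different Likert ranges.
The 0.05 threshold sometimes applied to such networks is strictly a
display rule: centrality and bootstrap computations always use the
unthresholded weights.

All cross-validation work runs through a single Gram-matrix kernel
(:mod:`clpnet._solver`), which keeps a full network fit cheap enough for
the bootstrap to repeat it thousands of times.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._solver import cd_path, cv_fold_mse
from .panel import PanelDataset

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for the node-wise LASSO estimator.

    ``n_alphas`` log-spaced penalties descend from each node's lambda_max
    to ``alpha_min_ratio * lambda_max``. ``lambda_rule`` is ``"min"``
    (CV-MSE minimizer, default) or ``"1se"`` (sparsest model within one
    standard error of the minimum). Fold assignment hashes the subject id
    together with ``cv_seed`` so it is invariant to row order.
    """

    n_alphas: int = 100
    alpha_min_ratio: float = 0.001
    cv_folds: int = 10
    cv_seed: int = 0
    lambda_rule: str = "min"
    standardize: bool = True
    display_threshold: float = 0.05
    tol: float = 1e-7
    max_sweeps: int = 100_000

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_alphas < 1 or not (0 < self.alpha_min_ratio < 1):
            raise ValueError("invalid penalty grid settings")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class CLPNetwork:
    """A directed, signed cross-lagged network for one wave pair.

    ``W[j, i]`` is the standardized coefficient of predictor i (wave t)
    for outcome j (wave t+1); the diagonal holds autoregressive paths.
    """

    nodes: list[str]
    W: np.ndarray
    lambdas: np.ndarray
    wave_pair: tuple[str, str]
    n_used: int
    cv_seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")
        if self.W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("W must be square over the node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_frame(self) -> pd.DataFrame:
        """Edge list with one row per (from, to) ordered pair."""
        p = self.n_nodes
        jj, ii = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
        return pd.DataFrame(
            {
                "from": np.asarray(self.nodes, dtype=object)[ii.ravel()],
                "to": np.asarray(self.nodes, dtype=object)[jj.ravel()],
                "weight": self.W.ravel(),
                "wave_pair": f"{self.wave_pair[0]}->{self.wave_pair[1]}",
                "autoregressive": (ii == jj).ravel(),
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": self.nodes,
            "W": self.W.tolist(),
            "lambdas": np.asarray(self.lambdas).tolist(),
            "wave_pair": list(self.wave_pair),
            "n_used": self.n_used,
            "cv_seed": self.cv_seed,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CLPNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            nodes=d["nodes"],
            W=np.asarray(d["W"]),
            lambdas=np.asarray(d["lambdas"]),
            wave_pair=tuple(d["wave_pair"]),
            n_used=d["n_used"],
            cv_seed=d.get("cv_seed", 0),
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Solver surface


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is identically zero.

    Assumes centered (and, if configured, scaled) inputs; equals
    ``max_i |<x_i, y>| / n``. A zero-variance outcome yields 0 with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        warnings.warn("outcome has zero variance; lambda_max = 0", stacklevel=2)
        return 0.0
    # center and divide in exactly the order the solver uses for its
    # cross-moment vector, so a fit at exactly this penalty is identically zero
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc / len(y))))


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Coefficients at a single fixed penalty (inputs used as given).

    Centers X and y internally (unpenalized intercept); no scaling. The
    returned coefficients apply to the original columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc / n
    c = Xc.T @ yc / n
    B, converged = cd_path(G, c, np.array([float(alpha)]), tol, max_sweeps)
    if not converged:
        raise EstimationError(f"coordinate descent did not converge at alpha={alpha}")
    return B[0]


def _alpha_grid(lam_max: float, config: EstimationConfig) -> np.ndarray:
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, config.alpha_min_ratio * lam_max, config.n_alphas)


def subject_folds(subject_ids, n_folds: int, cv_seed: int) -> np.ndarray:
    """Deterministic, row-order-invariant fold labels from subject ids.

    Each subject's fold is ``crc32("<id>|<seed>") % n_folds``, so permuting
    rows (or duplicating a subject in a bootstrap resample) never changes
    fold membership.
    """
    return np.array(
        [zlib.crc32(f"{s}|{cv_seed}".encode()) % n_folds for s in subject_ids],
        dtype=np.int64,
    )


def _cv_fit_multi(
    Xs: np.ndarray,
    Ys: np.ndarray,
    subject_ids,
    config: EstimationConfig,
    labels: list[str],
):
    """CV-selected LASSO of every Ys column on Xs (shared fold moments).

    Inputs must already be centered/standardized per the config. Returns
    ``(W (N, p), lambdas (N,))`` with one coefficient row per outcome.
    """
    n, p = Xs.shape
    N = Ys.shape[1]
    n_folds = config.cv_folds

    c_full = Xs.T @ Ys / n  # (p, N)
    lam_max_all = np.abs(c_full).max(axis=0)
    if np.any(lam_max_all <= 0):
        j = int(np.flatnonzero(lam_max_all <= 0)[0])
        raise EstimationError(f"node {labels[j]!r}: degenerate outcome (lambda_max = 0)")
    alphas_all = np.stack([_alpha_grid(lm, config) for lm in lam_max_all])

    folds = subject_folds(subject_ids, n_folds, config.cv_seed)
    m = np.bincount(folds, minlength=n_folds).astype(float)
    if np.any(m == 0):
        raise EstimationError(
            f"fold(s) {np.flatnonzero(m == 0).tolist()} received no subjects; "
            "use fewer folds or more subjects"
        )

    # per-fold raw moments (outcome-major layouts), then training complements
    S1 = np.zeros((n_folds, p))
    S2 = np.zeros((n_folds, p, p))
    Sy = np.zeros((n_folds, N, p))
    s1y = np.zeros((n_folds, N))
    Syy = np.zeros((n_folds, N))
    for f in range(n_folds):
        rows = folds == f
        Xf, Yf = Xs[rows], Ys[rows]
        S1[f] = Xf.sum(axis=0)
        S2[f] = Xf.T @ Xf
        Sy[f] = Yf.T @ Xf
        s1y[f] = Yf.sum(axis=0)
        Syy[f] = (Yf**2).sum(axis=0)
    m_tr = n - m
    S1_tr = S1.sum(axis=0) - S1
    S2_tr = S2.sum(axis=0) - S2
    Sy_tr = Sy.sum(axis=0) - Sy
    s1y_tr = s1y.sum(axis=0) - s1y
    xbar_tr = S1_tr / m_tr[:, None]
    ybar_tr = s1y_tr / m_tr[:, None]
    G_tr = S2_tr / m_tr[:, None, None] - np.einsum("fi,fj->fij", xbar_tr, xbar_tr)
    C_tr = Sy_tr / m_tr[:, None, None] - np.einsum("fj,fi->fji", ybar_tr, xbar_tr)

    fold_mse, converged = cv_fold_mse(
        G_tr, C_tr, xbar_tr, ybar_tr,
        S2, S1, Sy, s1y, Syy, m,
        alphas_all, config.tol, config.max_sweeps,
    )
    if not converged:
        raise EstimationError("coordinate descent did not converge in a CV fold")

    mean_mse = fold_mse.mean(axis=1)  # (N, na)
    G_full = Xs.T @ Xs / n
    W = np.zeros((N, p))
    lambdas = np.zeros(N)
    for j in range(N):
        idx_min = int(np.argmin(mean_mse[j]))
        if config.lambda_rule == "min":
            idx = idx_min
        else:
            se = fold_mse[j].std(axis=0, ddof=1) / np.sqrt(n_folds)
            within = np.flatnonzero(mean_mse[j] <= mean_mse[j, idx_min] + se[idx_min])
            idx = int(within[0])  # grid descends: first index = largest penalty
        B, ok = cd_path(G_full, c_full[:, j], alphas_all[j], config.tol, config.max_sweeps)
        if not ok:
            raise EstimationError(
                f"node {labels[j]!r}: coordinate descent did not converge"
            )
        W[j] = B[idx]
        lambdas[j] = alphas_all[j, idx]
    return W, lambdas


def _prepare(X, y, config, node_id):
    if config.standardize:
        sx = X.std(axis=0, ddof=0)
        sy = y.std(ddof=0)
        if np.any(sx == 0) or sy == 0:
            bad = (
                "outcome"
                if sy == 0
                else f"predictor column {int(np.flatnonzero(sx == 0)[0])}"
            )
            raise EstimationError(f"node {node_id!r}: zero-variance {bad}")
        return (X - X.mean(axis=0)) / sx, (y - y.mean()) / sy
    return X - X.mean(axis=0), y - y.mean()


def fit_node_lasso(
    X: np.ndarray,
    y: np.ndarray,
    config: EstimationConfig | None = None,
    subject_ids=None,
    node_id: str = "?",
):
    """One node-wise regression: CV-selected LASSO of y on the X columns.

    Standardizes X and y (population sd) when ``config.standardize``,
    otherwise only centers. Returns ``(coef, selected_lambda)`` on the
    (standardized) input scale.
    """
    config = config or EstimationConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < config.cv_folds:
        raise EstimationError(
            f"node {node_id!r}: {n} subjects but {config.cv_folds} CV folds"
        )
    if n <= p:
        warnings.warn(
            f"node {node_id!r}: n={n} subjects <= p={p} predictors", stacklevel=2
        )
    if subject_ids is None:
        subject_ids = np.arange(n)
    Xs, ys = _prepare(X, y, config, node_id)
    W, lambdas = _cv_fit_multi(Xs, ys[:, None], subject_ids, config, [node_id])
    return W[0], float(lambdas[0])


# ---------------------------------------------------------------------------
# Network assembly


def estimation_sample(data: PanelDataset, wave_pair: tuple[str, str]):
    """Rows complete at both waves: (subject ids, X_t matrix, Y_{t+1} matrix)."""
    wa, wb = wave_pair
    A = data.wave_matrix(wa)
    Bm = data.wave_matrix(wb)
    ok = ~np.isnan(A).any(axis=1) & ~np.isnan(Bm).any(axis=1)
    return data.subjects[ok], A[ok], Bm[ok]


def estimate_clpn(
    data: PanelDataset, wave_pair: tuple[str, str], config: EstimationConfig | None = None
) -> CLPNetwork:
    """Estimate the cross-lagged network for one wave pair.

    Subjects with complete (observed or imputed) responses at both waves
    enter; all 13 wave-t predictors and each wave-(t+1) outcome are
    z-standardized on this sample; one CV-selected LASSO regression per
    outcome node fills the corresponding row of W.
    """
    config = config or EstimationConfig()
    subjects, X, Y = estimation_sample(data, wave_pair)
    n, p = X.shape
    if n < config.cv_folds:
        raise EstimationError(f"only {n} complete subjects for wave pair {wave_pair}")
    if n < 50:
        warnings.warn(f"only {n} subjects enter estimation for {wave_pair}", stacklevel=2)

    sx = X.std(axis=0, ddof=0)
    sy = Y.std(axis=0, ddof=0)
    for k, bad in enumerate((sx == 0) | (sy == 0)):
        if bad:
            raise EstimationError(
                f"item {data.item_ids[k]!r} has zero variance in the estimation sample"
            )
    if config.standardize:
        Xs = (X - X.mean(axis=0)) / sx
        Ys = (Y - Y.mean(axis=0)) / sy
    else:
        Xs = X - X.mean(axis=0)
        Ys = Y - Y.mean(axis=0)

    W, lambdas = _cv_fit_multi(Xs, Ys, subjects, config, data.item_ids)

    return CLPNetwork(
        nodes=list(data.item_ids),
        W=W,
        lambdas=lambdas,
        wave_pair=tuple(wave_pair),
        n_used=n,
        cv_seed=config.cv_seed,
        meta={
            "lambda_rule": config.lambda_rule,
            "cv_folds": config.cv_folds,
            "n_alphas": config.n_alphas,
            "standardize": config.standardize,
        },
    )


def count_nonzero_edges(net: CLPNetwork, include_autoregressive: bool = False) -> int:
    """Number of exactly nonzero weights (off-diagonal unless requested)."""
    W = net.W
    if include_autoregressive:
        return int(np.count_nonzero(W))
    off = ~np.eye(net.n_nodes, dtype=bool)
    return int(np.count_nonzero(W[off]))


def apply_display_threshold(net: CLPNetwork, threshold: float | None = None) -> CLPNetwork:
    """Copy of the network with |weight| < threshold blanked, for display only.

    The strict inequality follows the usual figure convention (a weight
    exactly at the threshold is kept). Estimation results, centrality and
    bootstraps always operate on the unthresholded network.
    """
    thr = net.meta.get("display_threshold", 0.05) if threshold is None else threshold
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    W = net.W.copy()
    W[np.abs(W) < thr] = 0.0
    return replace(net, W=W, lambdas=np.asarray(net.lambdas).copy(),
                   meta={**net.meta, "display_threshold_applied": thr})
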