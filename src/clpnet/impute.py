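"""Single-dataset predictive mean matching (PMM) imputation.

Chained-equations imputation where each incomplete item column is
regressed on all other item columns (every item at every wave) plus the
auxiliary covariates, and a missing cell receives the *observed* value of
a donor whose model-predicted value is closest to the missing case's
prediction. Because donors are observed values, imputations can never
fall outside an item's Likert range or create fractional categories.

A single imputed dataset (not multiple imputation with pooling) is
produced: downstream network estimation has no pooling rule for LASSO
networks, so the single-dataset route is the appropriate one here.
Type-1 matching is used: observed cases are predicted from the
least-squares fit, missing cases from a Bayesian parameter draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .panel import PanelDataset

logger = logging.getLogger(__name__)


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    """PMM settings.

    ``n_donors`` candidate donors per missing cell (one drawn uniformly);
    ``max_iter`` chained-equation sweeps; ``auxiliary`` names of complete
    per-subject covariates entering every imputation model.
    """

    n_donors: int = 5
    max_iter: int = 10
    seed: int = 0
    auxiliary: tuple[str, ...] = ("sex", "ethnicity", "age")

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _ridge_lstsq(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8):
    """Least squares with a tiny ridge for rank safety; returns (beta, cov_chol, sigma)."""
    n, p = X.shape
    G = X.T @ X + ridge * np.eye(p)
    beta = np.linalg.solve(G, X.T @ y)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    Ginv = np.linalg.inv(G)
    return beta, Ginv, sigma2, dof


def pmm_donor_draw(
    pred_obs: np.ndarray,
    obs_values: np.ndarray,
    pred_mis: np.ndarray,
    n_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Match each missing prediction to its closest observed predictions.

    For every missing case, the ``n_donors`` observed cases with the
    smallest ``|pred_obs - pred_mis|`` are the candidate donors; one is
    drawn uniformly and its observed value imputed.
    """
    imputed = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        donors = np.argpartition(d, n_donors - 1)[:n_donors]
        imputed[i] = obs_values[donors[rng.integers(n_donors)]]
    return imputed


def pmm_impute(data: PanelDataset, config: ImputationConfig | None = None) -> PanelDataset:
    """Impute all missing responses by chained-equation PMM.

    Items are treated as numeric inside the regressions (the network
    estimator treats them as continuous too); the donor mechanism restores
    ordinality. Variables are visited in order of ascending missingness.
    Deterministic given ``config.seed``. Raises if any incomplete item has
    fewer observed values than ``n_donors``.
    """
    config = config or ImputationConfig()
    rng = np.random.default_rng(config.seed)
    n, n_waves, p = data.responses.shape

    # flatten to an (n, p * n_waves) item-column matrix, wave-major
    cols = np.column_stack(
        [data.responses[:, t, k] for t in range(n_waves) for k in range(p)]
    )
    names = [f"{data.item_ids[k]}__{data.waves[t]}" for t in range(n_waves) for k in range(p)]
    miss = np.isnan(cols)
    if not miss.any():
        return data.copy()

    n_obs = (~miss).sum(axis=0)
    for c in np.flatnonzero(miss.any(axis=0)):
        if n_obs[c] < config.n_donors:
            raise ImputationError(
                f"variable {names[c]!r} has {n_obs[c]} observed values "
                f"(< n_donors={config.n_donors})"
            )
        if n_obs[c] == 0:
            raise ImputationError(f"variable {names[c]!r} has no observed values")

    aux = None
    if data.aux is not None:
        use = [c for c in config.auxiliary if c in data.aux.columns]
        if use:
            aux = data.aux[list(use)].to_numpy(dtype=float)
            if np.isnan(aux).any():
                # mode/median fill: auxiliaries are assumed essentially complete
                for j in range(aux.shape[1]):
                    col = aux[:, j]
                    col[np.isnan(col)] = np.nanmedian(col)

    # initialize missing cells by random draws from the observed values
    filled = cols.copy()
    for c in np.flatnonzero(miss.any(axis=0)):
        obs_vals = cols[~miss[:, c], c]
        filled[miss[:, c], c] = rng.choice(obs_vals, size=miss[:, c].sum(), replace=True)

    incomplete = np.flatnonzero(miss.any(axis=0))
    visit = incomplete[np.argsort(miss[:, incomplete].sum(axis=0), kind="stable")]

    for sweep in range(config.max_iter):
        for c in visit:
            m = miss[:, c]
            others = np.delete(np.arange(filled.shape[1]), c)
            Xfull = filled[:, others]
            if aux is not None:
                Xfull = np.column_stack([Xfull, aux])
            Xfull = np.column_stack([np.ones(n), Xfull])
            Xo, yo = Xfull[~m], cols[~m, c]
            beta, Ginv, sigma2, dof = _ridge_lstsq(Xo, yo)
            # proper-imputation parameter draw (type-1 matching)
            sigma2_star = sigma2 * dof / rng.chisquare(dof)
            L = np.linalg.cholesky(Ginv + 1e-12 * np.eye(Ginv.shape[0]))
            beta_star = beta + np.sqrt(sigma2_star) * (L @ rng.standard_normal(len(beta)))
            pred_obs = Xo @ beta
            pred_mis = Xfull[m] @ beta_star
            if not (np.all(np.isfinite(pred_obs)) and np.all(np.isfinite(pred_mis))):
                raise ImputationError(f"non-finite predictions for {names[c]!r}")
            filled[m, c] = pmm_donor_draw(pred_obs, yo, pred_mis, config.n_donors, rng)

    out = data.responses.copy()
    for idx, (t, k) in enumerate((t, k) for t in range(n_waves) for k in range(p)):
        out[:, t, k] = filled[:, idx]
    n_imputed = int(miss.sum())
    logger.info("PMM imputed %d of %d cells in %d sweeps",
                n_imputed, cols.size, config.max_iter)
    return replace(data, responses=out)


def complete_cases(data: PanelDataset, waves: list[str] | None = None) -> PanelDataset:
    """Subjects with zero missing responses across the listed waves.

    Used for the complete-case sensitivity analysis. Logs the retained
    count; an empty result warns rather than raises.
    """
    waves = list(waves) if waves is not None else list(data.waves)
    idx = [data.wave_index(w) for w in waves]
    keep = ~np.isnan(data.responses[:, idx, :]).any(axis=(1, 2))
    n_keep = int(keep.sum())
    logger.info("complete cases: retained %d of %d subjects", n_keep, data.n_subjects)
    if n_keep == 0:
        logger.warning("no complete cases remain for waves %s", waves)
    return data.subset(keep)
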