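"""Synthetic ordinal panel data with a sparse cross-lagged VAR(1) backbone.

The generator emulates the statistical structure a cross-lagged panel
network analysis assumes: a latent first-order vector-autoregressive
process among 13 symptoms (autoregressive diagonal plus a sparse set of
cross-lagged paths), ordinal measurement through per-item thresholds onto
the Likert scales of the GHQ-12 (0-3) and a loneliness item (1-3), and
wave-level attrition that depends on observed covariates (sex, ethnicity,
age) — i.e. missing-at-random dropout.

The wave-t latent vector is z-standardized across subjects before the
weight matrix ``B`` is applied, so ``B`` lives on the same standardized
scale as the coefficients the estimator reports and parameter recovery
can be read off directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AUX_COLUMNS, PanelDataset
from .schema import ItemSchema, default_schema

logger = logging.getLogger(__name__)


@dataclass
class TrueModel:
    """Ground-truth generating model for a synthetic symptom panel.

    ``B[j, i]`` is the effect of (standardized) item i at wave t on item j
    at wave t+1; the diagonal holds the autoregressive paths. ``thresholds``
    gives, per item, the ordered cut-points that discretize the latent value
    into that item's Likert categories (``n_categories - 1`` cut-points).
    ``missingness_params`` are logistic-regression coefficients
    ``(intercept, sex, ethnicity, age_centered)`` for per-wave dropout.
    """

    B: np.ndarray
    innovation_sd: np.ndarray
    wave1_cov: np.ndarray
    thresholds: list[np.ndarray]
    missingness_params: np.ndarray
    schema: list[ItemSchema] = field(default_factory=default_schema)
    sparsity_mask: np.ndarray | None = None
    out_hub: str | None = None
    in_hub: str | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.innovation_sd = np.broadcast_to(
            np.asarray(self.innovation_sd, dtype=float), (self.n_items,)
        ).copy()
        self.wave1_cov = np.asarray(self.wave1_cov, dtype=float)
        self.validate()

    @property
    def n_items(self) -> int:
        return self.B.shape[0]

    def validate(self) -> None:
        p = self.n_items
        if self.B.shape != (p, p):
            raise ValueError("B must be square")
        rho = spectral_radius(self.B)
        if rho >= 1.0:
            raise ValueError(f"spectral radius of B is {rho:.3f} >= 1 (non-stationary)")
        if np.any(self.innovation_sd < 0):
            raise ValueError("innovation_sd must be non-negative")
        if self.wave1_cov.shape != (p, p):
            raise ValueError("wave1_cov must be p x p")
        eigmin = np.linalg.eigvalsh((self.wave1_cov + self.wave1_cov.T) / 2).min()
        if eigmin < -1e-8:
            raise ValueError(f"wave1_cov is not positive semi-definite (eigmin={eigmin:.2e})")
        if len(self.thresholds) != p:
            raise ValueError("one threshold vector per item required")
        for k, (cuts, item) in enumerate(zip(self.thresholds, self.schema)):
            cuts = np.asarray(cuts, dtype=float)
            if len(cuts) != item.n_categories - 1:
                raise ValueError(
                    f"item {item.item_id!r}: {len(cuts)} cut-points for "
                    f"{item.n_categories} categories"
                )
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"item {item.item_id!r}: thresholds not strictly increasing")
            self.thresholds[k] = cuts
        if self.sparsity_mask is not None:
            off_mask = ~np.asarray(self.sparsity_mask, dtype=bool)
            if np.any(self.B[off_mask] != 0):
                raise ValueError("B has nonzero entries outside the sparsity mask")

    def true_expected_influence(self) -> pd.DataFrame:
        """Out-/in-expected-influence of the generating matrix (diagonal excluded)."""
        off = self.B - np.diag(np.diag(self.B))
        return pd.DataFrame(
            {
                "item": [s.item_id for s in self.schema],
                "out_ei": off.sum(axis=0),
                "in_ei": off.sum(axis=1),
            }
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int
    n_waves: int = 2
    seed: int = 0
    missingness_on: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(B))))


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # degenerate columns pass through centered
    return (X - X.mean(axis=0)) / sd


def _discretize(latent: np.ndarray, model: TrueModel) -> np.ndarray:
    out = np.empty_like(latent)
    for k, item in enumerate(model.schema):
        cat = np.searchsorted(model.thresholds[k], latent[:, k], side="right")
        out[:, k] = item.scale_min + cat
    return out


def simulate_panel(
    model: TrueModel, config: SimulationConfig
) -> tuple[PanelDataset, np.ndarray]:
    """Draw a complete ordinal panel plus the underlying latent values.

    Wave-1 latents come from ``wave1_cov``; each later wave is
    ``B @ z(latent_t) + innovation``. Returns the validated dataset and the
    ``(n_subjects, n_waves, n_items)`` latent array (for recovery tests).
    With ``missingness_on`` the MAR dropout step is applied afterwards.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, model.n_items

    aux = _draw_covariates(n, rng)

    latent = np.empty((n, config.n_waves, p))
    chol = _psd_cholesky(model.wave1_cov)
    latent[:, 0, :] = rng.standard_normal((n, p)) @ chol.T
    for t in range(1, config.n_waves):
        z = _standardize_columns(latent[:, t - 1, :])
        innov = rng.standard_normal((n, p)) * model.innovation_sd
        latent[:, t, :] = z @ model.B.T + innov

    responses = np.empty((n, config.n_waves, p))
    for t in range(config.n_waves):
        responses[:, t, :] = _discretize(latent[:, t, :], model)

    subjects = np.array([f"s{i:06d}" for i in range(n)])
    waves = [f"w{t + 1}" for t in range(config.n_waves)]
    data = PanelDataset(subjects, waves, responses, list(model.schema), aux)
    if config.missingness_on:
        data = apply_mar_missingness(data, model, seed=rng.integers(2**31))
    return data, latent


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
        if vals.min() < -1e-8:
            raise ValueError("wave1_cov is not positive semi-definite") from None
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sex (1 = male, ~42%), ethnicity (1 = non-white, ~15%), age in years."""
    return pd.DataFrame(
        {
            "sex": (rng.random(n) < 0.42).astype(int),
            "ethnicity": (rng.random(n) < 0.15).astype(int),
            "age": np.clip(rng.normal(50.0, 17.0, n), 16.0, 95.0).round(0),
        }
    )


def apply_mar_missingness(
    data: PanelDataset, model: TrueModel, seed: int
) -> PanelDataset:
    """Wave-level MAR dropout driven by sex, ethnicity and (centered) age.

    Each subject's wave after the first is set entirely missing with
    probability ``logistic(params . (1, sex, ethnicity, age - 50))``. The
    first wave is always observed. The realized marginal rate is logged.
    """
    if data.aux is None:
        raise ValueError("aux covariates required for MAR missingness")
    rng = np.random.default_rng(seed)
    b0, b_sex, b_eth, b_age = model.missingness_params
    lin = (
        b0
        + b_sex * data.aux["sex"].to_numpy()
        + b_eth * data.aux["ethnicity"].to_numpy()
        + b_age * (data.aux["age"].to_numpy() - 50.0)
    )
    prob = 1.0 / (1.0 + np.exp(-lin))
    out = data.responses.copy()
    dropped = 0
    for t in range(1, data.n_waves):
        drop = rng.random(data.n_subjects) < prob
        out[drop, t, :] = np.nan
        dropped += int(drop.sum())
    total = data.n_subjects * (data.n_waves - 1)
    logger.info(
        "MAR dropout: %d of %d subject-waves missing (%.1f%%)",
        dropped, total, 100.0 * dropped / max(total, 1),
    )
    return replace(data, responses=out)


def apply_item_missingness(
    data: PanelDataset, rate: float, seed: int, first_wave_observed: bool = True
) -> PanelDataset:
    """Item-level MCAR missingness at the given rate (for imputation tests)."""
    rng = np.random.default_rng(seed)
    mask = rng.random(data.responses.shape) < rate
    if first_wave_observed:
        mask[:, 0, :] = False
    out = data.responses.copy()
    out[mask] = np.nan
    return replace(data, responses=out)


# ---------------------------------------------------------------------------
# Default generating model

# Backbone cross-lagged paths (from, to, weight), echoing the strongest
# connections reported for GHQ/loneliness panels: worthlessness and
# loneliness drive other symptoms; feeling depressed receives many paths.
_BACKBONE = [
    ("ghq_worthless", "ghq_confidence", 0.20),
    ("loneliness", "ghq_depressed", 0.17),
    ("loneliness", "ghq_confidence", 0.14),
    ("loneliness", "ghq_worthless", 0.13),
    ("ghq_worthless", "ghq_overcome", 0.13),
    ("ghq_confidence", "ghq_worthless", 0.10),
    ("ghq_overcome", "ghq_stress", 0.12),
    ("loneliness", "ghq_overcome", 0.11),
    ("ghq_sleep", "ghq_stress", 0.12),
    ("ghq_stress", "ghq_sleep", 0.12),
    ("ghq_worthless", "ghq_depressed", 0.12),
    ("ghq_stress", "ghq_depressed", 0.11),
    ("ghq_overcome", "ghq_depressed", 0.11),
]

_N_FILLER_EDGES = 7
_AUTOREGRESSIVE = 0.3


def default_true_model(seed: int = 0) -> TrueModel:
    """The package's reference 13-item generating model.

    Autoregressive diagonal 0.3; 13 fixed backbone cross-lagged paths with
    a designated out-hub (loneliness, largest true out-expected-influence)
    and in-hub (feeling depressed), plus 7 seed-dependent filler paths with
    |weight| in [0.10, 0.15) placed so no other node can overtake the hubs.
    Thresholds are standard-normal quantiles that put most mass in the low
    Likert categories, mimicking the right-skew of symptom items.
    """
    rng = np.random.default_rng(seed)
    schema = default_schema()
    ids = [s.item_id for s in schema]
    pos = {item_id: k for k, item_id in enumerate(ids)}
    p = len(ids)

    B = np.diag(np.full(p, _AUTOREGRESSIVE))
    for src, dst, w in _BACKBONE:
        B[pos[dst], pos[src]] = w

    # filler edges: at most one extra outgoing edge per source and one
    # incoming edge per destination, never out of the hub sources, so the
    # designated out-hub (loneliness) and in-hub (feeling depressed) keep
    # the largest true expected influence for every seed
    hub_sources = {pos["loneliness"], pos["ghq_worthless"]}
    used_sources: set[int] = set()
    used_dests: set[int] = {pos["ghq_depressed"]}
    n_added = 0
    while n_added < _N_FILLER_EDGES:
        i = int(rng.integers(p))
        j = int(rng.integers(p))
        if (
            i == j
            or i in hub_sources
            or i in used_sources
            or j in used_dests
            or B[j, i] != 0
        ):
            continue
        w = rng.uniform(0.10, 0.15)
        if rng.random() < 0.15:
            w = -w
        B[j, i] = w
        used_sources.add(i)
        used_dests.add(j)
        n_added += 1

    mask = B != 0

    # first-wave latent correlations: moderate positive among GHQ items,
    # weaker with loneliness
    cov = np.full((p, p), 0.35)
    lon = pos["loneliness"]
    cov[lon, :] = cov[:, lon] = 0.25
    np.fill_diagonal(cov, 1.0)

    # innovation variance keeps later-wave latent variance near 1
    explained = np.diag(B @ cov @ B.T)
    innovation_sd = np.sqrt(np.clip(1.0 - explained, 0.2, None))

    thresholds = []
    for item in schema:
        if item.n_categories == 4:
            cum = np.array([0.55, 0.85, 0.96])
        else:
            cum = np.array([0.65, 0.88])
        thresholds.append(stats.norm.ppf(cum))

    # dropout ~22% per wave at the covariate means, higher for male,
    # non-white and older subjects
    missingness_params = np.array([-1.5, 0.25, 0.45, 0.015])

    return TrueModel(
        B=B,
        innovation_sd=innovation_sd,
        wave1_cov=cov,
        thresholds=thresholds,
        missingness_params=missingness_params,
        schema=schema,
        sparsity_mask=mask,
        out_hub="loneliness",
        in_hub="ghq_depressed",
    )
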