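"""Descriptive statistics for ordinal symptom panels.

Covers the usual reporting block for GHQ-type instruments: per-item
moments, sum-score summaries, internal consistency (Cronbach's alpha and
McDonald's omega total from a one-factor fit), caseness proportions, and
paired-sample change tests (t with Hedges's g) across wave pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GHQ_CASENESS_CUTOFF, PanelDataset, ghq_sum_and_caseness
from .schema import GHQ_ITEM_IDS

logger = logging.getLogger(__name__)


@dataclass
class DescriptivesTable:
    """Container for the descriptive-statistics report.

    ``items``: one row per (item, wave) with mean, sd, skewness and excess
    kurtosis (both bias-adjusted, normal = 0). ``waves``: one row per wave
    with GHQ sum-score mean/sd, alpha, omega total and caseness proportion.
    ``pairs``: one row per wave pair with the paired t statistic, df,
    p-value, Hedges's g and the number of paired subjects.
    """

    items: pd.DataFrame
    waves: pd.DataFrame
    pairs: pd.DataFrame

    def to_csv(self, path) -> None:
        """Single CSV: item rows, then per-wave and per-pair summary blocks."""
        blocks = []
        for name, frame in (("item", self.items), ("wave", self.waves), ("pair", self.pairs)):
            f = frame.copy()
            f.insert(0, "block", name)
            blocks.append(f)
        out = pd.concat(blocks, ignore_index=True)
        out.to_csv(path, index=False, float_format="%.6g")


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an ``(n_subjects, k)`` complete item matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum),
    with sample (n-1) variances. Undefined (NaN) when the sum score has
    zero variance.
    """
    n, k = items.shape
    var_sum = np.var(items.sum(axis=1), ddof=1)
    if var_sum <= 0:
        logger.warning("zero variance of the sum score; alpha undefined")
        return np.nan
    return k / (k - 1) * (1.0 - np.var(items, axis=0, ddof=1).sum() / var_sum)


def omega_total(
    items: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> float:
    """McDonald's omega total from a one-factor minimum-residual fit.

    Fits a single common factor to the item covariance matrix by iterated
    principal-axis extraction (communalities updated until convergence),
    then returns ``(sum lambda)^2 / ((sum lambda)^2 + sum psi)`` with the
    loading signs fixed so their sum is non-negative. Returns NaN with a
    warning if the fit does not converge or degenerates.
    """
    cov = np.cov(items, rowvar=False, ddof=1)
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        logger.warning("zero-variance item; omega undefined")
        return np.nan
    # start from squared multiple correlations as communalities
    corr = cov / np.sqrt(np.outer(diag, diag))
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        smc = np.full(len(diag), 0.5)
    h2 = np.clip(smc, 0.0, 1.0) * diag
    loadings = None
    for _ in range(max_iter):
        reduced = cov.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        lead = vals[-1]
        if lead <= 0:
            logger.warning("one-factor fit degenerate; omega undefined")
            return np.nan
        loadings = np.sqrt(lead) * vecs[:, -1]
        new_h2 = np.clip(loadings**2, 0.0, diag)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    else:
        logger.warning("one-factor fit did not converge in %d iterations", max_iter)
        return np.nan
    if loadings.sum() < 0:
        loadings = -loadings
    psi = np.maximum(diag - loadings**2, 0.0)
    s = loadings.sum()
    return s**2 / (s**2 + psi.sum())


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Small-sample-corrected standardized paired mean difference.

    Uses the pooled SD of the two measurement occasions (not the SD of the
    differences) and the correction factor J = 1 - 3/(4 df - 1) with
    df = n - 1 paired observations.
    """
    n = len(x)
    pooled = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    df = n - 1
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return j * (np.mean(y) - np.mean(x)) / pooled


def descriptives(
    data: PanelDataset, wave_pairs: list[tuple[str, str]] | None = None
) -> DescriptivesTable:
    """Compute the full descriptive report for a panel.

    Per-item moments use all observed responses at each wave. Sum-score
    summaries, alpha, omega and caseness are computed over subjects with
    all 12 GHQ items observed at the wave. Paired tests use subjects with
    complete GHQ responses at both waves of a pair.
    """
    if wave_pairs is None:
        wave_pairs = list(zip(data.waves[:-1], data.waves[1:]))

    item_rows = []
    for wave in data.waves:
        mat = data.wave_matrix(wave)
        for k, item in enumerate(data.schema):
            col = mat[:, k]
            obs = col[~np.isnan(col)]
            row = {"item": item.item_id, "wave": wave, "n_obs": len(obs)}
            if len(obs) >= 2:
                row.update(
                    mean=obs.mean(),
                    sd=obs.std(ddof=1),
                    skewness=stats.skew(obs, bias=False) if len(obs) >= 3 else np.nan,
                    kurtosis=stats.kurtosis(obs, fisher=True, bias=False)
                    if len(obs) >= 4
                    else np.nan,
                )
            else:
                row.update(mean=np.nan, sd=np.nan, skewness=np.nan, kurtosis=np.nan)
            item_rows.append(row)

    ghq_idx = [data.item_index(i) for i in GHQ_ITEM_IDS]
    wave_rows = []
    sums_by_wave = {}
    for wave in data.waves:
        scored = ghq_sum_and_caseness(data, wave)
        sums = scored["ghq_sum"].to_numpy()
        ok = ~np.isnan(sums)
        sums_by_wave[wave] = sums
        ghq = data.wave_matrix(wave)[:, ghq_idx][ok]
        row = {"wave": wave, "n_scored": int(ok.sum())}
        if ok.sum() >= 2:
            row.update(
                ghq_sum_mean=sums[ok].mean(),
                ghq_sum_sd=sums[ok].std(ddof=1),
                alpha=cronbach_alpha(ghq),
                omega=omega_total(ghq),
                caseness_prop=float(np.mean(sums[ok] > GHQ_CASENESS_CUTOFF)),
            )
        else:
            row.update(
                ghq_sum_mean=np.nan, ghq_sum_sd=np.nan,
                alpha=np.nan, omega=np.nan, caseness_prop=np.nan,
            )
        wave_rows.append(row)

    pair_rows = []
    for wa, wb in wave_pairs:
        sa, sb = sums_by_wave[wa], sums_by_wave[wb]
        both = ~np.isnan(sa) & ~np.isnan(sb)
        n = int(both.sum())
        row = {"wave_a": wa, "wave_b": wb, "n_pairs": n, "df": n - 1}
        if n >= 2:
            diff = sa[both] - sb[both]
            if np.all(diff == diff[0]):
                # zero-variance differences: no change (or a constant shift)
                t, p = (0.0, 1.0) if diff[0] == 0 else (np.nan, np.nan)
            else:
                t, p = stats.ttest_rel(sa[both], sb[both])
            row.update(t=float(t), p=float(p), hedges_g=hedges_g(sa[both], sb[both]))
        else:
            row.update(t=np.nan, p=np.nan, hedges_g=np.nan)
        pair_rows.append(row)

    return DescriptivesTable(
        items=pd.DataFrame(item_rows),
        waves=pd.DataFrame(wave_rows),
        pairs=pd.DataFrame(pair_rows),
    )
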