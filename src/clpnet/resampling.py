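"""Bootstrap accuracy, difference tests, and case-drop stability.

Nonparametric bootstrap over subjects: every resample re-runs the entire
estimation procedure, including per-node penalty re-selection, since
fixing the penalty would understate the variability of LASSO edges.
Percentile intervals (2.5/97.5) summarize edge accuracy; difference
tests ask whether the bootstrap distribution of a difference (between
two edges, or two nodes' centralities) excludes zero; the case-drop
bootstrap tracks how far the sample can be thinned before subsample
centralities stop correlating with the full-sample ones, summarized by
the CS coefficient (largest drop proportion at which >= 95% of
subsamples still correlate >= 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import expected_influence, expected_influence_raw
from .estimation import CLPNetwork, EstimationConfig, EstimationError, estimate_clpn
from .panel import PanelDataset

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.1, 0.75, 0.1), 2))
CS_CORRELATION_FLOOR = 0.7
CS_SUBSAMPLE_SHARE = 0.95


@dataclass
class BootstrapResult:
    """Bootstrap distributions of every edge (and derived centralities).

    ``samples`` has shape ``(n_boot, p, p)`` matching the network's W;
    ``centrality_samples`` has shape ``(n_boot, p, 2)`` with out-EI in
    slot 0 and in-EI in slot 1.
    """

    nodes: list[str]
    point: CLPNetwork
    samples: np.ndarray
    seed: int
    centrality_samples: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_boot, p, _ = self.samples.shape
        cs = np.empty((n_boot, p, 2))
        for b in range(n_boot):
            out_ei, in_ei = expected_influence_raw(self.samples[b])
            cs[b, :, 0] = out_ei
            cs[b, :, 1] = in_ei
        self.centrality_samples = cs

    @property
    def n_boot(self) -> int:
        return self.samples.shape[0]

    def edge_ci(self, level: float = 0.95) -> pd.DataFrame:
        """Percentile CI per edge; bounds are finite with lower <= upper."""
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        lower = np.percentile(self.samples, lo, axis=0)
        upper = np.percentile(self.samples, hi, axis=0)
        frame = self.point.edge_frame()
        frame["ci_lower"] = lower.ravel()
        frame["ci_upper"] = upper.ravel()
        frame["boot_mean"] = self.samples.mean(axis=0).ravel()
        return frame

    def _index_pair(self, edge):
        src, dst = edge
        i = self.nodes.index(src) if isinstance(src, str) else int(src)
        j = self.nodes.index(dst) if isinstance(dst, str) else int(dst)
        return j, i  # W[j, i] = src -> dst


def _interval_excludes_zero(diff: np.ndarray, alpha: float) -> bool:
    lo = np.percentile(diff, 100 * alpha / 2)
    hi = np.percentile(diff, 100 * (1 - alpha / 2))
    return bool(lo > 0 or hi < 0)


def edge_difference_test(
    result: BootstrapResult, edge_a, edge_b, alpha: float = 0.05
) -> bool:
    """Bootstrap percentile test that two edge weights differ.

    Edges are ``(from, to)`` pairs of node labels (or indices). Significant
    iff the (alpha/2, 1-alpha/2) percentile interval of the bootstrap
    distribution of the weight difference excludes zero; symmetric in its
    arguments, and an edge never differs from itself.
    """
    ja, ia = result._index_pair(edge_a)
    jb, ib = result._index_pair(edge_b)
    diff = result.samples[:, ja, ia] - result.samples[:, jb, ib]
    if ja == jb and ia == ib:
        return False
    return _interval_excludes_zero(diff, alpha)


def centrality_difference_test(
    result: BootstrapResult, node_a, node_b, index: str = "out", alpha: float = 0.05
) -> bool:
    """Bootstrap percentile test that two nodes' expected influences differ."""
    slot = {"out": 0, "in": 1}[index]
    a = result.nodes.index(node_a) if isinstance(node_a, str) else int(node_a)
    b = result.nodes.index(node_b) if isinstance(node_b, str) else int(node_b)
    if a == b:
        return False
    diff = result.centrality_samples[:, a, slot] - result.centrality_samples[:, b, slot]
    return _interval_excludes_zero(diff, alpha)


def edge_difference_matrix(
    result: BootstrapResult, alpha: float = 0.05, include_autoregressive: bool = False
) -> pd.DataFrame:
    """Symmetric significance matrix over all (off-diagonal) edge pairs."""
    p = len(result.nodes)
    pairs = [
        (j, i)
        for j in range(p)
        for i in range(p)
        if include_autoregressive or i != j
    ]
    flat = np.stack([result.samples[:, j, i] for j, i in pairs], axis=1)
    m = len(pairs)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    sig = np.zeros((m, m), dtype=bool)
    for a in range(m):
        diff = flat[:, a : a + 1] - flat
        lo = np.percentile(diff, lo_q, axis=0)
        hi = np.percentile(diff, hi_q, axis=0)
        sig[a] = (lo > 0) | (hi < 0)
    sig &= sig.T  # numerically symmetric by construction; enforce exactly
    np.fill_diagonal(sig, False)
    labels = [f"{result.nodes[i]}->{result.nodes[j]}" for j, i in pairs]
    return pd.DataFrame(sig, index=labels, columns=labels)


def centrality_difference_matrix(
    result: BootstrapResult, index: str = "out", alpha: float = 0.05
) -> pd.DataFrame:
    slot = {"out": 0, "in": 1}[index]
    c = result.centrality_samples[:, :, slot]
    p = c.shape[1]
    sig = np.zeros((p, p), dtype=bool)
    for a in range(p):
        diff = c[:, a : a + 1] - c
        lo = np.percentile(diff, 100 * alpha / 2, axis=0)
        hi = np.percentile(diff, 100 * (1 - alpha / 2), axis=0)
        sig[a] = (lo > 0) | (hi < 0)
    sig &= sig.T
    np.fill_diagonal(sig, False)
    return pd.DataFrame(sig, index=result.nodes, columns=result.nodes)


def bootstrap_edges(
    data: PanelDataset,
    wave_pair: tuple[str, str],
    config: EstimationConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 10,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the full estimation procedure.

    Each of ``n_boot`` resamples draws subjects with replacement and
    re-runs :func:`estimate_clpn` (penalties re-selected). A resample in
    which some item has zero variance is redrawn (at most ``max_redraws``
    times, logged). Deterministic given ``seed``.
    """
    config = config or EstimationConfig()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if n_boot < 1000:
        logger.warning("n_boot=%d is below the conventional 1000", n_boot)
    point = estimate_clpn(data, wave_pair, config)
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    p = len(point.nodes)
    samples = np.empty((n_boot, p, p))
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(n, size=n)
            boot = data.subset_resample(idx)
            try:
                net = estimate_clpn(boot, wave_pair, config)
                break
            except EstimationError:
                logger.info("redrawing degenerate bootstrap resample %d", b)
        else:
            raise EstimationError(
                f"bootstrap resample {b} degenerate after {max_redraws} redraws"
            )
        samples[b] = net.W
    return BootstrapResult(nodes=point.nodes, point=point, samples=samples, seed=seed)


@dataclass
class StabilityResult:
    """Case-drop bootstrap output.

    ``correlations``: long table (drop proportion, subsample, index,
    correlation with the full-sample centrality). ``cs_coefficient``:
    per-index CS value; an element of the grid, or 0.
    """

    drop_grid: tuple[float, ...]
    correlations: pd.DataFrame
    cs_coefficient: dict[str, float]
    seed: int

    def to_csv(self, path) -> None:
        out = self.correlations.copy()
        for index, cs in self.cs_coefficient.items():
            out[f"cs_{index}"] = cs
        out.to_csv(path, index=False)


def cs_coefficient_from_table(
    correlations: pd.DataFrame,
    drop_grid,
    index: str,
    floor: float = CS_CORRELATION_FLOOR,
    share: float = CS_SUBSAMPLE_SHARE,
) -> float:
    """Largest drop p such that every p' <= p keeps >= `share` of subsample
    correlations at or above `floor`; 0 if the first level already fails.
    NaN correlations (degenerate subsamples) count as failures."""
    cs = 0.0
    for pdrop in sorted(drop_grid):
        sub = correlations[
            (correlations["drop"] == pdrop) & (correlations["index"] == index)
        ]["correlation"].to_numpy()
        ok = np.mean(np.where(np.isnan(sub), -np.inf, sub) >= floor) if len(sub) else 0.0
        if ok >= share:
            cs = pdrop
        else:
            break
    return cs


def casedrop_stability(
    data: PanelDataset,
    wave_pair: tuple[str, str],
    config: EstimationConfig | None = None,
    drop_grid=DEFAULT_DROP_GRID,
    n_boot_per_level: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Case-drop bootstrap of centrality stability.

    For each drop proportion, subjects are subsampled without replacement,
    the network re-estimated, and the Pearson correlation between the
    subsample and full-sample expected influences recorded per index.
    """
    config = config or EstimationConfig()
    full = estimate_clpn(data, wave_pair, config)
    full_cent = expected_influence(full)
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    smallest = int(round((1 - max(drop_grid)) * n))
    if smallest < 50:
        raise ValueError(
            f"largest drop proportion leaves {smallest} subjects (< 50)"
        )
    rows = []
    for pdrop in drop_grid:
        keep_n = int(round((1 - pdrop) * n))
        for b in range(n_boot_per_level):
            idx = rng.choice(n, size=keep_n, replace=False)
            sub = data.subset_resample(idx)
            try:
                net = estimate_clpn(sub, wave_pair, config)
                cent = expected_influence(net)
                for index in ("out", "in"):
                    x, y = full_cent.raw(index), cent.raw(index)
                    if np.std(x) == 0 or np.std(y) == 0:
                        r = np.nan
                    else:
                        r = float(np.corrcoef(x, y)[0, 1])
                    rows.append({"drop": pdrop, "rep": b, "index": index, "correlation": r})
            except EstimationError:
                for index in ("out", "in"):
                    rows.append(
                        {"drop": pdrop, "rep": b, "index": index, "correlation": np.nan}
                    )
    table = pd.DataFrame(rows)
    cs = {
        index: cs_coefficient_from_table(table, drop_grid, index)
        for index in ("out", "in")
    }
    return StabilityResult(
        drop_grid=tuple(drop_grid), correlations=table, cs_coefficient=cs, seed=seed
    )
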