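"""Expected-influence centrality for directed, signed networks.

Out-expected-influence of a node is the signed sum of its outgoing
cross-lagged weights (how strongly the symptom predicts other symptoms at
the next wave); in-expected-influence is the signed sum of its incoming
weights (how strongly it is predicted by others). Autoregressive paths —
the diagonal — are excluded: the indices concern influence on *other*
items. Signs are preserved by definition; this is the one-step variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CLPNetwork


@dataclass
class CentralityTable:
    """Raw and z-standardized in-/out-expected-influence per node."""

    table: pd.DataFrame  # columns: item, out_ei, in_ei, out_ei_z, in_ei_z
    network_id: str = ""

    def raw(self, index: str) -> np.ndarray:
        return self.table[f"{index}_ei"].to_numpy()

    def z(self, index: str) -> np.ndarray:
        return self.table[f"{index}_ei_z"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "network", self.network_id)
        out.to_csv(path, index=False)


def expected_influence_raw(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(out_ei, in_ei) signed off-diagonal column/row sums of a weight matrix."""
    off = W - np.diag(np.diag(W))
    return off.sum(axis=0), off.sum(axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def expected_influence(net: CLPNetwork) -> CentralityTable:
    """In-/out-expected-influence of every node, raw and z-standardized.

    z-standardization is across the nodes of the network (sample sd,
    n-1 denominator), the scale conventionally used for centrality plots.
    """
    out_ei, in_ei = expected_influence_raw(net.W)
    table = pd.DataFrame(
        {
            "item": net.nodes,
            "out_ei": out_ei,
            "in_ei": in_ei,
            "out_ei_z": _zscore(out_ei),
            "in_ei_z": _zscore(in_ei),
        }
    )
    return CentralityTable(table, network_id=f"{net.wave_pair[0]}->{net.wave_pair[1]}")


def centrality_correlation(
    a: CentralityTable, b: CentralityTable, index: str = "out", use_z: bool = False
) -> float:
    """Pearson correlation of one centrality index across two networks.

    Raw and z values differ only by a per-network affine transform, so the
    correlation is identical either way; the flag exists for symmetry with
    reporting. Returns NaN if either vector has zero variance.
    """
    if list(a.table["item"]) != list(b.table["item"]):
        raise ValueError("centrality tables cover different node sets")
    x = a.z(index) if use_z else a.raw(index)
    y = b.z(index) if use_z else b.raw(index)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
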