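"""Cross-network comparison statistics and strongest-edge ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import centrality_correlation, expected_influence
from .estimation import CLPNetwork, count_nonzero_edges


@dataclass
class ComparisonResult:
    """Pairwise network comparison output.

    ``pairwise``: one row per network pair with edge-list and centrality
    correlations. ``per_network``: nonzero edge counts (with and without
    autoregressive paths). ``top_edges``: strongest-edge tables stacked
    across networks.
    """

    pairwise: pd.DataFrame
    per_network: pd.DataFrame
    top_edges: pd.DataFrame

    def to_csv(self, path) -> None:
        self.pairwise.to_csv(path, index=False)


def _net_id(net: CLPNetwork) -> str:
    return f"{net.wave_pair[0]}->{net.wave_pair[1]}"


def edge_list_correlation(
    a: CLPNetwork, b: CLPNetwork, nonzero_union_only: bool = False
) -> float:
    """Pearson correlation of the two vectorized off-diagonal edge lists.

    By default structural zeros (edges penalized out of either network)
    are included; ``nonzero_union_only`` restricts to edges nonzero in at
    least one network.
    """
    if a.nodes != b.nodes:
        raise ValueError("networks cover different node sets")
    off = ~np.eye(a.n_nodes, dtype=bool)
    x, y = a.W[off], b.W[off]
    if nonzero_union_only:
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def top_edges(
    net: CLPNetwork, k: int = 5, exclude_autoregressive: bool = True
) -> pd.DataFrame:
    """The k strongest edges by |weight|, zero-weight edges never listed.

    Ties in |weight| break lexicographically on (from, to) labels so the
    ranking is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = net.edge_frame()
    if exclude_autoregressive:
        frame = frame[~frame["autoregressive"]]
    frame = frame[frame["weight"] != 0].copy()
    frame["abs_weight"] = frame["weight"].abs()
    frame = frame.sort_values(
        ["abs_weight", "from", "to"], ascending=[False, True, True], kind="stable"
    ).head(k)
    frame = frame.drop(columns="abs_weight").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def compare_networks(
    nets: list[CLPNetwork], k_top: int = 5, nonzero_union_only: bool = False
) -> ComparisonResult:
    """Edge-list and centrality correlations across all network pairs.

    All networks must share the same node set and ordering.
    """
    if len(nets) < 1:
        raise ValueError("need at least one network")
    nodes = nets[0].nodes
    for net in nets[1:]:
        if net.nodes != nodes:
            raise ValueError("networks cover different node sets")
    cents = [expected_influence(net) for net in nets]
    pair_rows = []
    for a in range(len(nets)):
        for b in range(a + 1, len(nets)):
            pair_rows.append(
                {
                    "network_a": _net_id(nets[a]),
                    "network_b": _net_id(nets[b]),
                    "edge_r": edge_list_correlation(nets[a], nets[b], nonzero_union_only),
                    "out_ei_r": centrality_correlation(cents[a], cents[b], "out"),
                    "in_ei_r": centrality_correlation(cents[a], cents[b], "in"),
                }
            )
    per_net = pd.DataFrame(
        {
            "network": [_net_id(n) for n in nets],
            "nonzero_edges": [count_nonzero_edges(n, False) for n in nets],
            "nonzero_edges_with_ar": [count_nonzero_edges(n, True) for n in nets],
            "n_used": [n.n_used for n in nets],
        }
    )
    tops = []
    for net in nets:
        t = top_edges(net, k_top)
        t.insert(0, "network", _net_id(net))
        tops.append(t)
    return ComparisonResult(
        pairwise=pd.DataFrame(pair_rows),
        per_network=per_net,
        top_edges=pd.concat(tops, ignore_index=True) if tops else pd.DataFrame(),
    )
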