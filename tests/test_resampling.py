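"""Bootstrap accuracy, difference tests and case-drop stability."""

import numpy as np
import pandas as pd
import pytest

from clpnet import EstimationConfig, SimulationConfig, bootstrap_edges, simulate_panel
from clpnet.estimation import CLPNetwork
from clpnet.resampling import (
    BootstrapResult,
    casedrop_stability,
    centrality_difference_matrix,
    centrality_difference_test,
    cs_coefficient_from_table,
    edge_difference_matrix,
    edge_difference_test,
)


def result_from_samples(samples, nodes=None):
    n_boot, p, _ = samples.shape
    nodes = nodes or [f"n{i}" for i in range(p)]
    point = CLPNetwork(
        nodes=nodes, W=samples.mean(axis=0), lambdas=np.zeros(p),
        wave_pair=("w1", "w2"), n_used=100,
    )
    return BootstrapResult(nodes=nodes, point=point, samples=samples, seed=0)


@pytest.fixture(scope="module")
def small_bootstrap(true_model, fast_config):
    data, _ = simulate_panel(true_model, SimulationConfig(600, 2, seed=61))
    return bootstrap_edges(data, ("w1", "w2"), fast_config, n_boot=100, seed=62)


class TestBootstrapEdges:
    def test_deterministic_given_seed(self, true_model, fast_config):
        data, _ = simulate_panel(true_model, SimulationConfig(300, 2, seed=63))
        a = bootstrap_edges(data, ("w1", "w2"), fast_config, n_boot=100, seed=64)
        b = bootstrap_edges(data, ("w1", "w2"), fast_config, n_boot=100, seed=64)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_ci_bounds_finite_and_ordered(self, small_bootstrap):
        ci = small_bootstrap.edge_ci()
        assert np.isfinite(ci["ci_lower"]).all() and np.isfinite(ci["ci_upper"]).all()
        assert (ci["ci_lower"] <= ci["ci_upper"]).all()

    def test_percentiles_match_sort_and_index_oracle(self):
        # brute-force percentile on a stored 10-value bootstrap vector
        vec = np.array([0.3, -0.1, 0.2, 0.05, 0.4, 0.15, 0.25, 0.0, 0.1, 0.35])
        samples = np.zeros((10, 2, 2))
        samples[:, 0, 1] = vec
        res = result_from_samples(samples)
        ci = res.edge_ci()
        row = ci[(ci["from"] == "n1") & (ci["to"] == "n0")].iloc[0]
        # linear-interpolation percentile computed by hand from the sorted vector
        s = np.sort(vec)
        lo = s[0] + (s[1] - s[0]) * (0.025 * 9 - 0)
        hi = s[8] + (s[9] - s[8]) * (0.975 * 9 - 8)
        assert row["ci_lower"] == pytest.approx(lo, abs=1e-12)
        assert row["ci_upper"] == pytest.approx(hi, abs=1e-12)

    def test_strong_edge_ci_excludes_zero(self, true_model, fast_config):
        # worthless -> losing confidence carries the largest true weight
        data, _ = simulate_panel(true_model, SimulationConfig(2000, 2, seed=65))
        res = bootstrap_edges(data, ("w1", "w2"), fast_config, n_boot=200, seed=66)
        ci = res.edge_ci()
        row = ci[(ci["from"] == "ghq_worthless") & (ci["to"] == "ghq_confidence")].iloc[0]
        assert row["ci_lower"] > 0


class TestDifferenceTests:
    def test_edge_vs_itself_never_significant(self, small_bootstrap):
        edge = ("loneliness", "ghq_depressed")
        assert edge_difference_test(small_bootstrap, edge, edge) is False

    def test_disjoint_sign_difference_significant(self):
        rng = np.random.default_rng(8)
        samples = np.zeros((100, 2, 2))
        samples[:, 0, 1] = rng.uniform(0.3, 0.4, 100)
        samples[:, 1, 0] = rng.uniform(0.0, 0.05, 100)
        res = result_from_samples(samples)
        assert edge_difference_test(res, ("n1", "n0"), ("n0", "n1")) is True

    def test_flags_match_percentile_oracle(self):
        rng = np.random.default_rng(9)
        samples = rng.standard_normal((100, 3, 3)) * 0.05
        samples[:, 1, 0] += 0.12
        res = result_from_samples(samples)
        for ea, eb in [(("n0", "n1"), ("n1", "n2")), (("n0", "n2"), ("n2", "n1"))]:
            ja, ia = res._index_pair(ea)
            jb, ib = res._index_pair(eb)
            diff = samples[:, ja, ia] - samples[:, jb, ib]
            expected = bool(
                np.percentile(diff, 2.5) > 0 or np.percentile(diff, 97.5) < 0
            )
            assert edge_difference_test(res, ea, eb) is expected

    def test_symmetry_of_difference_tests(self, small_bootstrap):
        pairs = [
            (("loneliness", "ghq_depressed"), ("ghq_worthless", "ghq_confidence")),
            (("ghq_sleep", "ghq_stress"), ("ghq_stress", "ghq_sleep")),
        ]
        for ea, eb in pairs:
            assert edge_difference_test(small_bootstrap, ea, eb) == edge_difference_test(
                small_bootstrap, eb, ea
            )
        assert centrality_difference_test(
            small_bootstrap, "loneliness", "ghq_happy", "out"
        ) == centrality_difference_test(small_bootstrap, "ghq_happy", "loneliness", "out")

    def test_difference_matrices_symmetric_false_diagonal(self, small_bootstrap):
        for mat in (
            centrality_difference_matrix(small_bootstrap, "out"),
            centrality_difference_matrix(small_bootstrap, "in"),
        ):
            assert mat.values.dtype == bool
            assert (mat.values == mat.values.T).all()
            assert not mat.values.diagonal().any()
        em = edge_difference_matrix(small_bootstrap)
        assert (em.values == em.values.T).all()
        assert not em.values.diagonal().any()

    def test_centrality_flags_match_oracle(self, small_bootstrap):
        c = small_bootstrap.centrality_samples
        nodes = small_bootstrap.nodes
        a, b = nodes.index("loneliness"), nodes.index("ghq_happy")
        diff = c[:, a, 0] - c[:, b, 0]
        expected = bool(np.percentile(diff, 2.5) > 0 or np.percentile(diff, 97.5) < 0)
        assert centrality_difference_test(small_bootstrap, "loneliness", "ghq_happy") is expected


class TestCasedropStability:
    def test_full_sample_subsample_correlates_perfectly(self, true_model, fast_config):
        # drop proportion 0: the subsample is the full sample (in permuted
        # order), and estimation is order-invariant, so correlation is 1
        data, _ = simulate_panel(true_model, SimulationConfig(500, 2, seed=67))
        res = casedrop_stability(
            data, ("w1", "w2"), fast_config,
            drop_grid=(0.0,), n_boot_per_level=3, seed=68,
        )
        assert np.allclose(res.correlations["correlation"], 1.0, atol=1e-10)

    def test_cs_coefficient_from_stored_table_matches_scan_oracle(self):
        grid = (0.1, 0.2, 0.3)
        rows = []
        rng = np.random.default_rng(10)
        # correlations engineered: level 0.1 always fine, 0.2 fine in 96%,
        # 0.3 collapses
        for pdrop, low_rate in zip(grid, (0.0, 0.04, 0.5)):
            for rep in range(100):
                r = 0.3 if rng.random() < low_rate else 0.9
                rows.append({"drop": pdrop, "rep": rep, "index": "out", "correlation": r})
        table = pd.DataFrame(rows)
        cs = cs_coefficient_from_table(table, grid, "out")
        # oracle: exhaustive scan over the grid
        expected = 0.0
        for pdrop in sorted(grid):
            sub = table[table["drop"] == pdrop]["correlation"]
            if (sub >= 0.7).mean() >= 0.95:
                expected = pdrop
            else:
                break
        assert cs == expected
        assert cs in (0.0,) + grid

    def test_break_in_sequence_stops_cs(self):
        grid = (0.1, 0.2, 0.3)
        rows = []
        for pdrop, good in zip(grid, (True, False, True)):
            for rep in range(40):
                rows.append(
                    {"drop": pdrop, "rep": rep, "index": "out",
                     "correlation": 0.9 if good else 0.1}
                )
        cs = cs_coefficient_from_table(pd.DataFrame(rows), grid, "out")
        assert cs == 0.1  # the gap at 0.2 caps the coefficient despite 0.3 passing

    def test_too_small_retained_sample_rejected(self, true_model, fast_config):
        data, _ = simulate_panel(true_model, SimulationConfig(60, 2, seed=69))
        with pytest.raises(ValueError, match="< 50"):
            casedrop_stability(data, ("w1", "w2"), fast_config, drop_grid=(0.7,),
                               n_boot_per_level=5, seed=70)
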