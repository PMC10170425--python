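"""End-to-end orchestration: simulate/load -> impute -> estimate ->
centrality -> bootstrap -> stability -> compare, driven by one YAML (or
dict) config, with every output and seed recorded in a run manifest.

Rerunning the same config reproduces every analysis output byte for
byte; only the manifest's wall-clock timings differ between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .centrality import expected_influence
from .compare import compare_networks
from .descriptives import descriptives
from .estimation import EstimationConfig, estimate_clpn
from .impute import ImputationConfig, complete_cases, pmm_impute
from .panel import PanelDataset, read_panel, write_panel
from .resampling import DEFAULT_DROP_GRID, bootstrap_edges, casedrop_stability
from .simulate import SimulationConfig, default_true_model, simulate_panel

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(source) -> dict:
    """Accept a dict, a YAML string/path, and return a plain config dict."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _estimation_config(config: dict) -> EstimationConfig:
    return EstimationConfig(**config.get("estimation", {}))


def _load_or_simulate(config: dict, out_dir: Path):
    model = None
    if "input" in config:
        input_cfg = config["input"]
        data = read_panel(input_cfg["path"], format_config=input_cfg.get("format"))
        return data, model
    sim = config.get("simulate", {})
    model = default_true_model(seed=int(sim.get("model_seed", 0)))
    sim_cfg = SimulationConfig(
        n_subjects=int(sim.get("n_subjects", 1000)),
        n_waves=int(sim.get("n_waves", 2)),
        seed=int(sim.get("seed", 0)),
        missingness_on=bool(sim.get("missingness", False)),
    )
    data, _latent = simulate_panel(model, sim_cfg)
    write_panel(data, out_dir / "panel.csv")
    truth = {
        "B": model.B.tolist(),
        "thresholds": [t.tolist() for t in model.thresholds],
        "innovation_sd": model.innovation_sd.tolist(),
        "out_hub": model.out_hub,
        "in_hub": model.in_hub,
        "model_seed": int(sim.get("model_seed", 0)),
        "sim_seed": sim_cfg.seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return data, model


def run_full_pipeline(config_source, out_dir=None) -> dict:
    """Execute the configured analysis and write the result bundle.

    Returns a dict with the in-memory objects (data, networks,
    centralities, comparison, ...) and the output directory. On a stage
    failure the manifest and any partial outputs are persisted and a
    :class:`PipelineStageError` naming the stage is raised.
    """
    config = load_config(config_source)
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "clpnet_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": config,
        "config_hash": config_hash(config),
        "version": __version__,
        "numpy_version": np.__version__,
        "stages": [],
        "outputs": [],
        "timings_s": {},
    }
    results: dict = {"out_dir": out_dir}

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out_dir)))

    def finish_stage(stage: str, t0: float):
        manifest["stages"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    def write_manifest():
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
        )

    stage = "data"
    try:
        t0 = time.perf_counter()
        data, model = _load_or_simulate(config, out_dir)
        results["data"], results["true_model"] = data, model
        if "input" not in config:
            record(out_dir / "panel.csv")
            record(out_dir / "truth.json")
        finish_stage(stage, t0)

        imp = config.get("impute", {})
        if imp.get("enabled", data.missing_mask().any()):
            stage = "impute"
            t0 = time.perf_counter()
            icfg = ImputationConfig(
                n_donors=int(imp.get("n_donors", 5)),
                max_iter=int(imp.get("max_iter", 10)),
                seed=int(imp.get("seed", 0)),
            )
            if imp.get("complete_cases_only", False):
                data = complete_cases(data)
            else:
                data = pmm_impute(data, icfg)
            results["data_imputed"] = data
            write_panel(data, out_dir / "panel_imputed.csv")
            record(out_dir / "panel_imputed.csv")
            finish_stage(stage, t0)

        if config.get("descriptives", True):
            stage = "descriptives"
            t0 = time.perf_counter()
            desc = descriptives(data)
            desc.to_csv(out_dir / "descriptives.csv")
            record(out_dir / "descriptives.csv")
            results["descriptives"] = desc
            finish_stage(stage, t0)

        wave_pairs = [
            tuple(pair) for pair in config.get(
                "wave_pairs", list(zip(data.waves[:-1], data.waves[1:]))
            )
        ]
        est_cfg = _estimation_config(config)
        nets, cents = [], []
        for wa, wb in wave_pairs:
            tag = f"{wa}_{wb}"
            pair_dir = out_dir / f"pair_{tag}"
            pair_dir.mkdir(exist_ok=True)

            stage = f"estimate[{tag}]"
            t0 = time.perf_counter()
            net = estimate_clpn(data, (wa, wb), est_cfg)
            net.to_json(pair_dir / "network.json")
            net.edge_frame().to_csv(pair_dir / "edges.csv", index=False)
            record(pair_dir / "network.json")
            record(pair_dir / "edges.csv")
            nets.append(net)
            finish_stage(stage, t0)

            stage = f"centrality[{tag}]"
            t0 = time.perf_counter()
            cent = expected_influence(net)
            cent.to_csv(pair_dir / "centrality.csv")
            record(pair_dir / "centrality.csv")
            cents.append(cent)
            finish_stage(stage, t0)

            boot = config.get("bootstrap", {})
            if boot.get("enabled", False):
                stage = f"bootstrap[{tag}]"
                t0 = time.perf_counter()
                res = bootstrap_edges(
                    data, (wa, wb), est_cfg,
                    n_boot=int(boot.get("n_boot", 1000)),
                    seed=int(boot.get("seed", 0)),
                )
                res.edge_ci().to_csv(pair_dir / "edge_ci.csv", index=False)
                record(pair_dir / "edge_ci.csv")
                results.setdefault("bootstrap", {})[tag] = res
                finish_stage(stage, t0)

            stab = config.get("stability", {})
            if stab.get("enabled", False):
                stage = f"stability[{tag}]"
                t0 = time.perf_counter()
                sres = casedrop_stability(
                    data, (wa, wb), est_cfg,
                    drop_grid=tuple(stab.get("drop_grid", DEFAULT_DROP_GRID)),
                    n_boot_per_level=int(stab.get("n_boot_per_level", 1000)),
                    seed=int(stab.get("seed", 0)),
                )
                sres.to_csv(pair_dir / "stability.csv")
                record(pair_dir / "stability.csv")
                results.setdefault("stability", {})[tag] = sres
                finish_stage(stage, t0)

        results["networks"], results["centralities"] = nets, cents

        stage = "compare"
        t0 = time.perf_counter()
        comparison = compare_networks(
            nets, nonzero_union_only=bool(config.get("nonzero_union_only", False))
        )
        comparison.pairwise.to_csv(out_dir / "comparison.csv", index=False)
        comparison.per_network.to_csv(out_dir / "edge_counts.csv", index=False)
        comparison.top_edges.to_csv(out_dir / "top_edges.csv", index=False)
        for name in ("comparison.csv", "edge_counts.csv", "top_edges.csv"):
            record(out_dir / name)
        results["comparison"] = comparison
        finish_stage(stage, t0)
    except Exception as exc:  # persist partial outputs + manifest, then surface
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_manifest()
        raise PipelineStageError(stage, exc) from exc

    write_manifest()
    results["manifest"] = manifest
    return results
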