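"""End-to-end before/after analysis orchestration.

Runs, per condition: thresholding sensitivity sweep -> connectivity
inference -> signed-graph robustness metrics -> (optional) stimulation
forecast -> energy-landscape estimation, and writes a machine-readable
report plus all serialized intermediates.  All randomness derives from a
single master seed, so a fixed config reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from . import landscape as lsc
from . import netmetrics as nm
from . import preprocess as pp
from . import stimulate as stim
from . import synth
from .io import TraceSet, dump_json, load_traces, save_traces

__all__ = ["PipelineConfig", "make_fixture", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to reproduce one before/after analysis."""

    traces: dict = dataclasses.field(default_factory=dict)  # condition -> CSV path
    out_dir: str = "results/pipeline"
    seed: int = 0
    thresholds: list = dataclasses.field(default_factory=lambda: list(np.arange(0.0, 21.0)))
    stability_tol: float = 0.05
    subset_frac: float = 0.7
    train_frac: float = 0.75
    binarize_threshold: float | None = None  # default: the chosen noise threshold
    directed: bool = True
    weight_floor: float = 0.0
    grid_bins: int = 1_000_000
    grid_support: tuple = (-2.7, 2.7)
    landscape_weighting: str = "density"
    run_stimulation: bool = True
    # fixture generation; baselines sit well above zero so that a mid-level
    # binarization threshold yields a fluctuating mean-activity series
    n_neurons: int = 20
    n_hidden: int = 20
    n_frames: int = 4000
    noise_sd: float = 0.8
    baseline_range: tuple = (8.0, 14.0)
    perturbation: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_fixture(config: PipelineConfig, seed: int | None = None) -> dict:
    """Generate related before/after synthetic recordings plus ground truth.

    The "after" network re-draws a fraction of the synaptic matrix entries,
    moving couplings in both directions, which is the kind of bidirectional
    weight change the analysis is meant to detect.
    """
    seed = config.seed if seed is None else seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    before = synth.make_ground_truth_network(
        config.n_neurons,
        config.n_hidden,
        seed=seed,
        noise_sd=config.noise_sd,
        baseline_range=tuple(config.baseline_range),
    )
    after = _perturb_network(before, config.perturbation, rng, tuple(config.baseline_range))

    paths = {}
    nets = {"before": before, "after": after}
    for condition, net in nets.items():
        ts = synth.simulate_linear_dynamics(
            net,
            config.n_frames,
            v0=net.fixed_point + rng.uniform(-0.3, 0.3, net.n_neurons),
            seed=int(rng.integers(2**31 - 1)),
            condition=condition,
        )
        paths[condition] = str(save_traces(ts, out / f"traces_{condition}.csv"))
        dump_json(net.to_dict(), out / f"ground_truth_{condition}.json")
    config.traces = paths
    return {"paths": paths, "networks": nets}


def _perturb_network(
    net: synth.GroundTruthNetwork,
    fraction: float,
    rng: np.random.Generator,
    baseline_range: tuple[float, float] = (8.0, 14.0),
) -> synth.GroundTruthNetwork:
    xi = net.xi.copy()
    mask = rng.random(xi.shape) < fraction
    xi[mask] = rng.normal(xi.mean(), xi.std(), size=mask.sum())
    T = xi @ xi.T
    off = T.copy()
    np.fill_diagonal(off, 0.0)
    radius = max(np.abs(np.linalg.eigvals(T)).max(), np.abs(np.linalg.eigvals(off)).max())
    if radius > 0:
        factor = 0.9 / radius
        T = T * factor
        xi = xi * np.sqrt(factor)
    n = T.shape[0]
    baseline = rng.uniform(*baseline_range, n)
    v_ext = (np.eye(n) - T) @ baseline
    return synth.GroundTruthNetwork(
        xi=xi, T_true=T, v_ext_true=v_ext, noise_sd=net.noise_sd, seed=net.seed
    )


def _analyse_condition(ts: TraceSet, config: PipelineConfig, seed: int, out: Path) -> dict:
    t0 = time.time()
    logger.info("analysing condition %s: %d neurons, %d frames", ts.condition, ts.n_neurons, ts.n_frames)

    report = pp.threshold_sensitivity(
        ts, np.asarray(config.thresholds, dtype=float), subset_frac=config.subset_frac, seed=seed
    )
    try:
        threshold = pp.select_threshold(report, tol=config.stability_tol)
    except pp.NoStableThresholdError:
        logger.warning("no stable threshold found; falling back to the smallest")
        threshold = float(report.thresholds[0])
    dump_json(report.to_dict(), out / f"sensitivity_{ts.condition}.json")

    cleaned = pp.apply_threshold(ts, threshold)
    fc = conn.fit_connectivity(cleaned, train_frac=config.train_frac, threshold_used=threshold)
    dump_json(fc.to_dict(), out / f"connectivity_{ts.condition}.json")
    np.savetxt(out / f"T_{ts.condition}.csv", fc.T, delimiter=",")
    n_pos, n_neg, ratio = conn.connection_sign_counts(fc)

    pair = nm.split_signed_graph(fc, directed=config.directed, weight_floor=config.weight_floor)
    summary = nm.summarize_network(pair, seed=seed)
    dump_json(summary.to_dict(), out / f"network_{ts.condition}.json")

    stim_block = None
    if config.run_stimulation:
        protocol = stim.ramp_then_cutoff(ts.n_neurons, 80, t_off=40, amplitude=1.0, dt=ts.dt)
        traj = stim.forecast_response(fc, np.zeros(ts.n_neurons), protocol)
        rates = stim.decay_profile(traj, t_off=41)
        stim_block = {
            "protocol": "ramp_then_cutoff(80 steps, t_off=40)",
            "peak_response": float(np.nanmax(traj)),
            "decay_rates_defined": int(np.isfinite(rates).sum()),
        }

    bin_thr = config.binarize_threshold if config.binarize_threshold is not None else threshold
    binary = pp.binarize(ts, bin_thr)
    series = lsc.mean_activity(binary, dt=ts.dt, condition=ts.condition)
    landscape = lsc.estimate_landscape(
        series,
        support=tuple(config.grid_support),
        n_bins=config.grid_bins,
        weight_mode=config.landscape_weighting,
    )
    dump_json(landscape.to_dict(), out / f"landscape_{ts.condition}.json")

    return {
        "condition": ts.condition,
        "n_neurons": ts.n_neurons,
        "n_frames": ts.n_frames,
        "chosen_threshold": threshold,
        "connectivity": {
            "train_error": fc.train_error,
            "test_error": fc.test_error,
            "n_positive": n_pos,
            "n_negative": n_neg,
            "sign_ratio": ratio if np.isfinite(ratio) else None,
        },
        "network": summary.to_dict(),
        "stimulation": stim_block,
        "landscape": landscape.to_dict(),
        "wall_time_s": round(time.time() - t0, 3),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for each configured condition and write the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.traces:
        raise ValueError("config.traces must map condition labels to CSV paths")
    report: dict = {
        "provenance": {"config_digest": config.digest(), "seed": config.seed},
        "conditions": {},
    }
    results = {}
    for k, (condition, path) in enumerate(sorted(config.traces.items())):
        try:
            ts = load_traces(path, condition=condition)
            results[condition] = _analyse_condition(ts, config, seed=config.seed + k, out=out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for condition {condition!r}: {exc}") from exc
    report["conditions"] = results

    if {"before", "after"} <= set(results):
        fc_b = _load_fc(out / "connectivity_before.json")
        fc_a = _load_fc(out / "connectivity_after.json")
        delta, (counts, edges) = conn.delta_connectivity(fc_b, fc_a)
        table = nm.betweenness_change_table(
            _bet(results["before"], "excitatory"), _bet(results["after"], "excitatory")
        )
        table_inh = nm.betweenness_change_table(
            _bet(results["before"], "inhibitory"), _bet(results["after"], "inhibitory")
        )
        report["before_after"] = {
            "delta_T_mean_abs": float(np.abs(delta).mean()),
            "delta_histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
            "top_betweenness_changes": {
                "excitatory": table.to_dict(orient="records"),
                "inhibitory": table_inh.to_dict(orient="records"),
            },
            "stability": {
                c: results[c]["landscape"]["stability"]["verdict"] for c in ("before", "after")
            },
        }
    dump_json(report, out / "report.json")
    return report


def _load_fc(path: Path) -> conn.FunctionalConnectivity:
    d = json.loads(path.read_text())
    return conn.FunctionalConnectivity(
        T=np.asarray(d["T"]),
        v_ext=np.asarray(d["v_ext"]),
        train_error=d["train_error"],
        test_error=d["test_error"],
        threshold_used=d["threshold_used"],
        train_frac=d["train_frac"],
        dt=d["dt"],
        neuron_ids=d["neuron_ids"],
    )


def _bet(result: dict, graph: str) -> dict:
    return {k: v for k, v in result["network"]["betweenness"][graph].items()}
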