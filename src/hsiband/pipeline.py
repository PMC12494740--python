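"""End-to-end experiment orchestration and report generation.

``run_experiment`` ties simulation, band selection and classifier training
into one reproducible bundle: a selection report, a method-comparison table,
per-epoch accuracy curves, an accuracy-curve plot, and a manifest echoing the
configuration and seeds. Per-run seeds derive from the master seed by a fixed
offset, so a manifest suffices to replay the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import TrainConfig, run_comparison
from .hypercube import LabeledDataset, nm_width_to_channels, reduction_fraction
from .selection import SelectionConfig, select_for_dataset
from .simulate import SimulationConfig, paper_profile, simulate_dataset, test_profile

log = logging.getLogger("hsiband")

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "selection_report",
    "load_config",
    "benchmark_comparison",
]

_PROFILES = {"paper": paper_profile, "test": test_profile}


@dataclass
class ExperimentConfig:
    """One experiment: simulate a dataset, compare selection methods."""

    simulation: SimulationConfig = field(default_factory=test_profile)
    selection: list[SelectionConfig] = field(
        default_factory=lambda: [SelectionConfig(method=m) for m in ("std", "random")]
    )
    training: TrainConfig = field(default_factory=TrainConfig)
    n_runs: int = 10
    output_dir: Path = Path("hsiband_run")

    def validate(self) -> None:
        axis = self.simulation.axis
        for sel in self.selection:
            w = nm_width_to_channels(sel.window_nm, axis.step_nm)
            if w > axis.n_channels:
                raise ValueError(
                    f"selection window {sel.window_nm} nm spans {w} channels but the "
                    f"axis has only {axis.n_channels}"
                )


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a JSON file.

    Recognised keys: ``profile`` ("paper"/"test") with optional ``simulation``
    overrides (n_classes, cubes_per_class, seed, ...), ``selection`` (list of
    SelectionConfig field dicts), ``training`` (TrainConfig field overrides),
    ``n_runs``, ``output_dir``.
    """
    raw = json.loads(Path(path).read_text())
    profile = _PROFILES[raw.get("profile", "test")]
    sim = profile(**raw.get("simulation", {}))
    selection = [SelectionConfig(**d) for d in raw.get("selection", [{"method": "std"},
                                                                     {"method": "random"}])]
    training = replace(TrainConfig(), **{
        k: tuple(v) if k == "conv_filters" else v
        for k, v in raw.get("training", {}).items()
    })
    return ExperimentConfig(
        simulation=sim, selection=selection, training=training,
        n_runs=int(raw.get("n_runs", 10)),
        output_dir=Path(raw.get("output_dir", "hsiband_run")),
    )


def selection_report(dataset: LabeledDataset, configs: list[SelectionConfig]) -> pd.DataFrame:
    """One row per method: chosen window, its bounds in nm, score, reduction %."""
    axis = dataset.axis
    rows = []
    for cfg in configs:
        w = nm_width_to_channels(cfg.window_nm, axis.step_nm)
        win = select_for_dataset(dataset, cfg)
        rows.append({
            "method": cfg.method,
            "window_nm": cfg.window_nm,
            "w_channels": w,
            "s": win.s,
            "e": win.e,
            "start_nm": axis.wavelength(win.s),
            "end_nm": axis.wavelength(win.e),
            "score": win.score,
            "reduction_percent": 100.0 * reduction_fraction(w, axis.n_channels),
        })
    return pd.DataFrame(rows)


def benchmark_comparison(
    master_seed: int = 0,
    n_runs: int = 10,
    methods: tuple[str, ...] = ("std", "random"),
    window_nm: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """The standard desk-scale repeated-seed benchmark.

    Simulates the test-profile dataset (5 classes x 10 cubes, 32 x 32 x 200
    channels) with ``master_seed`` and compares band-selection methods over
    ``n_runs`` derived seeds. The training budget is deliberately small (12
    epochs, patience 5, (8, 16) conv filters, lr 3e-4) so the full benchmark
    runs in minutes on one CPU; these are the fixed benchmark conditions, not
    tunables.
    """
    dataset = simulate_dataset(test_profile(seed=master_seed))
    selection = [SelectionConfig(method=m, window_nm=window_nm) for m in methods]
    training = TrainConfig(lr_init=3e-4, max_epochs=12, patience=5,
                           conv_filters=(8, 16), seed=master_seed)
    return run_comparison(dataset, selection, n_runs, training)


def _plot_curves(records: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, runs in records.items():
        curves = [r["history"].test_accuracy for r in runs]
        n = min(len(c) for c in curves)
        arr = np.array([c[:n] for c in curves]) * 100
        mean, sd = arr.mean(axis=0), arr.std(axis=0)
        epochs = np.arange(1, n + 1)
        ax.plot(epochs, mean, label=method)
        ax.fill_between(epochs, mean - sd, mean + sd, alpha=0.2)
    ax.set_xlabel("epoch")
    ax.set_ylabel("test accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full pipeline and write the report bundle; returns the bundle dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating dataset: %d classes x %d cubes, %s spatial, %d channels",
             config.simulation.n_classes, config.simulation.cubes_per_class,
             config.simulation.spatial, config.simulation.axis.n_channels)
    dataset = simulate_dataset(config.simulation)

    log.info("band selection on the full dataset (reporting only)")
    selection_report(dataset, config.selection).to_csv(out / "selection_report.csv",
                                                       index=False)

    log.info("method comparison: %d methods x %d runs",
             len(config.selection), config.n_runs)
    table, records = run_comparison(dataset, config.selection, config.n_runs,
                                    config.training)
    table.to_csv(out / "comparison_table.csv", index=False)

    curves = []
    for method, runs in records.items():
        for run_idx, r in enumerate(runs):
            frame = r["history"].as_frame()
            frame.insert(0, "method", method)
            frame.insert(1, "run", run_idx)
            curves.append(frame.drop(columns=["epoch_seconds"]))
    pd.concat(curves, ignore_index=True).to_csv(out / "epoch_curves.csv", index=False)
    _plot_curves(records, out / "accuracy_curves.png")

    manifest = {
        "simulation": _as_jsonable(config.simulation),
        "selection": [dataclasses.asdict(s) for s in config.selection],
        "training": dataclasses.asdict(config.training),
        "n_runs": config.n_runs,
        "master_seed": config.training.seed,
        "run_seeds": [config.training.seed + r for r in range(config.n_runs)],
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("bundle written to %s", out)
    return out


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
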