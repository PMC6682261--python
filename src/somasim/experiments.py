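"""Named experiments that regenerate the package's figure-level outputs.

Each experiment is a fixed parameterization of one of the models:

- ``figure1`` — the analytic growth table r**n across a lethality grid
  for unprotected populations at several resource levels and for fully
  and partially protected populations.
- ``figure5a``..``figure5d`` — single lattice runs under the four
  canonical conditions (stem cells alone; moderately protective
  long-lived soma; fully protective short-lived soma; fully protective
  long-lived soma).
- ``figure6`` — the protection sweep: high-lethality occupancy as the
  somatic protection factor 1 - beta rises from 0 to 1, ten runs per
  value.
- ``percolation`` — transparency curves and threshold estimates for the
  one-to-one, layered and long-range blanket topologies.

Every experiment writes its tables plus a manifest JSON recording the
output files, the configuration hash, the seed and the package version,
so a rerun with the same manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from somasim import __version__
from somasim.config import config_hash, validate_config
from somasim.growth import figure_table
from somasim.lattice import SimConfig, grid_to_text, run, sweep_protection
from somasim.percolation import percolation_curve, threshold_estimate

__all__ = ["ExperimentSpec", "run_experiment", "EXPERIMENT_IDS", "FIGURE5_OVERRIDES"]

EXPERIMENT_IDS = (
    "figure1",
    "figure5a",
    "figure5b",
    "figure5c",
    "figure5d",
    "figure6",
    "percolation",
)

# Canonical lattice conditions: resource level, somatic-progeny
# probability, somatic exposure transmitted (beta), somatic resistance.
FIGURE5_OVERRIDES = {
    "figure5a": {"a": 1.0, "p_somatic": 0.0},
    "figure5b": {"a": 0.8, "p_somatic": 0.5, "beta_soma": 0.5, "soma_resistance": 0.5},
    "figure5c": {"a": 0.8, "p_somatic": 0.5, "beta_soma": 0.0, "soma_resistance": 0.2},
    "figure5d": {"a": 1.0, "p_somatic": 0.25, "beta_soma": 0.0, "soma_resistance": 0.5},
}

# Figure 6 sweep shares the somatic-progeny settings of the moderate
# condition; only beta_soma is varied by the sweep itself.
_FIGURE6_BASE = {"a": 0.8, "p_somatic": 0.5, "soma_resistance": 0.2}


@dataclass
class ExperimentSpec:
    """What to run, with which overrides, seed and output directory."""

    experiment: str
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | Path = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose one of {', '.join(EXPERIMENT_IDS)}"
            )


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run one named experiment and write its outputs plus a manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).
    """
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    summary: dict = {}
    cfg_hash = ""

    if spec.experiment == "figure1":
        settings = [
            ("a1.0_exposed", 1.0, 1.0, 1.0),
            ("a0.8_exposed", 0.8, 1.0, 1.0),
            ("a0.5_exposed", 0.5, 1.0, 1.0),
            ("a1.0_protected", 1.0, 1.0, 0.0),
            ("a1.0_partial", 1.0, 1.0, 0.4),
        ]
        n = int(spec.overrides.get("n", 10))
        table = figure_table(settings, n=n)
        path = out / "growth_table.tsv"
        _write_tsv(table, path)
        files.append(path.name)
        summary = {"n_cycles": n, "n_rows": len(table)}

    elif spec.experiment in FIGURE5_OVERRIDES:
        raw = {**FIGURE5_OVERRIDES[spec.experiment], **spec.overrides, "rng_seed": spec.seed}
        config = validate_config(raw)
        cfg_hash = config_hash(config)
        result = run(config)
        counts_path = out / "cycle_counts.tsv"
        _write_tsv(result.counts, counts_path)
        snap_path = out / "final_grid.txt"
        snap_path.write_text(grid_to_text(result.final_state) + "\n")
        files += [counts_path.name, snap_path.name]
        n_stem, n_soma = result.final_state.counts()
        summary = {
            "occupancy_high_b": result.occupancy_high_b,
            "n_stem": n_stem,
            "n_somatic": n_soma,
            "n_colonies": len(result.colonies),
        }

    elif spec.experiment == "figure6":
        raw = {**_FIGURE6_BASE, **spec.overrides, "rng_seed": spec.seed}
        runs_per_value = int(raw.pop("runs_per_value", 10))
        protection_values = raw.pop(
            "protection_values", [round(0.1 * i, 1) for i in range(11)]
        )
        config = validate_config(raw)
        cfg_hash = config_hash(config)
        table = sweep_protection(config, protection_values, runs_per_value)
        path = out / "protection_sweep.tsv"
        _write_tsv(table, path)
        files.append(path.name)
        means = table.groupby("protection")["occupancy_high_b"].mean()
        summary = {
            "protection_values": list(map(float, means.index)),
            "mean_occupancy_high_b": list(map(float, means.values)),
            "runs_per_value": runs_per_value,
        }

    elif spec.experiment == "percolation":
        sizes = spec.overrides.get("sizes", (6, 6, 6))
        replicates = int(spec.overrides.get("replicates", 200))
        grid = np.asarray(
            spec.overrides.get("edge_probs", np.linspace(0.0, 0.5, 26)), dtype=float
        )
        thresholds = {}
        for topology in ("one-to-one", "layered", "long-range"):
            curve = percolation_curve(
                *sizes,
                topology=topology,
                edge_probs=grid,
                replicates=replicates,
                seed=spec.seed,
            )
            path = out / f"curve_{topology.replace('-', '_')}.tsv"
            _write_tsv(curve.to_frame(), path)
            files.append(path.name)
            thr = threshold_estimate(curve)
            thresholds[topology] = thr
        summary = {"thresholds": thresholds, "replicates": replicates}

    manifest = {
        "experiment": spec.experiment,
        "files": files,
        "config_hash": cfg_hash,
        "seed": spec.seed,
        "overrides": _jsonable(spec.overrides),
        "version": __version__,
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return obj
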