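"""Serialization: trajectory/dataset CSV, config files, comparison plot.

Trajectory CSV dialect: '#'-prefixed comment header lines carrying the
model kind and the full parameter set (as a flat JSON mapping), then the
column header ``time_hpf,N_nM,V_nM,D_nM`` and data rows in I/O units
(nM, hpf) with a fixed decimal precision (default 4 places; a
full-precision mode exists for oracle comparisons).  ``V_nM`` is written as
0.0 for cold-start runs.  Times must be strictly increasing on read.

Dataset CSV dialect: the same comment-header scheme (plus sigma, seed,
model) followed by ``time_hpf,replicate,value`` rows, value in nM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import KineticParameters, ModelKind, M_PER_NM, S_PER_HPF
from .simulate import Trajectory
from .stochastic import SyntheticDataset

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "load_config",
    "plot_comparison",
]

TRAJECTORY_COLUMNS = ["time_hpf", "N_nM", "V_nM", "D_nM"]
DATASET_COLUMNS = ["time_hpf", "replicate", "value"]

#: Top-level keys accepted in a run configuration file.
CONFIG_KEYS = {
    "parameters",
    "model",
    "theta_nM",
    "grid_dt_s",
    "seed",
    "sigma",
    "n_replicates",
    "omega_L",
    "precision",
}


def _format(values: np.ndarray, precision: int | None) -> list:
    if precision is None:
        return [repr(float(v)) for v in values]
    return [f"{v:.{precision}f}" for v in values]


def write_trajectory_csv(
    traj: Trajectory, path: str | Path, precision: int | None = 4
) -> None:
    """Write a trajectory in the declared CSV dialect.

    ``precision`` is the number of decimal places in nM/hpf; ``None``
    writes full float precision (lossless round-trip).
    """
    path = Path(path)
    header = [
        f"# model={traj.model.value}",
        f"# params={traj.params.to_json()}",
        f"# precision={'full' if precision is None else precision}",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
        cols = [
            _format(traj.times_hpf, precision),
            _format(traj.N_nM, precision),
            _format(traj.V_nM, precision),
            _format(traj.D_nM, precision),
        ]
        for row in zip(*cols):
            fh.write(",".join(row) + "\n")


def _read_comment_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta, n_comment


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Parse a trajectory CSV back into a :class:`Trajectory`.

    The cumulative ledger fields are not stored in CSV and come back as
    ``None``; a ledger check on a round-tripped trajectory is a structural
    error by design.
    """
    path = Path(path)
    meta, n_comment = _read_comment_header(path)
    if "model" not in meta or "params" not in meta:
        raise ValueError(f"{path}: missing model/params comment header")
    frame = pd.read_csv(path, skiprows=n_comment, float_precision="round_trip")
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {TRAJECTORY_COLUMNS}, got {list(frame.columns)}"
        )
    times = frame["time_hpf"].to_numpy() * S_PER_HPF
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return Trajectory(
        model=ModelKind(meta["model"]),
        params=KineticParameters.from_json(meta["params"]),
        times=times,
        N=frame["N_nM"].to_numpy() * M_PER_NM,
        V=frame["V_nM"].to_numpy() * M_PER_NM,
        D=frame["D_nM"].to_numpy() * M_PER_NM,
    )


def write_dataset_csv(
    dataset: SyntheticDataset, path: str | Path, precision: int | None = None
) -> None:
    """Write a synthetic dataset as long-format CSV (value in nM)."""
    path = Path(path)
    header = [
        f"# model={dataset.model.value}",
        f"# params={dataset.true_params.to_json()}",
        f"# sigma={dataset.sigma!r}",
        f"# seed={dataset.seed}",
    ]
    n_reps, n_times = dataset.observations.shape
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(",".join(DATASET_COLUMNS) + "\n")
        times_hpf = _format(dataset.times / S_PER_HPF, precision)
        values_nM = dataset.observations_nM
        for rep in range(n_reps):
            row_vals = _format(values_nM[rep], precision)
            for j in range(n_times):
                fh.write(f"{times_hpf[j]},{rep},{row_vals[j]}\n")


def read_dataset_csv(path: str | Path) -> SyntheticDataset:
    """Parse a synthetic-dataset CSV back into a :class:`SyntheticDataset`."""
    path = Path(path)
    meta, n_comment = _read_comment_header(path)
    for key in ("model", "params", "sigma", "seed"):
        if key not in meta:
            raise ValueError(f"{path}: missing {key!r} comment header")
    frame = pd.read_csv(path, skiprows=n_comment, float_precision="round_trip")
    if list(frame.columns) != DATASET_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {DATASET_COLUMNS}, got {list(frame.columns)}"
        )
    wide = frame.pivot(index="replicate", columns="time_hpf", values="value")
    wide = wide.sort_index().sort_index(axis=1)
    return SyntheticDataset(
        times=wide.columns.to_numpy(dtype=float) * S_PER_HPF,
        observations=wide.to_numpy(dtype=float) * M_PER_NM,
        sigma=float(meta["sigma"]),
        true_params=KineticParameters.from_json(meta["params"]),
        seed=int(meta["seed"]),
        model=ModelKind(meta["model"]),
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(config) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "parameters" in config:
        # validate eagerly so a bad file fails at load, not mid-run
        KineticParameters.from_dict(config["parameters"])
    return config


def plot_comparison(
    primed: Trajectory, cold: Trajectory, path: str | Path
) -> None:
    """Plot both dimer curves vs time with the production window marked.

    Primed heterodimer in blue, cold-start homodimer in red; dotted
    vertical lines at the window boundaries (4 and 6 hpf under defaults).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(primed.times_hpf, primed.D_nM, color="tab:blue", label="Vg1-Nodal heterodimer (primed)")
    ax.plot(cold.times_hpf, cold.D_nM, color="tab:red", label="Nodal homodimer (cold-start)")
    for t in (primed.params.t_on, primed.params.t_off):
        ax.axvline(t / S_PER_HPF, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel("time (hpf)")
    ax.set_ylabel("dimer concentration (nM)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
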