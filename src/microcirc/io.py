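"""Circuit definition files, result bundles and reproducible experiment runs.

Circuits are stored as YAML with explicit units:

    version: 1
    populations: [E, P, S, V]
    fi:
      E: {v_th: -50.0, v_r: -60.0, v: 1.0, tau_m_s: 0.028, g_l_nS: 6.25, v_l: -70.0}
      ...
    W_pAs:            # row-major, rows = targets
      - [2.42, -0.33, -0.80, 0.0]
      ...
    baseline_rates_Hz: [1, 10, 3, 2]   # optional; calibrates the background

Tabular outputs are CSV, structured outputs JSON; every experiment
bundle records its seed and a hash of the resolved configuration so a
rerun can be checked bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .circuit import Circuit, calibrated
from .fi import FICurve

__all__ = [
    "circuit_to_dict",
    "circuit_from_dict",
    "load_circuit",
    "save_circuit",
    "packaged_config",
    "config_hash",
    "run_experiment",
]

_FI_KEYS = {"v_th": "v_th", "v_r": "v_r", "v": "v", "tau_m_s": "tau_m",
            "g_l_nS": "g_l", "v_l": "v_l"}


def circuit_to_dict(c: Circuit, baseline_rates=None) -> dict:
    doc = {
        "version": 1,
        "populations": list(c.populations),
        "fi": {
            lbl: {yk: getattr(p, ak) for yk, ak in _FI_KEYS.items()}
            for lbl, p in zip(c.populations, c.fi)
        },
        "W_pAs": [[float(x) for x in row] for row in c.W],
        "tau_r_s": c.tau_r,
    }
    if baseline_rates is not None:
        doc["baseline_rates_Hz"] = [float(r) for r in baseline_rates]
    elif c.i_bkg is not None:
        doc["i_bkg_pA"] = [float(x) for x in c.i_bkg]
    return doc


def circuit_from_dict(doc: dict) -> Circuit:
    if doc.get("version") != 1:
        raise ValueError("unsupported or missing circuit file version")
    pops = tuple(doc["populations"])
    fi = tuple(
        FICurve(**{ak: float(doc["fi"][lbl][yk]) for yk, ak in _FI_KEYS.items()})
        for lbl in pops
    )
    c = Circuit(
        populations=pops,
        fi=fi,
        W=np.array(doc["W_pAs"], dtype=float),
        tau_r=float(doc.get("tau_r_s", 0.002)),
        i_bkg=np.array(doc["i_bkg_pA"], dtype=float) if "i_bkg_pA" in doc else None,
    )
    if "baseline_rates_Hz" in doc:
        c = calibrated(c, np.array(doc["baseline_rates_Hz"], dtype=float))
    return c


def load_circuit(path) -> Circuit:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"circuit file not found: {path}")
    with open(path) as fh:
        return circuit_from_dict(yaml.safe_load(fh))


def save_circuit(c: Circuit, path, baseline_rates=None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(circuit_to_dict(c, baseline_rates), fh, sort_keys=False)


def packaged_config(name: str) -> Path:
    """Path of a circuit definition shipped with the package
    ("generic" or "v1")."""
    from importlib.resources import files

    p = files("microcirc") / "configs" / f"{name}.yaml"
    return Path(str(p))


def config_hash(doc: dict) -> str:
    """Stable hash of a resolved configuration document."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: dict, outdir) -> dict:
    """Run one configured experiment and write a deterministic bundle.

    ``config`` needs ``experiment`` ("calibrate" or "simulate"),
    ``circuit`` (path) and experiment-specific options; results land in
    ``outdir`` as CSV/JSON next to a ``run.json`` log echoing the
    configuration, its hash and the package version.  Reruns of the same
    config produce identical files.
    """
    from . import __version__
    from .circuit import InputSchedule, calibrate_background, simulate, steady_state

    outdir = Path(outdir)
    kind = config.get("experiment")
    circuit_path = Path(config["circuit"])
    c = load_circuit(circuit_path)  # raises before any output is written
    outdir.mkdir(parents=True, exist_ok=True)

    log = {
        "experiment": kind,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        "config_hash": config_hash({k: str(v) for k, v in config.items()}),
        "version": __version__,
        "seed": config.get("seed"),
    }
    if kind == "calibrate":
        targets = np.asarray(config["targets"], dtype=float)
        i_bkg = calibrate_background(c.with_background(np.zeros(c.n_pop)), targets)
        result = {f"i_bkg_{lbl}_pA": float(v) for lbl, v in zip(c.populations, i_bkg)}
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
        log["outputs"] = ["calibration.json"]
    elif kind == "simulate":
        step = np.asarray(config.get("step_pA", [0, 0, 0, 0]), dtype=float)
        T = float(config.get("T", 0.5))
        dt = float(config.get("dt", 1e-4))
        r0 = steady_state(c, 0.0, r0=np.ones(c.n_pop))
        traj = simulate(c, InputSchedule.constant(step), r0=r0, T=T, dt=dt)
        traj.write_csv(outdir / "trajectory.csv")
        log["outputs"] = ["trajectory.csv"]
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    with open(outdir / "run.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
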