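"""Scenario configuration, reproducible runs and file I/O.

A scenario is described by a YAML mapping (or an equivalent dict) and runs
deterministically given its seed.  Outputs are plain text: observables as
CSV with ``#`` header metadata, the final structure as extended XYZ
(N-terminal beads as element ``N``, coiled-coil beads as ``C``, one cluster
id column), and a JSON manifest recording every parameter.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gcmc import ExchangeRegion
from .geometry import Cluster, ModelParams
from .observables import measure_kd
from .rates import build_ode_system, estimate_diffusive_rates, integrate
from .reactions import AffinityCalibration, EncounterWindow, calibrate_rates
from .scaffolds import Scaffold
from .simulate import Simulation

SCENARIOS = ("bulk-bd", "bulk-rates", "cylinder", "sphere", "semisphere", "pair-kd")


class ConfigError(ValueError):
    """Configuration violates the scenario schema."""


@dataclass
class ScenarioResult:
    config: dict
    tables: dict[str, pd.DataFrame]
    manifest: dict
    simulation: Simulation | None = None


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _reaction_from(cfg: dict, delta_t_default: float = 2.0) -> tuple:
    rc = dict(cfg.get("reaction", {}))
    wc = dict(rc.pop("window", {}))
    window = EncounterWindow(**wc)
    calib = AffinityCalibration(kd_nn=rc.pop("kd_nn", 60.0), kd_cc=rc.pop("kd_cc", 1.0))
    params = calibrate_rates(
        calib,
        window,
        k_a=rc.pop("k_a", 1.0),
        delta_t=rc.pop("delta_t", delta_t_default),
        ring_energy=rc.pop("ring_energy", 0.0),
    )
    if rc:
        raise ConfigError(f"unknown reaction keys: {sorted(rc)}")
    return params, calib


def _validate(cfg: dict) -> str:
    scenario = cfg.get("scenario")
    if scenario not in SCENARIOS:
        raise ConfigError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    problems = []
    bd = scenario != "bulk-rates"
    if bd and "seed" not in cfg:
        problems.append("BD scenarios require an explicit seed")
    if scenario == "cylinder" and "exchange" not in cfg:
        problems.append("cylinder scenario requires an exchange (reservoir) block")
    if scenario in ("sphere", "semisphere") and "n_initial" not in cfg:
        problems.append("sphere/semisphere scenarios require n_initial")
    if scenario == "bulk-rates" and "concentration" not in cfg:
        problems.append("bulk-rates requires a concentration (μM)")
    if problems:
        raise ConfigError("; ".join(problems))
    return scenario


def run_scenario(cfg: dict, out_prefix: str | Path | None = None) -> ScenarioResult:
    """Run one scenario deterministically and optionally write its outputs."""
    scenario = _validate(cfg)
    t_wall = _time.time()
    model = ModelParams(**cfg.get("model", {}))
    tables: dict[str, pd.DataFrame] = {}
    sim = None

    if scenario == "bulk-rates":
        window = EncounterWindow(**cfg.get("reaction", {}).get("window", {}))
        calib = AffinityCalibration(kd_nn=cfg.get("reaction", {}).get("kd_nn", 60.0))
        rm = estimate_diffusive_rates(model, window, calib, seed=cfg.get("seed", 2024))
        system = build_ode_system(rm, cfg.get("ring_energy", 0.0), cfg["concentration"])
        pops = integrate(system, t_end=cfg.get("t_end"))
        df = pd.DataFrame(pops.concentrations, columns=[f"c{i}" for i in range(1, 10)] + ["c_ring"])
        df.insert(0, "time_s", pops.times)
        for i, col in enumerate(pops.relative_populations.T):
            df[f"p{i + 1}" if i < 9 else "p_ring"] = col
        tables["populations"] = df
    else:
        reaction, calib = _reaction_from(cfg)
        box = tuple(float(v) for v in cfg.get("box", (200.0, 200.0, 60.0)))
        sc_cfg = cfg.get("scaffold")
        scaffold = None
        if scenario in ("cylinder", "sphere", "semisphere"):
            sc_cfg = dict(sc_cfg or {})
            sc_cfg.setdefault("shape", scenario)
            center = sc_cfg.pop(
                "center",
                [box[0] / 2, box[1] / 2, 0.0 if scenario != "sphere" else box[2] / 2],
            )
            scaffold = Scaffold(center=np.asarray(center, float), **sc_cfg)
        exchange = None
        if "exchange" in cfg:
            exchange = ExchangeRegion(**cfg["exchange"])
        sim = Simulation(
            reaction,
            box,
            params=model,
            scaffold=scaffold,
            exchange=exchange,
            wall_z=(scenario == "semisphere"),
            reactions_on=cfg.get("reactions_on", True),
            capacity=cfg.get("capacity"),
            seed=int(cfg["seed"]),
        )
        n_initial = int(cfg.get("n_initial", 2 if scenario == "pair-kd" else 0))
        achieved = sim.place_random_homodimers(n_initial) if n_initial else 0.0
        sim.run(int(cfg.get("n_steps", 1_000_000)), int(cfg.get("record_every", 1000)))
        times, counts, occ = sim.record_arrays()
        df = pd.DataFrame(counts, columns=[f"n{i}" for i in range(1, 10)] + ["n_ring"])
        df.insert(0, "time_ns", times)
        df["occupancy"] = occ
        tables["observables"] = df
        tables["observables"].attrs["initial_concentration_uM"] = achieved
        if scenario == "pair-kd":
            bound = counts[:, 1:].sum(axis=1) > 0
            kd, (lo, hi) = measure_kd(bound, float(np.prod(box)))
            tables["kd"] = pd.DataFrame(
                {"kd_um": [kd], "ci_lo": [lo], "ci_hi": [hi], "kd_target": [calib.kd_nn]}
            )

    manifest = {
        "scenario": scenario,
        "config": _jsonable(cfg),
        "package_version": __version__,
        "wall_time_s": round(_time.time() - t_wall, 3),
    }
    result = ScenarioResult(cfg, tables, manifest, sim)
    if out_prefix is not None:
        write_outputs(result, out_prefix)
    return result


def _jsonable(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_outputs(result: ScenarioResult, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in result.tables.items():
        path = prefix.with_name(prefix.name + f"_{name}.csv")
        with open(path, "w") as fh:
            fh.write(f"# cartwheel {__version__} scenario={result.manifest['scenario']}\n")
            for k, v in df.attrs.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, index=False)
        written.append(path)
    mpath = prefix.with_name(prefix.name + "_manifest.json")
    with open(mpath, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    if result.simulation is not None:
        xpath = prefix.with_name(prefix.name + "_final.xyz")
        write_xyz(result.simulation.clusters(), xpath, comment="final state")
        written.append(xpath)
    return written


def write_xyz(clusters: list[Cluster], path: str | Path, comment: str = "") -> None:
    """Extended-XYZ dump: N-terminal beads as N, coiled-coil beads as C,
    with a per-bead cluster-id column."""
    lines = []
    n_total = sum(len(c.model.beads) * c.n_members for c in clusters)
    lines.append(str(n_total))
    lines.append(
        f'Properties=species:S:1:pos:R:3:cluster:I:1 Comment="{comment}"'
    )
    for c in clusters:
        pts, _ = c.world_beads()
        kinds = [b.kind for b in c.model.beads] * c.n_members
        for p, kind in zip(pts, kinds):
            el = "N" if kind == "N-term" else "C"
            lines.append(f"{el} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {c.id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_counts(path: str | Path) -> tuple[int, int]:
    """(bead count, cluster count) from an extended-XYZ file."""
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0])
    ids = {line.split()[-1] for line in text[2 : 2 + n]}
    return n, len(ids)
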