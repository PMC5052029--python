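"""End-to-end synthetic dataset generation with ground-truth manifests.

Each generated trial runs the full forward chain -- stimulus construction,
membrane integration, calcium/fluorescence dynamics, scan rendering -- and
records the generating parameters (seed, condition, true onset, true decay
constant, true dF/F peak, response flag) in one manifest entry per emitted
file set. Reruns with the same seed produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from glica.io import write_trace
from glica.stim_waveforms import QuantalKinetics, build_psp_train
from glica.synthetic_data.fluorescence import (CalciumModel,
                                               simulate_calcium_fluorescence)
from glica.synthetic_data.imaging import ImagingGeometry, render_linescan
from glica.synthetic_data.membrane import default_cell, simulate_membrane
from glica.trace import Trace

MANIFEST_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic trial."""

    trial_id: str
    seed: int
    condition: str
    stimulus: dict
    is_response: bool
    onset_s: float | None
    tau_decay_s: float
    dff_peak: float
    files: dict  # role -> relative path

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


DEFAULT_CONFIG: dict = {
    "n_cells": 3,
    "conditions": ["control", "4AP"],
    "R_in": 250.0,
    "C_m": 20.0,
    "n_psp": 10,
    "rate_hz": 100.0,
    "Q": 600,
    "pre_s": 0.5,
    "post_s": 6.5,
    "tau_extrusion": 3.16,
    "line_rate_hz": 200.0,
    "photon_budget": 100.0,
    "background_offset": 10.0,
    "n_dark_lines": 20,
}


def _pad(tr: Trace, pre_s: float, post_s: float) -> Trace:
    n_pre = int(round(pre_s / tr.dt))
    n_post = int(round(post_s / tr.dt))
    v = np.concatenate([np.zeros(n_pre), tr.values, np.zeros(n_post)])
    return Trace(values=v, dt=tr.dt, units=tr.units)


def generate_trial(condition: str, cfg: dict, seed: int) -> dict:
    """Run the forward chain for one trial; returns arrays plus truth fields."""
    kin = QuantalKinetics()
    stim = build_psp_train(kin, n=cfg["n_psp"], rate=cfg["rate_hz"],
                           Q=cfg["Q"])
    stim = _pad(stim, cfg["pre_s"], cfg["post_s"])
    cell = default_cell(condition, R_in=cfg["R_in"], C_m=cfg["C_m"])
    V, i_ca = simulate_membrane(cell, stim)
    model = CalciumModel(tau_extrusion=cfg["tau_extrusion"])
    _, F = simulate_calcium_fluorescence(model, i_ca)
    geom = ImagingGeometry(line_period=1.0 / cfg["line_rate_hz"],
                           photon_budget=cfg["photon_budget"],
                           background_offset=cfg["background_offset"],
                           n_dark_lines=cfg["n_dark_lines"])
    total_s = F.duration
    n_lines = geom.n_dark_lines + int(total_s / geom.line_period)
    cols = {geom.n_pixels // 2 + k: F for k in (-1, 0, 1)}
    scans = render_linescan(cols, geom, n_lines=n_lines,
                            f_rest=model.f_rest, seed=seed)
    dff_true = float((F.values.max() - model.f_rest) / model.f_rest)
    return {
        "stim": stim, "V": V, "F": F, "scans": scans, "geom": geom,
        "onset_s": cfg["pre_s"],
        "tau_decay_s": cfg["tau_extrusion"],
        "dff_peak": dff_true,
        # declared truth: a trial counts as a generated responder when the
        # noiseless forward model exceeds 2% dF/F
        "is_response": dff_true > 0.02,
    }


def generate_dataset(config: dict | None, seed: int,
                     out_dir: str | Path, force: bool = False) -> Path:
    """Generate trial files plus a versioned ground-truth manifest JSON.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns the manifest path.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)

    root_rng = np.random.default_rng(seed)
    entries: list[GroundTruth] = []
    for ci in range(cfg["n_cells"]):
        for condition in cfg["conditions"]:
            trial_seed = int(root_rng.integers(0, 2**31 - 1))
            trial_id = f"cell{ci:02d}_{condition}"
            res = generate_trial(condition, cfg, trial_seed)
            files = {}
            for role, tr in (("stim", res["stim"]), ("voltage", res["V"])):
                rel = f"{trial_id}_{role}.csv"
                write_trace(out / rel, tr)
                files[role] = rel
            for chan, ls in res["scans"].items():
                rel = f"{trial_id}_{chan}.tif"
                tifffile.imwrite(out / rel,
                                 ls.pixels.astype(np.uint16))
                files[chan] = rel
            entries.append(GroundTruth(
                trial_id=trial_id, seed=trial_seed, condition=condition,
                stimulus={"n_psp": cfg["n_psp"], "rate_hz": cfg["rate_hz"],
                          "Q": cfg["Q"]},
                is_response=res["is_response"], onset_s=res["onset_s"],
                tau_decay_s=res["tau_decay_s"], dff_peak=res["dff_peak"],
                files=files))

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "seed": seed,
        "config": cfg,
        "trials": [e.to_json() for e in entries],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
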