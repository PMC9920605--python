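"""Persistence of realisation ensembles.

One ensemble goes into a single ``.npz`` array container: stacked windowed
trajectories plus a JSON-encoded metadata blob (model parameters, bubble
spec, seeds), so a saved ensemble can be re-loaded and fed to the
correlation/fitting layers exactly like a freshly computed one.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .dynamics import TrajectoryRecord
from .model import ModelParameters
from .protocol import BubbleSpec, RealisationResult

__all__ = ["save_ensemble", "load_ensemble"]


def save_ensemble(path: str | Path, results: Sequence[RealisationResult]) -> None:
    if not results:
        raise ValueError("nothing to save")
    r0 = results[0]
    meta = {
        "params": {k: getattr(r0.params, k) for k in ("D", "a", "K", "rho", "b", "mass", "sequence")},
        "spec": {"h": r0.spec.h, "w": r0.spec.w, "c": r0.spec.c},
        "energy_per_site": r0.energy_per_site,
        "window": list(r0.record.window),
        "n_sites": r0.record.n_sites,
        "seeds": [r.seed for r in results],
        "lambdas": [r.rescale_lambda for r in results],
        "pre_insertion_mean_y": [r.pre_insertion_mean_y for r in results],
    }
    np.savez_compressed(
        Path(path),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        times=r0.record.times,
        y_window=np.stack([r.record.y_window for r in results]),
        e_window=np.stack([r.record.e_window for r in results]),
        H_series=np.stack([r.record.H_series for r in results]),
        ke_series=np.stack([r.record.ke_series for r in results]),
        y_mean=np.stack([r.record.y_mean for r in results]),
    )


def load_ensemble(path: str | Path) -> list[RealisationResult]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        times = data["times"]
        blocks = {k: data[k] for k in ("y_window", "e_window", "H_series", "ke_series", "y_mean")}
    params = ModelParameters(**meta["params"])
    spec = BubbleSpec(**meta["spec"])
    window = tuple(meta["window"])
    out = []
    for i, seed in enumerate(meta["seeds"]):
        rec = TrajectoryRecord(times=times.copy(), y_window=blocks["y_window"][i],
                               e_window=blocks["e_window"][i], H_series=blocks["H_series"][i],
                               ke_series=blocks["ke_series"][i], y_mean=blocks["y_mean"][i],
                               window=window, n_sites=meta["n_sites"])
        out.append(RealisationResult(
            seed=seed, record=rec, y0_window=rec.y_window[0].copy(),
            e0_window=rec.e_window[0].copy(),
            pre_insertion_mean_y=meta["pre_insertion_mean_y"][i],
            spec=spec, params=params, energy_per_site=meta["energy_per_site"],
            rescale_lambda=meta["lambdas"][i]))
    return out
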