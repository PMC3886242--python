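"""Plain-text session storage: frames as CSV, ground truth and reports as JSON.

A stored session is a directory holding

* ``frames.csv`` — long table ``(rep_index, sample_index, time_s, real, imag)``
* ``truth.json`` — acquisition/design metadata plus the simulator ground truth
* optional products: ``t2_series.csv``, ``t_curve.csv``, ``l_optim.json``,
  ``feedback.csv``, ``metrics.json``, ``provenance.json``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AcquisitionParams, FidFrame, SessionDesign, TruthRecord

__all__ = [
    "write_session",
    "read_session",
    "write_json",
    "read_json",
]

FRAMES_CSV = "frames.csv"
TRUTH_JSON = "truth.json"


def write_session(
    out_dir: str | Path,
    frames: Sequence[FidFrame],
    design: SessionDesign,
    acq: AcquisitionParams,
    truth: TruthRecord | None = None,
) -> Path:
    """Write a session to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_pts = frames[0].n_points
    rep = np.repeat(np.arange(len(frames)), n_pts)
    sample = np.tile(np.arange(n_pts), len(frames))
    t = np.tile(frames[0].times(), len(frames))
    data = np.concatenate([f.samples for f in frames])
    pd.DataFrame(
        {
            "rep_index": rep,
            "sample_index": sample,
            "time_s": t,
            "real": data.real,
            "imag": data.imag,
        }
    ).to_csv(out / FRAMES_CSV, index=False)

    meta: dict = {
        "acquisition": {
            "bandwidth": acq.bandwidth,
            "n_points": acq.n_points,
            "te": acq.te,
        },
        "design": {
            "tr": design.tr,
            "n_reps": design.n_reps,
            "n_discard": design.n_discard,
            "block_len": design.block_len,
            "labels": design.labels.tolist(),
        },
    }
    if truth is not None:
        meta["truth"] = {
            "true_t2star": truth.true_t2star.tolist(),
            "spike_positions": truth.spike_positions.tolist(),
            "labels": truth.labels.tolist(),
            "center_freq": truth.center_freq.tolist(),
        }
    write_json(out / TRUTH_JSON, meta)
    return out


def read_session(
    session_dir: str | Path,
) -> tuple[list[FidFrame], SessionDesign, AcquisitionParams, TruthRecord | None]:
    """Read a stored session back into memory."""
    d = Path(session_dir)
    meta = read_json(d / TRUTH_JSON)
    acq = AcquisitionParams(**meta["acquisition"])
    dmeta = dict(meta["design"])
    dmeta["labels"] = np.asarray(dmeta["labels"])
    design = SessionDesign(**dmeta)

    df = pd.read_csv(d / FRAMES_CSV)
    frames = []
    for _, grp in df.groupby("rep_index", sort=True):
        samples = grp["real"].to_numpy() + 1j * grp["imag"].to_numpy()
        frames.append(FidFrame(samples=samples, bandwidth=acq.bandwidth, te=acq.te))

    truth = None
    if "truth" in meta:
        t = meta["truth"]
        truth = TruthRecord(
            true_t2star=np.asarray(t["true_t2star"]),
            spike_positions=np.asarray(t["spike_positions"], dtype=int),
            labels=np.asarray(t["labels"]),
            center_freq=np.asarray(t["center_freq"]),
        )
    return frames, design, acq, truth


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
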