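"""Readers and writers for the package's external formats.

Events go out as BIDS-style ``events.tsv`` (onset, duration, trial_type plus
behavioral columns); simulated time series can be written either as a plain
TSV matrix or as a 4-D NIfTI image with the ROI's voxels unraveled onto a
line of the image grid; ground truth (latent fidelity, direction patterns)
goes in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_events_tsv(dataset, path) -> Path:
    """Write a session's events as a BIDS-style TSV."""
    path = Path(path)
    ev = dataset.events.copy()
    g = dataset.trials.get("g")
    if g is not None and len(g) == len(ev):
        ev["fidelity"] = np.asarray(g)
    ev.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries_tsv(dataset, path) -> Path:
    """Concatenated voxels x volumes matrix as TSV (volumes in columns)."""
    path = Path(path)
    pd.DataFrame(dataset.concatenated()).to_csv(path, sep="\t", index=False,
                                                header=False,
                                                float_format="%.6g")
    return path


def write_timeseries_nifti(dataset, path) -> Path:
    """Write each run's series into one 4-D NIfTI, voxels along the x axis."""
    import nibabel as nib

    path = Path(path)
    data = dataset.concatenated()                     # voxels x volumes
    img = nib.Nifti1Image(
        data[:, None, None, :].astype(np.float32), affine=np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr))
    nib.save(img, str(path))
    return path


def read_timeseries_nifti(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    return arr.reshape(-1, arr.shape[-1])


def write_ground_truth_json(dataset, path) -> Path:
    """Latent fidelity and ROI patterns as a JSON sidecar."""
    path = Path(path)
    payload = {
        "task_variant": dataset.task_variant,
        "tr": dataset.tr,
        "seed": dataset.seed,
        "fidelity": [float(v) for v in dataset.trials["g"]],
        "roi": {
            "n_voxels": dataset.roi.n_voxels,
            "selectivity": dataset.roi.selectivity,
            "mu": dataset.roi.mu.tolist(),
            "p_cw": dataset.roi.p_cw.tolist(),
            "p_ccw": dataset.roi.p_ccw.tolist(),
        },
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_staircase_trace(staircase, path) -> Path:
    """Staircase history (trial, intensity, response, ML threshold) as CSV."""
    path = Path(path)
    staircase.trace().to_csv(path, index=False)
    return path
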