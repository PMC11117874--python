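"""On-disk formats: the HDF5 epoch container and CSV side outputs.

The epoch container is a minimal hierarchical file holding ``/data``
(trials x channels x samples, float64), ``/labels`` (int) and the
attributes ``fs``, ``t0`` and optionally ``channel_names``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import TrialSet

__all__ = [
    "save_trialset",
    "load_trialset",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_regression_bench",
]


def save_trialset(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data.astype(np.float64))
        f.create_dataset("labels", data=np.asarray(trials.labels, dtype=np.int64))
        f.attrs["fs"] = float(trials.fs)
        f.attrs["t0"] = float(trials.t0)
        if trials.channel_names is not None:
            f.attrs["channel_names"] = [str(c) for c in trials.channel_names]


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("channel_names")
        return TrialSet(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs.get("t0", 0.0)),
            channel_names=None if names is None else [str(c) for c in names],
        )


def write_feature_matrix(prefix, X: np.ndarray, columns: list[dict],
                         y=None) -> None:
    """Write the design matrix as CSV with a sidecar JSON of metadata."""
    prefix = Path(prefix)
    names = [f"b{c['band']}_e{c['i']}_{c['j']}" for c in columns]
    pd.DataFrame(X, columns=names).to_csv(prefix.with_suffix(".csv"), index=False)
    meta = {"columns": columns, "n": int(X.shape[0]), "p": int(X.shape[1])}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if y is not None:
        pd.DataFrame({"y": np.asarray(y)}).to_csv(
            prefix.parent / (prefix.name + "_y.csv"), index=False
        )


def read_feature_matrix(prefix):
    prefix = Path(prefix)
    X = pd.read_csv(prefix.with_suffix(".csv")).to_numpy()
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return X, meta["columns"]


def write_regression_bench(outdir, X, y, beta_true) -> None:
    """CSV triplet (X, y, beta_true) for a linear-model bench."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(X).to_csv(outdir / "X.csv", index=False)
    pd.DataFrame({"y": y}).to_csv(outdir / "y.csv", index=False)
    pd.DataFrame({"beta_true": beta_true}).to_csv(outdir / "beta_true.csv", index=False)
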