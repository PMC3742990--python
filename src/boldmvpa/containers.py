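"""In-memory containers for BOLD time series and their file round trips.

A :class:`TimeSeries` holds one scanning run as a dense ``voxels x timepoints``
array sampled every ``tr_seconds``.  Multi-run sessions are plain lists of
TimeSeries.  Serialization targets an HDF5 layout (one group per run) and,
for volumetric input, NIfTI 4-D images read through a boolean voxel mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "TimeSeries",
    "save_timeseries",
    "read_timeseries",
    "read_nifti_timeseries",
]


@dataclass
class TimeSeries:
    """One run of BOLD data: ``data[v, t]`` in acquisition order.

    Parameters
    ----------
    data : ndarray, shape (n_voxels, n_timepoints)
        Signal values; units depend on the processing stage (raw scanner
        units or percent signal change).
    tr_seconds : float
        Sampling interval (repetition time).
    run : int
        Zero-based run index within the session.
    provenance : list of str
        Processing steps applied so far, oldest first.
    """

    data: np.ndarray
    tr_seconds: float
    run: int = 0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("TimeSeries.data must be 2-D (voxels x timepoints)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds

    def with_data(self, data: np.ndarray, step: str | None = None) -> "TimeSeries":
        """Copy of this run with new data and an optional provenance entry."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return TimeSeries(data=data, tr_seconds=self.tr_seconds, run=self.run,
                          provenance=prov)


def save_timeseries(runs: list[TimeSeries], path) -> None:
    """Write a list of runs to one HDF5 file (group ``run###`` per run)."""
    with h5py.File(path, "w") as f:
        for ts in runs:
            g = f.create_group(f"run{ts.run:03d}")
            g.create_dataset("data", data=ts.data)
            g.attrs["tr_seconds"] = ts.tr_seconds
            g.attrs["run"] = ts.run
            g.attrs["provenance"] = json.dumps(ts.provenance)


def read_timeseries(path) -> list[TimeSeries]:
    """Read runs written by :func:`save_timeseries`, sorted by run index."""
    runs = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            if "tr_seconds" not in g.attrs:
                raise ValueError(f"group {name!r} has no tr_seconds attribute")
            runs.append(TimeSeries(
                data=g["data"][()],
                tr_seconds=float(g.attrs["tr_seconds"]),
                run=int(g.attrs["run"]),
                provenance=json.loads(g.attrs.get("provenance", "[]")),
            ))
    runs.sort(key=lambda ts: ts.run)
    return runs


def read_nifti_timeseries(path, mask, tr_seconds: float | None = None,
                          run: int = 0) -> TimeSeries:
    """Read a 4-D NIfTI volume into a TimeSeries through a voxel mask.

    Voxel order is the C-order scan of the nonzero mask entries; this order is
    stable and must be used for any per-voxel coordinate tables supplied
    alongside the image.

    Parameters
    ----------
    mask : ndarray of bool or path to a 3-D NIfTI mask image.
    tr_seconds : optional explicit TR; if None it is taken from the header and
        an error is raised when the header does not record one.
    """
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D image, got {img.ndim}-D")
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
        if not np.isfinite(tr_seconds) or tr_seconds <= 0:
            raise ValueError(
                "NIfTI header does not record a TR; pass tr_seconds explicitly")
    if not isinstance(mask, np.ndarray):
        mask = np.asanyarray(nib.load(str(mask)).dataobj)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {img.shape[:3]}")
    vol = np.asanyarray(img.dataobj)
    data = vol[mask, :].astype(float)  # C-order scan of mask voxels
    return TimeSeries(data=data, tr_seconds=tr_seconds, run=run,
                      provenance=[f"nifti:{path}"])
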