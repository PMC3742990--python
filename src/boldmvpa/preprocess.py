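"""Temporal preprocessing: percent signal change and high-pass filtering.

The high-pass filter removes the discrete-cosine components of each voxel's
series whose frequency falls below the cutoff (including DC).  Because the
DCT basis is orthogonal this is a zero-phase projection with no edge
transients: sub-cutoff components are annihilated, supra-cutoff components
pass essentially unchanged, and the operation is idempotent and linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct

from .containers import TimeSeries

__all__ = ["PreprocessConfig", "highpass", "highpass_array",
           "percent_signal_change", "preprocess_run"]


def highpass_array(data: np.ndarray, tr_seconds: float,
                   cutoff_hz: float) -> np.ndarray:
    """DCT high-pass projection of row-wise series (see :func:`highpass`).

    Also used to filter GLM design-matrix columns so that regressors and data
    live in the same subspace.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    coef = dct(data, type=2, axis=1, norm="ortho")
    freqs = np.arange(n) / (2.0 * n * tr_seconds)
    coef[:, freqs < cutoff_hz] = 0.0
    return idct(coef, type=2, axis=1, norm="ortho")


@dataclass
class PreprocessConfig:
    highpass_cutoff_hz: float = 0.025
    psc: bool = True

    def validate(self, tr_seconds: float) -> "PreprocessConfig":
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.highpass_cutoff_hz < nyquist):
            raise ValueError(
                f"cutoff {self.highpass_cutoff_hz} Hz outside (0, {nyquist}) Hz")
        return self


def highpass(ts: TimeSeries, cfg: PreprocessConfig | None = None) -> TimeSeries:
    """Remove slow components below the cutoff frequency (and the mean).

    DCT-II coefficient ``k`` of an ``N``-point series represents frequency
    ``k / (2 N TR)``; coefficients with frequency strictly below the cutoff
    are zeroed and the series reconstructed by the inverse transform.
    """
    cfg = (cfg or PreprocessConfig()).validate(ts.tr_seconds)
    n = ts.n_timepoints
    total = n * ts.tr_seconds
    if total < 1.0 / cfg.highpass_cutoff_hz:
        raise ValueError(
            f"run of {total}s is shorter than one cutoff period "
            f"({1.0 / cfg.highpass_cutoff_hz}s)")
    out = highpass_array(ts.data, ts.tr_seconds, cfg.highpass_cutoff_hz)
    return ts.with_data(out, step=f"highpass:{cfg.highpass_cutoff_hz}Hz")


def percent_signal_change(ts: TimeSeries) -> TimeSeries:
    """Convert to percent signal change: ``100 (x - mean) / mean`` per voxel.

    The baseline is the per-voxel temporal mean of the incoming (raw) series.
    Voxels with a non-positive baseline carry no interpretable percent scale;
    they are zeroed out and a warning names how many were excluded.
    """
    mean = ts.data.mean(axis=1, keepdims=True)
    bad = (mean <= 0).ravel()
    if bad.any():
        warnings.warn(f"{bad.sum()} voxel(s) with non-positive baseline "
                      "excluded from percent-signal-change conversion")
    safe = np.where(mean > 0, mean, 1.0)
    out = 100.0 * (ts.data - mean) / safe
    out[bad] = 0.0
    return ts.with_data(out, step="psc")


def preprocess_run(ts: TimeSeries, cfg: PreprocessConfig | None = None) -> TimeSeries:
    """Standard order: percent signal change first, then high-pass filter."""
    cfg = cfg or PreprocessConfig()
    if cfg.psc:
        ts = percent_signal_change(ts)
    return highpass(ts, cfg)
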