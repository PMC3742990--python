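"""Phase-encoded periodic analysis: coherence, phase, amplitude per voxel.

The stimulus traverses the visual field periodically (``n_cycles`` cycles
per run), so a driven voxel responds sinusoidally at the cycle frequency
with a phase encoding its visual-field position.  Fitting the sinusoid is a
single discrete Fourier coefficient; coherence measures how much of the
series' non-DC spectral amplitude sits in the stimulus bin and is used to
select retinotopically driven voxels (strictly above a threshold, 0.25 by
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TimeSeries

__all__ = ["PeriodicFit", "periodic_fit", "select_by_coherence"]


@dataclass
class PeriodicFit:
    """Per-voxel sinusoid fit at the stimulus frequency."""

    coherence: np.ndarray    # in [0, 1]
    phase: np.ndarray        # radians, wrapped to [0, 2*pi)
    amplitude: np.ndarray    # response amplitude, >= 0
    stimulus_frequency: int  # cycles per run

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel": np.arange(len(self.coherence)),
            "coherence": self.coherence,
            "phase": self.phase,
            "amplitude": self.amplitude,
        })


def periodic_fit(ts: TimeSeries, n_cycles: int) -> PeriodicFit:
    """Amplitude/phase from the DFT bin at ``n_cycles``; coherence is that
    bin's amplitude over the root-sum-square of all non-DC bin amplitudes up
    to Nyquist.

    Phase follows the convention ``x(t) = A cos(2*pi*f*t - phase)``, so a
    response delayed in time has a larger phase.
    """
    n = ts.n_timepoints
    if n_cycles < 1 or n_cycles >= n // 2 + 1:
        raise ValueError(f"stimulus bin {n_cycles} at or beyond Nyquist "
                         f"for {n} timepoints")
    F = np.fft.rfft(ts.data, axis=1)
    # one-sided amplitude spectrum (DC and Nyquist unpaired)
    amp = np.abs(F) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0
    denom = np.sqrt((amp[:, 1:] ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, amp[:, n_cycles] / np.where(denom > 0, denom, 1.0), 0.0)
    phase = (-np.angle(F[:, n_cycles])) % (2.0 * np.pi)
    return PeriodicFit(coherence=coh, phase=phase,
                       amplitude=amp[:, n_cycles],
                       stimulus_frequency=int(n_cycles))


def select_by_coherence(fit: PeriodicFit, threshold: float = 0.25) -> np.ndarray:
    """Boolean voxel mask: coherence strictly greater than the threshold."""
    return fit.coherence > threshold
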