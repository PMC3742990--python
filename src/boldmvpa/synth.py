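"""Synthetic event-related BOLD data with known ground truth.

The generator mirrors the linear model the analysis assumes: each voxel's
series is a baseline plus a sum of trial responses (a scalar amplitude times
a shared hemodynamic kernel shifted to the trial onset), slow drift, and
white Gaussian noise.  Trial amplitudes follow Gaussian tuning in log2 speed
around a voxel-specific preferred speed, scaled by a luminance-dependent
gain, plus an optional additive luminance pattern.  Preferred speed drifts
with cortical eccentricity so that a perifoveal-to-peripheral gradient (and,
optionally, a luminance-dependent difference in that gradient) is present by
construction.

Signals are built on a 1-s grid (trial onsets are integer seconds and are
not aligned to the 2-s TR) and sampled at TR instants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TimeSeries
from .design import DesignSpec

__all__ = [
    "VoxelPopulation",
    "GroundTruth",
    "make_population",
    "canonical_hrf",
    "trial_amplitudes_true",
    "simulate_runs",
    "simulate_retinotopy_run",
    "simulate_preference_profiles",
]


@dataclass
class VoxelPopulation:
    """Generative parameters of a synthetic ROI.

    preferred_speed is the tuning center in deg/s (tuning operates in log2
    speed); ``low_luminance_pref_shift_log2`` shifts the log2 center at the
    low-luminance level, which injects a luminance x tuning interaction.
    ``gain_per_luminance`` maps luminance value (cd/m^2) -> per-voxel response
    gain; ``luminance_pattern_weight`` is a per-voxel additive response offset
    applied at the high-luminance level only (dummy coding: high = 1).
    """

    preferred_speed: np.ndarray
    tuning_width_log2: np.ndarray
    gain_per_luminance: dict
    eccentricity_mm: np.ndarray
    luminance_pattern_weight: np.ndarray
    low_luminance_pref_shift_log2: np.ndarray
    noise_sd: float = 1.0
    drift_order: int = 3
    drift_amplitude: float = 1.0
    cortical_extent_mm: float = 25.0

    def __post_init__(self):
        n = self.n_voxels
        for name in ("preferred_speed", "tuning_width_log2", "eccentricity_mm",
                     "luminance_pattern_weight", "low_luminance_pref_shift_log2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if n < 1:
            raise ValueError("population must contain at least one voxel")
        if np.any(self.tuning_width_log2 <= 0):
            raise ValueError("tuning widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_voxels(self) -> int:
        return len(np.atleast_1d(self.preferred_speed))

    @property
    def high_luminance(self) -> float:
        return max(self.gain_per_luminance)


def make_population(n_voxels: int = 120, seed=None, *,
                    center_speed: float = 6.0,
                    center_spread_log2: float = 1.0,
                    tuning_width_log2: float = 1.0,
                    gain: float = 15.0,
                    luminances=(30.0, 1.5),
                    gain_low_factor: float = 1.0,
                    luminance_pattern_sd: float = 0.0,
                    ecc_gradient_log2: float = 1.0,
                    ecc_gradient_log2_low: float | None = None,
                    cortical_extent_mm: float = 25.0,
                    noise_sd: float = 1.0,
                    drift_order: int = 3,
                    drift_amplitude: float = 1.0) -> VoxelPopulation:
    """Draw a heterogeneous voxel population.

    Preferred log2 speed = log2(center_speed)
    + ecc_gradient_log2 * (eccentricity/extent - 1/2) + N(0, center_spread_log2^2),
    so periphery prefers faster speeds while the population mean stays at
    ``center_speed`` (band-pass mean tuning).  ``ecc_gradient_log2_low``, when
    given, replaces the gradient at low luminance (the interaction used in the
    eccentricity analyses); the default is no interaction.  Gains default to
    luminance-invariant (no mean luminance effect), and
    ``luminance_pattern_sd`` > 0 adds a zero-mean voxel-specific additive
    luminance response (a pattern, not a mean shift).
    """
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(0.0, cortical_extent_mm, size=n_voxels)
    resid = rng.normal(0.0, center_spread_log2, size=n_voxels)
    base = np.log2(center_speed) + resid
    rel = ecc / cortical_extent_mm - 0.5
    pref_log2_high = base + ecc_gradient_log2 * rel
    if ecc_gradient_log2_low is None:
        shift_low = np.zeros(n_voxels)
    else:
        shift_low = (ecc_gradient_log2_low - ecc_gradient_log2) * rel
    hi, lo = max(luminances), min(luminances)
    gains = {hi: np.full(n_voxels, gain),
             lo: np.full(n_voxels, gain * gain_low_factor)}
    lum_weight = rng.normal(0.0, luminance_pattern_sd, size=n_voxels) \
        if luminance_pattern_sd > 0 else np.zeros(n_voxels)
    return VoxelPopulation(
        preferred_speed=2.0 ** pref_log2_high,
        tuning_width_log2=np.full(n_voxels, tuning_width_log2),
        gain_per_luminance=gains,
        eccentricity_mm=ecc,
        luminance_pattern_weight=lum_weight,
        low_luminance_pref_shift_log2=shift_low,
        noise_sd=noise_sd,
        drift_order=drift_order,
        drift_amplitude=drift_amplitude,
        cortical_extent_mm=cortical_extent_mm,
    )


@dataclass
class GroundTruth:
    """Noiseless quantities recorded during simulation for recovery tests."""

    hrf_true: np.ndarray          # kernel samples on the 1-s grid
    amplitudes_true: np.ndarray   # (m trials, n voxels)
    labels: pd.DataFrame          # per-trial speed, luminance, run


def canonical_hrf(peak_s: float = 5.0, undershoot_s: float = 15.0,
                  undershoot_ratio: float = 1.0 / 6.0,
                  tr_seconds: float = 1.0, window_s: float = 30.0) -> np.ndarray:
    """Double-gamma hemodynamic kernel, sampled every ``tr_seconds`` on
    [0, window_s], zero at t=0, normalized so the samples sum to one.

    Gamma shapes are parameterized by their modes (``peak_s`` for the positive
    lobe, ``undershoot_s`` for the negative lobe of relative depth
    ``undershoot_ratio``).
    """
    if min(peak_s, undershoot_s, tr_seconds) <= 0 or undershoot_ratio < 0:
        raise ValueError("HRF shape parameters must be positive")
    if window_s < peak_s:
        raise ValueError("window must extend beyond the response peak")
    from scipy.stats import gamma

    t = np.arange(0.0, window_s + 0.5 * tr_seconds, tr_seconds)
    h = gamma.pdf(t, a=peak_s + 1.0, scale=1.0) \
        - undershoot_ratio * gamma.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    total = h.sum()
    if total <= 0:
        raise ValueError("degenerate kernel: non-positive total area")
    return h / total


def trial_amplitudes_true(events: pd.DataFrame, pop: VoxelPopulation) -> np.ndarray:
    """Noiseless (m trials x n voxels) response amplitudes under the model."""
    speeds = events["speed"].to_numpy(float)
    lums = events["luminance"].to_numpy(float)
    high = pop.high_luminance
    log2s = np.log2(speeds)[:, None]
    center = np.log2(pop.preferred_speed)[None, :] \
        + np.where(lums[:, None] == high, 0.0,
                   pop.low_luminance_pref_shift_log2[None, :])
    gains = np.stack([pop.gain_per_luminance[l] for l in lums])
    tuning = np.exp(-(log2s - center) ** 2
                    / (2.0 * pop.tuning_width_log2[None, :] ** 2))
    return gains * tuning \
        + np.where(lums[:, None] == high, 1.0, 0.0) \
        * pop.luminance_pattern_weight[None, :]


def _drift(n_timepoints: int, tr: float, order: int, amplitude: float,
           n_voxels: int, rng) -> np.ndarray:
    if order <= 0 or amplitude == 0:
        return np.zeros((n_voxels, n_timepoints))
    t = np.arange(n_timepoints) * tr
    total = n_timepoints * tr
    basis = np.stack([np.cos(np.pi * k * t / total) for k in range(1, order + 1)])
    coeffs = rng.normal(0.0, amplitude, size=(n_voxels, order))
    return coeffs @ basis


def simulate_runs(events: pd.DataFrame, pop: VoxelPopulation,
                  hrf: np.ndarray, spec: DesignSpec, seed=None,
                  baseline: float = 0.0):
    """Generate all runs of a session plus the recorded ground truth.

    ``hrf`` is the kernel on the 1-s grid.  With ``baseline == 0`` the output
    is already in evoked-signal units (percent-signal-change-like); with
    ``baseline > 0`` it is raw scanner units ``baseline * (1 + x / 100)`` and
    should go through percent-signal-change conversion before modeling.
    """
    tr = spec.tr_seconds
    if abs(tr - round(tr)) > 1e-9:
        raise ValueError("simulation requires an integer TR in seconds")
    tr = int(round(tr))
    run_len_s = int(round(spec.run_seconds))
    rng = np.random.default_rng(seed)
    hrf = np.asarray(hrf, dtype=float)
    amps = trial_amplitudes_true(events, pop)
    n_vox = pop.n_voxels
    runs = []
    for run in sorted(events["run"].unique()):
        grp = events[events["run"] == run]
        idx = grp.index.to_numpy()
        signal = np.zeros((n_vox, run_len_s + len(hrf)))
        for j, onset in zip(idx, grp["onset"].to_numpy()):
            o = int(round(onset))
            if not np.isclose(onset, o):
                raise ValueError("trial onsets must lie on the 1-s grid")
            signal[:, o:o + len(hrf)] += np.outer(amps[j], hrf)
        sampled = signal[:, :run_len_s:tr][:, :spec.volumes_per_run]
        x = sampled \
            + _drift(spec.volumes_per_run, tr, pop.drift_order,
                     pop.drift_amplitude, n_vox, rng) \
            + (rng.normal(0.0, pop.noise_sd,
                          size=(n_vox, spec.volumes_per_run))
               if pop.noise_sd > 0 else 0.0)
        data = baseline * (1.0 + x / 100.0) if baseline > 0 else x
        runs.append(TimeSeries(data=data, tr_seconds=float(tr), run=int(run),
                               provenance=["synthetic"]))
    truth = GroundTruth(hrf_true=hrf, amplitudes_true=amps,
                        labels=events[["speed", "luminance", "run"]].copy())
    return runs, truth


def simulate_retinotopy_run(n_cycles: int, cycle_s: float, tr_seconds: float,
                            pop: VoxelPopulation, seed=None,
                            amplitude=1.0) -> TimeSeries:
    """Phase-encoded run: each voxel responds sinusoidally at the stimulus
    cycle frequency with phase proportional to its position along the
    eccentricity axis (the generator's linear phase map), plus noise."""
    if n_cycles < 2:
        raise ValueError("need at least 2 stimulus cycles")
    if abs(cycle_s / tr_seconds - round(cycle_s / tr_seconds)) > 1e-9:
        raise ValueError("cycle duration must be an integer number of TRs "
                         "(keeps the stimulus frequency on an exact DFT bin)")
    n_t = int(round(n_cycles * cycle_s / tr_seconds))
    rng = np.random.default_rng(seed)
    phase = 2.0 * np.pi * pop.eccentricity_mm / pop.cortical_extent_mm
    t = np.arange(n_t)
    arg = 2.0 * np.pi * n_cycles * t[None, :] / n_t - phase[:, None]
    amp = np.broadcast_to(np.asarray(amplitude, float), (pop.n_voxels,))
    data = amp[:, None] * np.cos(arg)
    if pop.noise_sd > 0:
        data = data + rng.normal(0.0, pop.noise_sd, size=data.shape)
    return TimeSeries(data=data, tr_seconds=tr_seconds, run=0,
                      provenance=["synthetic-retinotopy"])


def simulate_preference_profiles(n_subjects: int = 6, hemispheres: int = 2,
                                 n_bins: int = 8, *,
                                 base_speed: float = 3.0,
                                 slope_high_log2: float = 0.1,
                                 slope_low_log2: float = 0.2,
                                 noise_sd_log2: float = 0.3,
                                 seed=None):
    """Binned speed-preference profiles for a cohort, per luminance.

    Each profile holds per-bin mean preferred speed (deg/s) following a linear
    trend in log2 speed across the usable eccentricity bins (perifoveal ->
    peripheral), with independent Gaussian per-bin noise across
    subject x hemisphere profiles.  The low/high slope difference is the
    luminance x eccentricity interaction under study; equal slopes give the
    exchangeable null.

    Returns ``(profiles_high, profiles_low)`` as lists of
    :class:`~boldmvpa.preference.PreferenceProfile`.
    """
    from .preference import PreferenceProfile

    rng = np.random.default_rng(seed)
    bins = np.arange(n_bins, dtype=float)
    out = {"high": [], "low": []}
    slopes = {"high": slope_high_log2, "low": slope_low_log2}
    for s in range(n_subjects):
        for h in range(hemispheres):
            hemi = "left" if h == 0 else "right"
            for cond, slope in slopes.items():
                log2pref = np.log2(base_speed) + slope * bins \
                    + rng.normal(0.0, noise_sd_log2, size=n_bins)
                out[cond].append(PreferenceProfile(
                    subject=f"S{s + 1:02d}", hemisphere=hemi, luminance=cond,
                    bin_index=np.arange(n_bins),
                    mean_preferred_speed=2.0 ** log2pref,
                    included_fraction=np.ones(n_bins),
                ))
    return out["high"], out["low"]
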