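"""HRF deconvolution, trial-wise GLM amplitudes, and condition statistics.

The response model follows a two-step scheme.  First the trial-triggered
response (the HRF) is estimated per stimulus condition by finite-impulse-
response deconvolution: one delta-basis regressor per lag per condition, so
overlapping trials are resolved by ordinary least squares without assuming a
response shape.  Lags live on a 1-s grid even though the data are sampled at
the TR, because trial onsets fall on integer seconds that jitter relative to
the TR; this jitter makes the 1-s kernel identifiable.  Second, the pooled,
unit-area HRF is shifted to each trial onset to form one design column per
trial, and per-voxel regression coefficients give the m x n matrix of trial
response amplitudes that feeds the decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .containers import TimeSeries
from .preprocess import highpass_array

__all__ = [
    "HRFEstimate",
    "TrialAmplitudeMatrix",
    "ConditionStats",
    "deconvolve_hrf",
    "pool_and_normalize_hrf",
    "trial_design_matrix",
    "fit_trial_amplitudes",
    "condition_stats",
    "mean_tuning",
    "save_amplitudes",
    "load_amplitudes",
]


@dataclass
class HRFEstimate:
    """Sampled response kernel over a post-onset window.

    ``dt_seconds`` is the lag-grid resolution (1 s by default: finer than the
    TR, resolvable thanks to onset jitter).  ``unit_area`` kernels have
    samples summing to one.
    """

    samples: np.ndarray
    dt_seconds: float
    condition: object = "pooled"
    unit_area: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.unit_area and abs(self.samples.sum() - 1.0) > 1e-9:
            raise ValueError("unit_area kernel must have samples summing to 1")

    @property
    def window_seconds(self) -> float:
        return len(self.samples) * self.dt_seconds


@dataclass
class TrialAmplitudeMatrix:
    """Per-trial, per-voxel GLM response amplitudes plus fit quality."""

    amplitudes: np.ndarray     # (m trials, n voxels)
    trial_meta: pd.DataFrame   # columns speed, luminance, run
    r_squared: np.ndarray      # (n,)
    mean_sign: np.ndarray      # (n,) sign of the mean evoked amplitude

    def __post_init__(self):
        m, n = self.amplitudes.shape
        if len(self.trial_meta) != m:
            raise ValueError("trial_meta length must equal number of trials")
        if self.r_squared.shape != (n,) or self.mean_sign.shape != (n,):
            raise ValueError("per-voxel arrays must have length n_voxels")

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[1]


@dataclass
class ConditionStats:
    """One-sample statistics of trial amplitudes per voxel x speed x luminance."""

    speeds: np.ndarray
    luminances: np.ndarray
    mean: np.ndarray   # (n_voxels, n_speeds, n_luminances)
    sd: np.ndarray
    count: np.ndarray
    t: np.ndarray
    df: np.ndarray


def _impulse_design(events: pd.DataFrame, runs: list[TimeSeries],
                    n_lags: int, dt: float, by) -> tuple[np.ndarray, list]:
    """FIR design: one column per (condition, lag) over the stacked runs."""
    conditions = sorted(events.groupby(list(by)).groups)
    tr = runs[0].tr_seconds
    blocks = []
    for ts in runs:
        grp = events[events["run"] == ts.run]
        run_len_s = int(round(ts.n_timepoints * tr))
        block = np.zeros((ts.n_timepoints, len(conditions) * n_lags))
        for ci, cond in enumerate(conditions):
            key = cond if isinstance(cond, tuple) else (cond,)
            sel = np.ones(len(grp), dtype=bool)
            for col, val in zip(by, key):
                sel &= grp[col].to_numpy() == val
            for onset in grp["onset"].to_numpy()[sel]:
                for lag in range(n_lags):
                    t_s = onset + lag * dt
                    if t_s >= run_len_s:
                        break
                    # sample the 1-s impulse train at TR instants
                    if abs(t_s / tr - round(t_s / tr)) < 1e-9:
                        block[int(round(t_s / tr)), ci * n_lags + lag] += 1.0
        blocks.append(block)
    return np.vstack(blocks), conditions


def deconvolve_hrf(runs: list[TimeSeries], events: pd.DataFrame,
                   window_seconds: float = 20.0, dt_seconds: float = 1.0,
                   by=("speed",), highpass_cutoff_hz: float | None = None
                   ) -> dict:
    """Least-squares FIR estimate of the trial-triggered response per condition.

    Operates on the ROI-mean series of each run.  When the data were
    high-pass filtered, pass the same cutoff so the design columns are
    filtered identically (otherwise estimates of slow response components are
    biased).  Returns ``{condition: HRFEstimate}``.
    """
    tr = runs[0].tr_seconds
    n_lags = int(round(window_seconds / dt_seconds))
    X, conditions = _impulse_design(events, runs, n_lags, dt_seconds, by)
    if highpass_cutoff_hz is not None:
        X = _filter_blocks(X, runs, highpass_cutoff_hz, tr)
    y = np.concatenate([ts.data.mean(axis=0) for ts in runs])
    # per-run intercepts absorb baseline offsets without biasing the kernel
    inter = np.zeros((X.shape[0], len(runs)))
    row = 0
    for bi, ts in enumerate(runs):
        inter[row:row + ts.n_timepoints, bi] = 1.0
        row += ts.n_timepoints
    Xf = np.hstack([X, inter])
    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        # name offending columns: start with any all-zero ones
        norms = np.linalg.norm(X, axis=0)
        dead = np.where(norms < 1e-12)[0]
        raise np.linalg.LinAlgError(
            f"FIR design rank-deficient ({rank}/{Xf.shape[1]}); "
            f"zero/collinear columns include indices {dead.tolist()}")
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    out = {}
    for ci, cond in enumerate(conditions):
        key = cond if not isinstance(cond, tuple) or len(cond) > 1 else cond[0]
        out[key] = HRFEstimate(samples=beta[ci * n_lags:(ci + 1) * n_lags],
                               dt_seconds=dt_seconds, condition=key)
    return out


def _filter_blocks(X: np.ndarray, runs: list[TimeSeries],
                   cutoff: float, tr: float) -> np.ndarray:
    X = X.copy()
    row = 0
    for ts in runs:
        stop = row + ts.n_timepoints
        X[row:stop] = highpass_array(X[row:stop].T, tr, cutoff).T
        row = stop
    return X


def pool_and_normalize_hrf(estimates) -> HRFEstimate:
    """Average kernels across conditions and rescale to unit area."""
    if isinstance(estimates, dict):
        estimates = list(estimates.values())
    if not estimates:
        raise ValueError("no HRF estimates to pool")
    dt = estimates[0].dt_seconds
    n = len(estimates[0].samples)
    if any(e.dt_seconds != dt or len(e.samples) != n for e in estimates):
        raise ValueError("HRF estimates differ in window or resolution")
    pooled = np.mean([e.samples for e in estimates], axis=0)
    total = pooled.sum()
    if abs(total) < 1e-12:
        raise ValueError("pooled kernel has zero area; cannot normalize")
    return HRFEstimate(samples=pooled / total, dt_seconds=dt,
                       condition="pooled", unit_area=True)


def trial_design_matrix(events: pd.DataFrame, hrf: HRFEstimate,
                        n_timepoints: int, tr_seconds: float) -> np.ndarray:
    """One column per trial: the unit-area HRF shifted to the trial onset.

    Columns are built on the 1-s grid, sampled at TR instants, truncated at
    the run end, and stacked across runs in run order.  Column order follows
    the event-table row order.
    """
    if not hrf.unit_area:
        raise ValueError("trial design requires the pooled unit-area HRF")
    if abs(hrf.dt_seconds - 1.0) > 1e-9:
        grid = np.arange(int(round(hrf.window_seconds)))
        kernel = np.interp(grid, np.arange(len(hrf.samples)) * hrf.dt_seconds,
                           hrf.samples)
    else:
        kernel = hrf.samples
    tr = int(round(tr_seconds))
    events = events.reset_index(drop=True)
    run_ids = sorted(events["run"].unique())
    run_len_s = n_timepoints * tr
    m = len(events)
    X = np.zeros((n_timepoints * len(run_ids), m))
    for bi, run in enumerate(run_ids):
        grp = events[events["run"] == run]
        for j, onset in zip(grp.index, grp["onset"].to_numpy()):
            if onset >= run_len_s:
                raise ValueError(f"trial onset {onset}s beyond run end")
            col_1s = np.zeros(run_len_s + len(kernel))
            col_1s[int(round(onset)):int(round(onset)) + len(kernel)] = kernel
            X[bi * n_timepoints:(bi + 1) * n_timepoints, j] = \
                col_1s[:run_len_s:tr][:n_timepoints]
    return X


def fit_trial_amplitudes(runs: list[TimeSeries], events: pd.DataFrame,
                         hrf: HRFEstimate,
                         highpass_cutoff_hz: float | None = None
                         ) -> TrialAmplitudeMatrix:
    """Per-voxel OLS of the stacked series on the per-trial HRF regressors.

    Per-run intercepts are included (and discarded); R-squared is computed
    per voxel around the series mean.  ``mean_sign`` is the sign of the mean
    fitted amplitude and marks positive responders.
    """
    tr = runs[0].tr_seconds
    n_t = runs[0].n_timepoints
    X = trial_design_matrix(events, hrf, n_t, tr)
    if highpass_cutoff_hz is not None:
        X = _filter_blocks(X, runs, highpass_cutoff_hz, tr)
    m = X.shape[1]
    # per-run intercepts
    blocks = np.zeros((X.shape[0], len(runs)))
    for bi in range(len(runs)):
        blocks[bi * n_t:(bi + 1) * n_t, bi] = 1.0
    Xf = np.hstack([X, blocks])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise np.linalg.LinAlgError("trial design matrix is rank-deficient")
    Y = np.concatenate([ts.data for ts in sorted(runs, key=lambda t: t.run)],
                       axis=1).T  # (timepoints_total, n_voxels)
    beta, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    amps = beta[:m]                       # (m, n_voxels)
    resid = Y - Xf @ beta
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss = (resid ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return TrialAmplitudeMatrix(
        amplitudes=amps,
        trial_meta=events[["speed", "luminance", "run"]].reset_index(drop=True),
        r_squared=r2,
        mean_sign=np.sign(amps.mean(axis=0)),
    )


def condition_stats(amps: TrialAmplitudeMatrix) -> ConditionStats:
    """One-sample t statistic of trial amplitudes vs zero per condition cell.

    ``t = mean / (sd / sqrt(count))`` with ``df = count - 1``; a zero sd
    yields a signed-infinity sentinel with a warning.
    """
    speeds = np.sort(amps.trial_meta["speed"].unique())
    lums = np.sort(amps.trial_meta["luminance"].unique())
    n = amps.n_voxels
    shape = (n, len(speeds), len(lums))
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    count = np.zeros(shape[1:], dtype=int)
    t = np.full(shape, np.nan)
    for si, s in enumerate(speeds):
        for li, l in enumerate(lums):
            sel = ((amps.trial_meta["speed"] == s)
                   & (amps.trial_meta["luminance"] == l)).to_numpy()
            k = int(sel.sum())
            count[si, li] = k
            if k == 0:
                continue
            vals = amps.amplitudes[sel]
            mean[:, si, li] = vals.mean(axis=0)
            if k >= 2:
                sd[:, si, li] = vals.std(axis=0, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    tv = mean[:, si, li] / (sd[:, si, li] / np.sqrt(k))
                zero_sd = sd[:, si, li] == 0
                if np.any(zero_sd & (mean[:, si, li] != 0)):
                    warnings.warn("zero-variance condition cell: t reported "
                                  "as signed infinity")
                with np.errstate(invalid="ignore"):
                    sentinel = np.sign(mean[:, si, li]) * np.inf
                sentinel[mean[:, si, li] == 0] = 0.0
                t[:, si, li] = np.where(zero_sd, sentinel, tv)
    count_full = np.broadcast_to(count, shape).copy()
    return ConditionStats(speeds=speeds, luminances=lums, mean=mean, sd=sd,
                          count=count_full, t=t,
                          df=np.maximum(count_full - 1, 0))


def mean_tuning(amps: TrialAmplitudeMatrix) -> pd.DataFrame:
    """ROI tuning curve: mean voxel-averaged amplitude per speed x luminance.

    Each trial is first collapsed across voxels; the mean and standard error
    are then taken across trials within each condition cell.
    """
    trial_vals = amps.amplitudes.mean(axis=1)
    df = amps.trial_meta.assign(amplitude=trial_vals)
    rows = []
    for (s, l), grp in df.groupby(["speed", "luminance"]):
        if len(grp) == 0:
            raise ValueError(f"empty condition cell speed={s} luminance={l}")
        vals = grp["amplitude"].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append((s, l, vals.mean(), sem, len(vals)))
    return pd.DataFrame(rows, columns=["speed", "luminance", "mean", "sem", "n"])


def save_amplitudes(amps: TrialAmplitudeMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=amps.amplitudes)
        f.create_dataset("r_squared", data=amps.r_squared)
        f.create_dataset("mean_sign", data=amps.mean_sign)
        for col in ("speed", "luminance", "run"):
            f.create_dataset(f"trial_meta/{col}",
                             data=amps.trial_meta[col].to_numpy(float))


def load_amplitudes(path) -> TrialAmplitudeMatrix:
    with h5py.File(path, "r") as f:
        meta = pd.DataFrame({col: f[f"trial_meta/{col}"][()]
                             for col in ("speed", "luminance", "run")})
        meta["run"] = meta["run"].astype(int)
        return TrialAmplitudeMatrix(
            amplitudes=f["amplitudes"][()],
            trial_meta=meta,
            r_squared=f["r_squared"][()],
            mean_sign=f["mean_sign"][()],
        )
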