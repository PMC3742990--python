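"""Speed-preference maps along eccentricity and the slope-difference test.

Each responsive voxel (model fit R^2 strictly above threshold, positive mean
evoked response) is labeled with the speed giving its most significant
response (largest signed one-sample t; winner takes all, ties broken toward
the slower speed).  Labels are averaged within equal-width eccentricity bins
from the perifoveal to the peripheral stimulus boundary; the most peripheral
bins are dropped (sparsely populated by construction of the stimulus edge).

The luminance effect on the preference-vs-eccentricity slope is tested by
resampling: a line is regressed onto the bin-wise difference between the
high- and low-luminance mean profiles (slope ``b``, correlation ``r``); the
null redistributes all subject x hemisphere x luminance profiles into two
random equal-sized sets and recomputes the difference regression per
iteration.  The p-value counts iterations whose ``|b|`` and ``|r|`` both
reach the observed magnitudes (a signed one-sided variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import ConditionStats, TrialAmplitudeMatrix

__all__ = [
    "PreferenceProfile",
    "SlopeTestResult",
    "responsive_mask",
    "voxel_preferences",
    "bin_profile",
    "slope_difference_test",
    "profiles_to_frame",
]


@dataclass
class PreferenceProfile:
    """Binned mean preferred speed along eccentricity for one
    subject x hemisphere x luminance condition."""

    subject: str
    hemisphere: str
    luminance: object
    bin_index: np.ndarray             # perifoveal -> peripheral
    mean_preferred_speed: np.ndarray  # deg/s, NaN where a bin is empty
    included_fraction: np.ndarray     # fraction of bin voxels passing masks


@dataclass
class SlopeTestResult:
    """Observed difference regression and its resampling null."""

    b: float
    r: float
    p: float
    n_iterations: int
    seed: object
    mode: str
    null_b: np.ndarray = field(repr=False, default=None)
    null_r: np.ndarray = field(repr=False, default=None)

    def summary(self) -> dict:
        return {"b": self.b, "r": self.r, "p": self.p,
                "n_iterations": self.n_iterations,
                "seed": self.seed, "mode": self.mode}


def responsive_mask(amps: TrialAmplitudeMatrix,
                    r2_threshold: float = 0.25) -> np.ndarray:
    """Voxels with R^2 strictly above threshold and a positive mean evoked
    response."""
    return (amps.r_squared > r2_threshold) & (amps.mean_sign > 0)


def voxel_preferences(stats: ConditionStats, mask: np.ndarray | None = None,
                      luminance=None) -> np.ndarray:
    """Winner-takes-all preferred speed per voxel from signed t statistics.

    ``luminance`` picks the luminance slice (default: the only one present).
    Speeds are scanned in ascending order and ``argmax`` keeps the first
    maximum, so exact ties resolve toward the slower speed.  Voxels outside
    ``mask`` or without a finite t at any speed come back NaN.
    """
    if luminance is None:
        if len(stats.luminances) != 1:
            raise ValueError("multiple luminances present; pick one")
        li = 0
    else:
        where = np.where(stats.luminances == luminance)[0]
        if not where.size:
            raise ValueError(f"luminance {luminance} not in stats")
        li = int(where[0])
    t = stats.t[:, :, li]  # (n_voxels, n_speeds), speeds ascending
    pref = np.full(t.shape[0], np.nan)
    ok = np.isfinite(t).any(axis=1)
    if mask is not None:
        ok &= np.asarray(mask, bool)
    safe = np.where(np.isfinite(t), t, -np.inf)
    pref[ok] = stats.speeds[np.argmax(safe[ok], axis=1)]
    return pref


def bin_profile(prefs: np.ndarray, eccentricity_mm: np.ndarray,
                n_bins: int = 10, n_drop: int = 2,
                min_inclusion: float = 0.10, ecc_range=None,
                subject: str = "S01", hemisphere: str = "left",
                luminance=None) -> PreferenceProfile:
    """Average preferred speed in equal-width eccentricity bins, dropping the
    ``n_drop`` most peripheral bins.

    ``prefs`` may contain NaN for voxels excluded by the responsiveness
    criteria; ``included_fraction`` records, per kept bin, the fraction of
    its voxels with a valid label (bins below ``min_inclusion`` keep their
    mean but are flaggable by the caller; empty bins come back NaN).
    """
    prefs = np.asarray(prefs, float)
    ecc = np.asarray(eccentricity_mm, float)
    lo, hi = ecc_range if ecc_range is not None else (ecc.min(), ecc.max())
    if hi <= lo:
        raise ValueError("eccentricity span must be positive")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(ecc, edges[1:-1]), 0, n_bins - 1)
    keep = n_bins - n_drop
    means = np.full(keep, np.nan)
    fractions = np.zeros(keep)
    for b in range(keep):
        in_bin = idx == b
        valid = in_bin & np.isfinite(prefs)
        if in_bin.sum():
            fractions[b] = valid.sum() / in_bin.sum()
        if valid.sum():
            means[b] = prefs[valid].mean()
    return PreferenceProfile(subject=subject, hemisphere=hemisphere,
                             luminance=luminance,
                             bin_index=np.arange(keep),
                             mean_preferred_speed=means,
                             included_fraction=fractions)


def _stack(profiles) -> np.ndarray:
    vals = np.vstack([p.mean_preferred_speed for p in profiles])
    widths = {len(p.mean_preferred_speed) for p in profiles}
    if len(widths) != 1:
        raise ValueError("profiles differ in bin count")
    return vals


def _regress(x: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
    """Slope and Pearson r of a line fit, ignoring NaN bins (needs >= 3)."""
    ok = np.isfinite(yv)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable bins for the slope regression")
    xo, yo = x[ok], yv[ok]
    xc = xo - xo.mean()
    yc = yo - yo.mean()
    b = float(xc @ yc / (xc @ xc))
    sy = np.sqrt(yc @ yc)
    r = float(xc @ yc / (np.sqrt(xc @ xc) * sy)) if sy > 0 else 0.0
    return b, r


def slope_difference_test(profiles_high, profiles_low,
                          n_iterations: int = 10_000, seed=None,
                          mode: str = "two_sided",
                          require_r: bool = True) -> SlopeTestResult:
    """Resampling test for a luminance difference in the preference slope.

    Observed statistic: regress (mean high profile - mean low profile) on
    bin position -> slope ``b`` and correlation ``r``.  Null: pool all
    profiles, split randomly into two equal sets, difference the set means,
    regress identically.  ``p = (1 + #{null as extreme}) / (n_iterations + 1)``
    where "as extreme" requires both the slope and the correlation to reach
    the observed ones — in magnitude (``two_sided``, default) or signed
    (``one_sided``).

    The joint b-and-r condition follows the original procedure but is
    anti-conservative: demanding that null iterations clear two hurdles
    shrinks the count, so the type-I error exceeds the nominal level (about
    0.09 at alpha = 0.05 in simulations with 24 exchangeable profiles).
    ``require_r=False`` drops the correlation condition, giving an exactly
    exchangeable single-statistic permutation test with the usual (slightly
    conservative) +1-corrected calibration.
    """
    if mode not in ("two_sided", "one_sided"):
        raise ValueError(f"unknown mode {mode!r}")
    high = _stack(profiles_high)
    low = _stack(profiles_low)
    if high.shape[1] != low.shape[1]:
        raise ValueError("high/low profiles differ in bin count")
    pool = np.vstack([high, low])
    n_prof, n_bins = pool.shape
    if n_prof % 2:
        raise ValueError("pooled profile count must be even for equal splits")
    x = np.arange(n_bins, dtype=float)
    diff_obs = np.nanmean(high, axis=0) - np.nanmean(low, axis=0)
    b_obs, r_obs = _regress(x, diff_obs)

    rng = np.random.default_rng(seed)
    half = n_prof // 2
    if np.isfinite(pool).all():
        # vectorized: random equal splits as +/- weight vectors
        order = np.argsort(rng.random((n_iterations, n_prof)), axis=1)
        w = np.full((n_iterations, n_prof), -1.0 / half)
        np.put_along_axis(w, order[:, :half], 1.0 / half, axis=1)
        D = w @ pool                                # (n_iterations, n_bins)
        xc = x - x.mean()
        Dc = D - D.mean(axis=1, keepdims=True)
        b_null = Dc @ xc / (xc @ xc)
        sy = np.sqrt((Dc ** 2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_null = np.where(sy > 0, Dc @ xc / (np.sqrt(xc @ xc) * np.where(sy > 0, sy, 1.0)), 0.0)
    else:
        b_null = np.empty(n_iterations)
        r_null = np.empty(n_iterations)
        for it in range(n_iterations):
            sel = rng.permutation(n_prof)
            d = np.nanmean(pool[sel[:half]], axis=0) \
                - np.nanmean(pool[sel[half:]], axis=0)
            b_null[it], r_null[it] = _regress(x, d)

    if mode == "two_sided":
        hits = np.abs(b_null) >= abs(b_obs)
        if require_r:
            hits &= np.abs(r_null) >= abs(r_obs)
    else:
        hits = b_null >= b_obs
        if require_r:
            hits &= r_null >= r_obs
    p = (1 + int(hits.sum())) / (n_iterations + 1)
    mode_name = mode if require_r else f"{mode}_slope_only"
    return SlopeTestResult(b=b_obs, r=r_obs, p=p, n_iterations=n_iterations,
                           seed=seed, mode=mode_name,
                           null_b=b_null, null_r=r_null)


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for b, mean, frac in zip(p.bin_index, p.mean_preferred_speed,
                                 p.included_fraction):
            rows.append((p.subject, p.hemisphere, p.luminance, int(b),
                         mean, frac))
    return pd.DataFrame(rows, columns=["subject", "hemisphere", "luminance",
                                       "bin", "mean_pref", "fraction"])
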