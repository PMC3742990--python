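"""Event-related experimental designs: ITI sampling, trial sequencing, I/O.

The event table is a pandas DataFrame in a BIDS-events-like dialect with
columns ``onset``, ``duration``, ``speed``, ``luminance``, ``run`` (onset in
seconds from the start of that run).  Designs follow a rapid event-related
layout: a buffer period at each end of the run, fixed-duration trials, and
integer-second inter-trial intervals drawn from a truncated Poisson law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "sample_itis",
    "build_design",
    "read_events",
    "write_events",
    "validate_events",
]

EVENT_COLUMNS = ["onset", "duration", "speed", "luminance", "run"]

#: speeds used in the two stimulus sets (deg/s)
EXPERIMENT1_SPEEDS = (2.0, 4.0, 8.0, 13.3)
EXPERIMENT2_SPEEDS = (3.0, 6.0, 10.0)
HIGH_LUMINANCE = 30.0   # cd/m^2
LOW_LUMINANCE = 1.5     # cd/m^2


@dataclass
class DesignSpec:
    """Parameters of one scanning session's event-related design.

    Defaults reproduce the first stimulus set: six 224-volume runs at
    TR = 2 s (448 s per run), 3-s drifting-grating trials, 10 trials per
    speed per run, truncated-Poisson ITIs in [2, 10] s with mean 5.5 s,
    10-s buffers, and runs alternating between 30 and 1.5 cd/m^2.
    """

    tr_seconds: float = 2.0
    volumes_per_run: int = 224
    buffer_seconds: float = 10.0
    trial_duration_seconds: float = 3.0
    iti_min_seconds: float = 2.0
    iti_max_seconds: float = 10.0
    iti_mean_seconds: float = 5.5
    speeds: tuple = EXPERIMENT1_SPEEDS
    trials_per_speed: int = 10
    n_runs: int = 6
    luminances: tuple = (HIGH_LUMINANCE, LOW_LUMINANCE)
    luminance_schedule: str = "alternate_runs"  # or "blocked"
    seed: int | None = None

    def __post_init__(self):
        if not (self.iti_min_seconds <= self.iti_mean_seconds
                <= self.iti_max_seconds):
            raise ValueError("ITI mean must lie within [min, max]")
        spd = list(self.speeds)
        if len(set(spd)) != len(spd) or any(s <= 0 for s in spd):
            raise ValueError("speeds must be distinct and positive")
        if self.luminance_schedule not in ("alternate_runs", "blocked"):
            raise ValueError(f"unknown schedule {self.luminance_schedule!r}")
        needed = (2 * self.buffer_seconds
                  + self.trials_per_run * self.trial_duration_seconds
                  + self.trials_per_run * self.iti_min_seconds)
        if self.run_seconds < needed:
            raise ValueError(
                f"run length {self.run_seconds}s cannot fit the design "
                f"(needs >= {needed}s)")

    @property
    def run_seconds(self) -> float:
        return self.volumes_per_run * self.tr_seconds

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_speed * len(self.speeds)

    @classmethod
    def experiment1(cls, **kw) -> "DesignSpec":
        return cls(**kw)

    @classmethod
    def experiment2(cls, **kw) -> "DesignSpec":
        kw.setdefault("speeds", EXPERIMENT2_SPEEDS)
        kw.setdefault("luminance_schedule", "blocked")
        return cls(**kw)


def sample_itis(spec: DesignSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` integer-second ITIs from Poisson(mean) truncated to [min, max].

    Rejection sampling from Poisson(iti_mean) keeps only draws inside the
    stated range; the truncated mean at the default parameters is 5.465 s.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = spec.iti_mean_seconds
    lo, hi = spec.iti_min_seconds, spec.iti_max_seconds
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.poisson(lam, size=max(2 * (n - filled), 16)).astype(float)
        keep = draws[(draws >= lo) & (draws <= hi)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _luminance_for_run(spec: DesignSpec, run: int, first_high: bool) -> float:
    hi, lo = max(spec.luminances), min(spec.luminances)
    if len(set(spec.luminances)) == 1:
        return spec.luminances[0]
    if spec.luminance_schedule == "alternate_runs":
        order = (hi, lo) if first_high else (lo, hi)
        return order[run % 2]
    # blocked: first half of the runs one level, second half the other
    order = (hi, lo) if first_high else (lo, hi)
    return order[0] if run < spec.n_runs // 2 else order[1]


def build_design(spec: DesignSpec, seed=None, max_retries: int = 100) -> pd.DataFrame:
    """Lay out all runs of a session as an event table.

    Per run: the trial order is a random permutation of the balanced speed
    labels, onsets start after the opening buffer, successive trials are
    separated by truncated-Poisson ITIs, and the sequence must end before the
    closing buffer (re-drawn up to ``max_retries`` times, then an error).
    Onsets land on a 1-s grid (integer seconds) by construction.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    first_high = bool(rng.integers(2))
    rows = []
    for run in range(spec.n_runs):
        labels = np.repeat(spec.speeds, spec.trials_per_speed)
        for attempt in range(max_retries):
            order = rng.permutation(labels)
            itis = sample_itis(spec, spec.trials_per_run - 1,
                               seed=rng.integers(2**31))
            onsets = spec.buffer_seconds + np.concatenate(
                [[0.0], np.cumsum(spec.trial_duration_seconds + itis)])
            if onsets[-1] + spec.trial_duration_seconds <= \
                    spec.run_seconds - spec.buffer_seconds:
                break
        else:
            raise RuntimeError(
                f"could not fit {spec.trials_per_run} trials into run {run} "
                f"after {max_retries} ITI draws")
        lum = _luminance_for_run(spec, run, first_high)
        for onset, speed in zip(onsets, order):
            rows.append((onset, spec.trial_duration_seconds, speed, lum, run))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    validate_events(events)
    return events


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Schema and monotonicity checks for an event table."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    for run, grp in events.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(f"onsets not strictly increasing in run {run}")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    """Serialize an event table as tab-separated text (unknown columns kept)."""
    validate_events(events)
    ordered = EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]
    events[ordered].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read and validate a tab-separated event table."""
    events = pd.read_csv(path, sep="\t")
    return validate_events(events)
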