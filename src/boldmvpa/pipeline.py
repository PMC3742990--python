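"""End-to-end orchestration: synthesize, preprocess, model, decode, map.

``run_pipeline`` ties the stages into a deterministic bundle: a single
master seed is split into named substreams (design, population, noise,
permutations, resampling) so each stage can be re-run independently while
the whole bundle stays a pure function of (config, seed).  Outputs are
written as diff-able TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import save_timeseries
from .decoder import (DecoderConfig, cross_condition, decode_binary,
                      leave_one_run_out, permutation_chance,
                      univariate_control)
from .design import DesignSpec, build_design, write_events
from .glm import (condition_stats, deconvolve_hrf, fit_trial_amplitudes,
                  mean_tuning, pool_and_normalize_hrf, save_amplitudes)
from .preference import (bin_profile, profiles_to_frame, responsive_mask,
                         slope_difference_test, voxel_preferences)
from .preprocess import PreprocessConfig, preprocess_run
from .retinotopy import periodic_fit, select_by_coherence
from .synth import (canonical_hrf, make_population, simulate_preference_profiles,
                    simulate_retinotopy_run, simulate_runs)

__all__ = ["AnalysisConfig", "stage_seeds", "run_pipeline", "write_bundle"]

_STAGES = ("design", "population", "noise", "permutations", "resampling")


def stage_seeds(seed) -> dict:
    """Named per-stage seeds derived deterministically from the master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; sub-configs validate themselves."""

    experiment: int = 1
    seed: int = 0
    design: DesignSpec | None = None
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    n_voxels: int = 120
    population: dict = field(default_factory=dict)
    baseline: float = 1000.0
    coherence_threshold: float = 0.25
    preference: dict = field(default_factory=lambda: {
        "n_bins": 10, "n_drop": 2, "r2_threshold": 0.25,
        "n_iterations": 10_000, "n_subjects": 6,
        "slope_high_log2": 0.1, "slope_low_log2": 0.2,
        "noise_sd_log2": 0.3,
    })
    retinotopy: dict = field(default_factory=lambda: {
        "n_cycles": 8, "cycle_s": 64.0})

    def resolved_design(self) -> DesignSpec:
        if self.design is not None:
            return self.design
        if self.experiment == 1:
            return DesignSpec.experiment1()
        if self.experiment == 2:
            return DesignSpec.experiment2()
        raise ValueError(f"unknown experiment {self.experiment}")


def run_pipeline(config: AnalysisConfig, outdir=None) -> dict:
    """Synthesize one session, analyze it through every stage, and return the
    result bundle (optionally writing it to ``outdir``)."""
    seeds = stage_seeds(config.seed)
    spec = config.resolved_design()
    events = build_design(spec, seed=seeds["design"])
    pop = make_population(config.n_voxels, seed=seeds["population"],
                          luminances=spec.luminances, **config.population)
    hrf_true = canonical_hrf()
    runs, truth = simulate_runs(events, pop, hrf_true, spec,
                                seed=seeds["noise"], baseline=config.baseline)
    pre_cfg = config.preprocessing
    pre = [preprocess_run(ts, pre_cfg) for ts in runs]
    cutoff = pre_cfg.highpass_cutoff_hz
    hrf_by_cond = deconvolve_hrf(pre, events, highpass_cutoff_hz=cutoff)
    hrf = pool_and_normalize_hrf(hrf_by_cond)
    amps = fit_trial_amplitudes(pre, events, hrf, highpass_cutoff_hz=cutoff)
    tuning = mean_tuning(amps)

    dec_cfg = DecoderConfig(max_active=config.decoder.max_active,
                            n_permutations=config.decoder.n_permutations,
                            normalization=config.decoder.normalization,
                            seed=seeds["permutations"])
    decoding = {}
    if config.experiment == 1:
        decoding["within"] = leave_one_run_out(amps, "speed", dec_cfg)
        decoding["permuted"] = permutation_chance(amps, "speed", dec_cfg)
        decoding["univariate"] = univariate_control(amps, "speed", dec_cfg)
    else:
        hi, lo = max(spec.luminances), min(spec.luminances)
        for train, test in [(hi, hi), (hi, lo), (lo, lo), (lo, hi),
                            ("all", hi), ("all", lo)]:
            res = cross_condition(amps, "speed", train, test, dec_cfg)
            decoding[res.regime] = res
        decoding["luminance_binary"] = decode_binary(amps, "luminance", dec_cfg)

    # eccentricity preference maps for this session (both luminances present)
    pref_cfg = config.preference
    stats = condition_stats(amps)
    mask = responsive_mask(amps, pref_cfg["r2_threshold"])
    session_profiles = []
    for lum in stats.luminances:
        prefs = voxel_preferences(stats, mask=mask, luminance=lum)
        session_profiles.append(bin_profile(
            prefs, pop.eccentricity_mm, n_bins=pref_cfg["n_bins"],
            n_drop=pref_cfg["n_drop"], ecc_range=(0, pop.cortical_extent_mm),
            luminance=float(lum)))

    # cohort-level slope test from profile-level synthesis
    usable_bins = pref_cfg["n_bins"] - pref_cfg["n_drop"]
    prof_hi, prof_lo = simulate_preference_profiles(
        n_subjects=pref_cfg["n_subjects"], n_bins=usable_bins,
        slope_high_log2=pref_cfg["slope_high_log2"],
        slope_low_log2=pref_cfg["slope_low_log2"],
        noise_sd_log2=pref_cfg["noise_sd_log2"], seed=seeds["resampling"])
    slope_test = slope_difference_test(
        prof_hi, prof_lo, n_iterations=pref_cfg["n_iterations"],
        seed=seeds["resampling"])

    retino_ts = simulate_retinotopy_run(
        config.retinotopy["n_cycles"], config.retinotopy["cycle_s"],
        spec.tr_seconds, pop, seed=seeds["noise"])
    retino = periodic_fit(preprocess_run(retino_ts, PreprocessConfig(psc=False)),
                          config.retinotopy["n_cycles"])
    retino_mask = select_by_coherence(retino, config.coherence_threshold)

    bundle = {
        "config": config,
        "seeds": seeds,
        "events": events,
        "population": pop,
        "runs": runs,
        "ground_truth": truth,
        "hrf": hrf,
        "amplitudes": amps,
        "tuning": tuning,
        "decoding": decoding,
        "session_profiles": session_profiles,
        "cohort_profiles": (prof_hi, prof_lo),
        "slope_test": slope_test,
        "retinotopy": retino,
        "retinotopy_mask": retino_mask,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def bundle_summary(bundle: dict) -> dict:
    """JSON-serializable summary of a result bundle (deterministic layout)."""
    cfg = bundle["config"]
    return {
        "version": __version__,
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "stage_seeds": bundle["seeds"],
        "decoder": asdict(cfg.decoder),
        "preprocessing": asdict(cfg.preprocessing),
        "n_voxels": cfg.n_voxels,
        "decoding": {name: res.summary()
                     for name, res in bundle["decoding"].items()},
        "slope_test": bundle["slope_test"].summary(),
        "n_retinotopic_voxels": int(bundle["retinotopy_mask"].sum()),
        "tuning": bundle["tuning"].round(10).to_dict(orient="list"),
    }


def write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_events(bundle["events"], out / "events.tsv")
    save_timeseries(bundle["runs"], out / "bold.h5")
    save_amplitudes(bundle["amplitudes"], out / "amplitudes.h5")
    bundle["tuning"].to_csv(out / "tuning.tsv", sep="\t", index=False)
    frames = [res.to_frame() for res in bundle["decoding"].values()]
    pd.concat(frames).to_csv(out / "decoding.tsv", sep="\t", index=False)
    profiles = list(bundle["session_profiles"]) \
        + list(bundle["cohort_profiles"][0]) + list(bundle["cohort_profiles"][1])
    profiles_to_frame(profiles).to_csv(out / "profiles.tsv", sep="\t",
                                       index=False)
    bundle["retinotopy"].to_frame().to_csv(out / "retinotopy.tsv", sep="\t",
                                           index=False)
    with open(out / "slope_test.json", "w") as f:
        json.dump(bundle["slope_test"].summary(), f, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as f:
        json.dump(bundle_summary(bundle), f, indent=2, sort_keys=True)
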