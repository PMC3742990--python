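import numpy as np
import pytest

import boldmvpa as bm


@pytest.fixture(scope="session")
def exp1_spec():
    return bm.DesignSpec()


@pytest.fixture(scope="session")
def noiseless_session(exp1_spec):
    """Small noiseless session (baseline 0): the exact-recovery workhorse."""
    events = bm.build_design(exp1_spec, seed=101)
    pop = bm.make_population(8, seed=102, noise_sd=0.0, drift_order=0)
    hrf = bm.canonical_hrf()
    runs, truth = bm.simulate_runs(events, pop, hrf, exp1_spec, seed=103)
    return {"events": events, "pop": pop, "hrf": hrf, "runs": runs,
            "truth": truth, "spec": exp1_spec}


@pytest.fixture(scope="session")
def noisy_session(exp1_spec):
    """Generator-default session through the full preprocessing + GLM chain."""
    events = bm.build_design(exp1_spec, seed=201)
    pop = bm.make_population(120, seed=202)
    hrf = bm.canonical_hrf()
    runs, truth = bm.simulate_runs(events, pop, hrf, exp1_spec, seed=203,
                                   baseline=1000.0)
    pre = [bm.preprocess_run(ts) for ts in runs]
    cutoff = 0.025
    hrf_est = bm.pool_and_normalize_hrf(
        bm.deconvolve_hrf(pre, events, highpass_cutoff_hz=cutoff))
    amps = bm.fit_trial_amplitudes(pre, events, hrf_est,
                                   highpass_cutoff_hz=cutoff)
    return {"events": events, "pop": pop, "runs": pre, "truth": truth,
            "amps": amps, "spec": exp1_spec}


@pytest.fixture(scope="session")
def exp2_amps():
    """Experiment-2-style session (blocked luminance) with a luminance pattern."""
    spec = bm.DesignSpec.experiment2()
    events = bm.build_design(spec, seed=301)
    pop = bm.make_population(100, seed=302, luminances=spec.luminances,
                             luminance_pattern_sd=5.0)
    runs, _ = bm.simulate_runs(events, pop, bm.canonical_hrf(), spec,
                               seed=303, baseline=1000.0)
    pre = [bm.preprocess_run(ts) for ts in runs]
    hrf = bm.pool_and_normalize_hrf(
        bm.deconvolve_hrf(pre, events, highpass_cutoff_hz=0.025))
    return bm.fit_trial_amplitudes(pre, events, hrf, highpass_cutoff_hz=0.025)


def simulate_session_amps(seed, n_voxels=120, experiment=1, **pop_kw):
    """Fresh synthesized + analyzed session; helper for replicate loops."""
    spec = (bm.DesignSpec() if experiment == 1 else bm.DesignSpec.experiment2())
    ss = np.random.SeedSequence(seed).spawn(3)
    ints = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    events = bm.build_design(spec, seed=ints[0])
    pop_kw.setdefault("luminances", spec.luminances)
    pop = bm.make_population(n_voxels, seed=ints[1], **pop_kw)
    runs, truth = bm.simulate_runs(events, pop, bm.canonical_hrf(), spec,
                                   seed=ints[2], baseline=1000.0)
    pre = [bm.preprocess_run(ts) for ts in runs]
    hrf = bm.pool_and_normalize_hrf(
        bm.deconvolve_hrf(pre, events, highpass_cutoff_hz=0.025))
    amps = bm.fit_trial_amplitudes(pre, events, hrf, highpass_cutoff_hz=0.025)
    return amps, truth
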