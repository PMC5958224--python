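import numpy as np
import pytest

from fluorpheno import fluorsim, imaging, phenoml
from fluorpheno.fluorsim import (
    DroughtPreset,
    NoiseModel,
    RosetteSpec,
    control_preset,
    generate_rosette,
    make_truth,
    simulate_multicolor,
    simulate_stack,
)
from fluorpheno.protocol import default_quenching_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_quenching_protocol()


@pytest.fixture(scope="session")
def square_mask():
    """A 20x20 plant block inside a 32x32 image: spatially uniform ROI."""
    mask = np.zeros((32, 32), dtype=bool)
    mask[6:26, 6:26] = True
    return mask


@pytest.fixture(scope="session")
def uniform_truth(square_mask):
    """Control physiology with no between-plant effect: every map is flat
    at the baseline (fvfm 0.85, npq_ss 1.2, phi_ss 0.55, Fm 1000)."""
    return make_truth(square_mask, control_preset(between_plant_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def clean_stack(uniform_truth, protocol):
    return simulate_stack(uniform_truth, protocol, NoiseModel.none())


@pytest.fixture(scope="session")
def clean_trace(clean_stack, square_mask):
    return imaging.extract_trace(clean_stack, square_mask)


@pytest.fixture(scope="session")
def clean_signals(clean_trace, protocol):
    from fluorpheno.fluorparams import extract_basic_signals

    return extract_basic_signals(clean_trace, protocol)


@pytest.fixture(scope="session")
def clean_multicolor(uniform_truth):
    return simulate_multicolor(uniform_truth, NoiseModel.none())


@pytest.fixture(scope="session")
def cohort_table():
    """Cached factory for simulated-cohort feature tables, shared between
    the acceptance tests and the slower property tests."""
    import warnings

    cache = {}

    def build(preset: str, seed: int, n: int = 54):
        key = (preset, seed, n)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                samples = fluorsim.simulate_cohort(n, n, preset, seed=seed)
                cache[key] = phenoml.cohort_feature_table(samples)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def small_cohort():
    """12-plant severe cohort, reused by extraction/selection tests."""
    return fluorsim.simulate_cohort(6, 6, "severe", seed=11)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phenoml.cohort_feature_table(small_cohort)


def model_curves(truth, protocol, times):
    """Independent closed-form evaluation of the forward model for a
    uniform truth: returns (Fm_prime(t), Ft(t)) arrays for actinic-phase
    times. Written from the model definition, separate from the simulator
    rendering code."""
    fm = truth.mean("fm_amp")
    npq_ss = truth.mean("npq_ss")
    phi_ss = truth.mean("phi_ss")
    t_on = protocol.actinic_on_s
    times = np.asarray(times, dtype=float)
    npq_t = npq_ss * (1.0 - np.exp(-truth.k_ind * (times - t_on)))
    fm_prime = fm / (1.0 + npq_t)
    phi_t = phi_ss + (truth.phi0 - phi_ss) * np.exp(-truth.k_p * (times - t_on))
    return fm_prime, fm_prime * (1.0 - phi_t)
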