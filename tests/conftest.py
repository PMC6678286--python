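import numpy as np
import pytest

from repscreen import SimulationConfig, generate_paired_cohort
from repscreen.cohort import PairedExpressionCohort
from repscreen.signatures import preprocess_floor


@pytest.fixture
def noiseless_cfg() -> SimulationConfig:
    """Deterministic planted cohort: exact ratios, no noise."""
    # baseline well above the floor so planted down-probes are not clipped
    return SimulationConfig(
        n_patients=6, n_probes=200, n_up=10, n_down=10,
        effect_size=1.5, noise_sd=0.0, patient_sd=0.0,
        baseline_mean=10.0, baseline_sd=0.5, seed=7,
    )


@pytest.fixture
def noiseless_cohort(noiseless_cfg) -> PairedExpressionCohort:
    return preprocess_floor(generate_paired_cohort(noiseless_cfg))


@pytest.fixture
def planted_cohort() -> PairedExpressionCohort:
    """Realistic planted cohort at study conditions but smaller probe count."""
    cfg = SimulationConfig(
        n_patients=24, n_probes=1000, n_up=30, n_down=30,
        effect_size=1.5, noise_sd=0.5, seed=3,
    )
    return preprocess_floor(generate_paired_cohort(cfg))


def make_cohort(intensities, pairing=None, probe_ids=None) -> PairedExpressionCohort:
    """Hand-built cohort from a probes x samples array (patients are
    consecutive (tumor, normal) column pairs)."""
    intensities = np.asarray(intensities, dtype=float)
    n_probes, n_samples = intensities.shape
    assert n_samples % 2 == 0
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = []
    pairing = {}
    for k in range(n_samples // 2):
        sample_ids += [f"pt{k}_T", f"pt{k}_N"]
        pairing[f"pt{k}"] = (f"pt{k}_T", f"pt{k}_N")
    return PairedExpressionCohort(
        probe_ids=probe_ids, intensities=intensities,
        sample_ids=sample_ids, pairing=pairing,
    )
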