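import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipidims import PipelineConfig, SyntheticConfig, run_pipeline

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_config(**overrides) -> SyntheticConfig:
    """A fast small-panel study for structural tests."""
    defaults = dict(n_extract_ions=12, n_ims_ions=10, n_shared=5,
                    mz_range=(600.0, 700.0), n_replicates=3,
                    noise_sd=0.0, sigma_log=0.0, seed=11)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def zero_noise_result():
    """Full default-design study at zero noise, run through the pipeline."""
    cfg = SyntheticConfig(noise_sd=0.0, sigma_log=0.0, seed=7)
    return run_pipeline(PipelineConfig(synthetic=cfg, seed=7))


def planted_expectation(ion):
    """(direction, progression, recovery) implied by a planted ion."""
    if ion.category == "stable":
        return ("unchanged", "n/a", "n/a")
    direction, progression = ion.category.split("_")
    return (direction, progression, ion.recovery)


def match_patterns_to_truth(result, modality, mz_tol=0.1):
    """Pair classified patterns with planted ions; yields (expected, got)."""
    planted = list(result.truth.members(modality))
    for mz, pat in result.patterns[modality].items():
        ion = min(planted, key=lambda x: abs(x.mz - mz))
        if abs(ion.mz - mz) > mz_tol:
            continue
        yield planted_expectation(ion), (pat.direction, pat.progression, pat.recovery)
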