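import numpy as np
import pytest

from mammclock.datamodel import AgeTransformSpec, BetaMatrix, SampleRecord
from mammclock.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_signal_data():
    """Compact dataset with a clear age signal: 30 samples x 120 probes."""
    cfg = SimConfig(
        n_per_species={"asian_elephant": 30},
        age_range={"asian_elephant": (1.0, 60.0)},
        n_probes=120,
        n_age_probes=30,
        n_sex_probes=10,
        n_species_probes=0,
        age_effect_sd=2.0,
        sex_effect=2.5,
        noise_sd=0.3,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def two_species_data():
    """Two cohorts with species offsets and sex effects: 60 samples."""
    cfg = SimConfig(
        n_per_species={"asian_elephant": 30, "african_elephant": 30},
        age_range={"asian_elephant": (2.0, 70.0), "african_elephant": (1.0, 50.0)},
        n_probes=150,
        n_age_probes=30,
        n_sex_probes=15,
        n_species_probes=20,
        age_effect_sd=2.0,
        sex_effect=2.5,
        species_effect=3.0,
        noise_sd=0.3,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture()
def identity_transform():
    return AgeTransformSpec(kind="identity")


def make_beta(values, probe_prefix="cg", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        [f"{probe_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values,
    )


def make_samples(ages, species="asian_elephant", sexes=None, confidences=None):
    n = len(ages)
    sexes = sexes or ["F"] * n
    confidences = confidences or [100.0] * n
    return [
        SampleRecord(
            sample_id=f"s{i}",
            species=species if isinstance(species, str) else species[i],
            sex=sexes[i],
            age_years=float(ages[i]),
            age_confidence=float(confidences[i]),
        )
        for i in range(n)
    ]
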