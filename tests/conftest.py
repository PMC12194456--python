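import numpy as np
import pytest

from dkabase import FluidRegistry, SyntheticCohortConfig, TimepointPanel, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return FluidRegistry.default()


@pytest.fixture
def reference_panel():
    """A normal-ish adult plasma panel used by the worked SIG example."""
    return TimepointPanel(
        na=140, k=4, ca=4.4, mg=1.6, cl=105, lactate=1,
        ph=7.40, paco2=40, albumin=42, phosphate=1.2,
    )


@pytest.fixture
def dka_panel():
    """An admission panel meeting the DKA definition (severe ketoacidosis)."""
    return TimepointPanel(
        ph=7.10, paco2=16.4, hco3_measured=7.2, na=135, k=4.4, ca=4.6, mg=1.6,
        cl=106, lactate=2.1, albumin=38, phosphate=1.2, glucose=426,
        hematocrit=40.9, urine_ketones=3, urea=56, creatinine=1.5,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort (22 + 13), shared across tests."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


def random_panels(n, seed=0):
    """Random but physiologically bounded panels for oracle sweeps."""
    rng = np.random.default_rng(seed)
    panels = []
    for _ in range(n):
        panels.append(TimepointPanel(
            ph=rng.uniform(6.8, 7.6),
            paco2=rng.uniform(10, 60),
            na=rng.uniform(120, 150),
            k=rng.uniform(2.5, 6.5),
            ca=rng.uniform(3.5, 5.5),
            mg=rng.uniform(1.0, 2.2),
            cl=rng.uniform(85, 125),
            lactate=rng.uniform(0.5, 10),
            albumin=rng.uniform(20, 50),
            phosphate=rng.uniform(0.5, 2.5),
        ))
    return panels
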