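import numpy as np
import pytest

from gwinet import CohortConfig, MeasureSpec, StandardCurve, default_study_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_catalog():
    return [
        MeasureSpec("IL-15", "cytokine", 0.24, 0.199, panel="both"),
        MeasureSpec("RDW", "cbc", 12.74, 0.80),
        MeasureSpec("MFI_general_fatigue", "symptom", 30.0, 18.0, bounds=(0, 100)),
    ]


@pytest.fixture
def small_config(small_catalog):
    return CohortConfig(
        measure_catalog=small_catalog,
        group_sizes={"HC": 10, "GWI_L": 8, "GWI_H": 9},
        site_split=0.5,
        missing_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def study_config():
    return default_study_config(seed=314159)


@pytest.fixture
def fivepl_curve():
    return StandardCurve(
        model="logistic5p",
        params={"a": 30000.0, "d": 50.0, "c": 100.0, "b": 1.2, "g": 1.0},
        calibrated_range=(0.5, 1000.0),
    )
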