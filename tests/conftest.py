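import numpy as np
import pandas as pd
import pytest

from trialecon import ArmSpec, CohortConfig, generate_cohort, impose_missingness


@pytest.fixture(scope="session")
def null_config():
    """Three identical arms: every contrast's true value is null."""
    return CohortConfig(
        arms=[ArmSpec("UC", 120), ArmSpec("UC+MI", 120), ArmSpec("UC+SVAI", 120)],
        seed=11, missingness_rates={},
    )


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return generate_cohort(null_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Small three-arm cohort with modest true contrasts, complete data."""
    cfg = CohortConfig(
        arms=[
            ArmSpec("UC", 80),
            ArmSpec("UC+MI", 80, rtw_hazard_ratio=1.2, intervention_unit_cost=53.0),
            ArmSpec("UC+SVAI", 80, rtw_hazard_ratio=1.3, intervention_unit_cost=78.0),
        ],
        seed=3, missingness_rates={},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def missing_cohort():
    """Cohort with the default MAR overlay applied."""
    cfg = CohortConfig(
        arms=[ArmSpec("UC", 100), ArmSpec("UC+MI", 100), ArmSpec("UC+SVAI", 100)],
        seed=8,
    )
    return impose_missingness(generate_cohort(cfg), cfg)


def toy_survival(times, events, arms=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "id": [f"S{i}" for i in range(len(times))],
        "time": times, "event": events,
    })
    df["arm"] = arms if arms is not None else "UC"
    return df


def assert_close(a, b, tol):
    assert abs(a - b) <= tol, f"{a} vs {b} (tol {tol})"
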