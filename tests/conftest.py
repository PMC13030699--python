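import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def example_plate() -> pd.DataFrame:
    """One plate whose blank/control means match the worked example:
    blank (0.1, 0.05), control (1.2, 0.4), control signal 0.75."""
    rows = [
        ("p1", "B1", "blank", None, 0.08, 0.04),
        ("p1", "B2", "blank", None, 0.12, 0.06),
        ("p1", "C1", "control", None, 1.1, 0.35),
        ("p1", "C2", "control", None, 1.3, 0.45),
        ("p1", "T1", "treated", "mix-a", 0.8, 0.3),
        ("p1", "T2", "treated", "mix-a", 1.2, 0.4),
        ("p1", "T3", "treated", "blank-like", 0.1, 0.05),
    ]
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "condition_id", "a570", "a600"]
    )


@pytest.fixture
def truth24():
    from mixtox.synthetic import default_ground_truth

    return default_ground_truth(24)
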