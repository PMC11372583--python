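import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from affectvar.core_data import EMOTION_ITEMS

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def ratings_frame(values_by_session: dict[int, list[int]], pid: str = "p1") -> pd.DataFrame:
    """Long-format ratings for one participant: session -> 16 item values
    in the fixed item order."""
    rows = []
    for session, values in values_by_session.items():
        assert len(values) == 16
        for item, rating in zip(EMOTION_ITEMS, values):
            rows.append((pid, session, item, rating))
    return pd.DataFrame(rows, columns=["participant_id", "session", "item", "rating"])


def quadrant_ratings(pa, pd_, na, nd, sessions=range(1, 15), pid: str = "p1") -> pd.DataFrame:
    """Ratings where every item of a quadrant gets that quadrant's value.

    pa/pd_/na/nd may be scalars (constant over sessions) or sequences of
    per-session values.
    """
    from affectvar.core_data import ITEM_QUADRANTS

    sessions = list(sessions)

    def per_session(v):
        return list(v) if np.ndim(v) else [v] * len(sessions)

    vals = {"pa": per_session(pa), "pd": per_session(pd_), "na": per_session(na), "nd": per_session(nd)}
    rows = []
    for k, session in enumerate(sessions):
        for item in EMOTION_ITEMS:
            rows.append((pid, session, item, vals[ITEM_QUADRANTS[item]][k]))
    return pd.DataFrame(rows, columns=["participant_id", "session", "item", "rating"])


def random_problem(rng: np.random.Generator, n: int = 200, p: int = 4):
    """A random well-conditioned RegressionProblem built from raw data."""
    from affectvar.relative_importance import RegressionProblem

    X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
    beta = rng.normal(0, 0.5, size=p)
    y = X @ beta + rng.standard_normal(n) * 2.0
    data = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    data["y"] = y
    return RegressionProblem.from_dataframe(data, "y", [f"x{i}" for i in range(p)]), data


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by pipeline-level tests."""
    from affectvar.synthetic_data import GeneratorConfig, simulate_study

    config = GeneratorConfig(n_participants=60, careless_fraction=3 / 60)
    return simulate_study(config, seed=11)
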