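import numpy as np
import pandas as pd
import pytest

from hiermove.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """34 individuals, ~60 rows each — quick end-to-end fixture."""
    return simulate_dataset(SimConfig(seed=11, mean_locations=60))


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 individuals, ~40 rows each — for oracle-level comparisons."""
    return simulate_dataset(
        SimConfig(seed=3, n_individuals=5, mean_locations=40, sigma_u=1.0)
    )


@pytest.fixture(scope="session")
def raw_locations():
    """Raw Argos-like location table with multiple fixes per day."""
    rng = np.random.default_rng(5)
    rows = []
    t0 = pd.Timestamp("2010-06-01", tz="UTC")
    for tag in ("A1", "B2"):
        t = t0
        for day in range(30):
            for _ in range(int(rng.integers(1, 4))):
                rows.append(
                    {
                        "tag_id": tag,
                        "timestamp": t
                        + pd.Timedelta(days=day, hours=int(rng.integers(0, 24))),
                        "lon": float(-130 + 10 * rng.uniform()),
                        "lat": float(25 + 10 * rng.uniform()),
                        "argos_class": str(
                            rng.choice(["3", "2", "1", "0", "A", "B", "Z"])
                        ),
                    }
                )
    return pd.DataFrame(rows)
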