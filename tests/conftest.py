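import numpy as np
import pandas as pd
import pytest

from cleanstation.synthetic import Baselines, EffectProfile, StudyDesign, simulate_study


@pytest.fixture(scope="session")
def light_baselines():
    """Baselines with a thin client community, for fast simulation."""
    return Baselines(client_abundance_per_hr=6.0)


@pytest.fixture(scope="session")
def decline_study(light_baselines):
    """One default-scenario study (40% behavioural decline, +3 cm FID)."""
    effects = EffectProfile.default_decline(baselines=light_baselines)
    return simulate_study(StudyDesign(), effects, seed=42)


@pytest.fixture(scope="session")
def null_study(light_baselines):
    """A study with no treatment effects anywhere."""
    effects = EffectProfile.null(baselines=light_baselines)
    return simulate_study(StudyDesign(), effects, seed=42)


@pytest.fixture()
def mixed_model_data():
    """Balanced 10-station, 4-replicate response with known structure."""

    def _make(seed, beta_second=0.0, station_sd=1.0, resid_sd=1.0, mu=5.0):
        rng = np.random.default_rng(seed)
        stations = [f"S{i:02d}" for i in range(10)]
        reps = ["before", "first", "second", "after"]
        u = dict(zip(stations, rng.normal(0.0, station_sd, len(stations))))
        rows = []
        for s in stations:
            for r in reps:
                y = mu + (beta_second if r == "second" else 0.0)
                y += u[s] + rng.normal(0.0, resid_sd)
                rows.append(
                    {
                        "station_id": s,
                        "replicate": r,
                        "y": y,
                        "area_group": f"g{int(s[1:]) % 3}",
                    }
                )
        return pd.DataFrame(rows)

    return _make
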