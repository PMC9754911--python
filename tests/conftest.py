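import numpy as np
import pandas as pd
import pytest

from albicoord.simulate import SimulationConfig, simulate_study, simulate_traits

T0 = pd.Timestamp("2010-12-16")


def make_bouts(spec, bird_id="B1", start=T0):
    """Bout frame from a list of (state, hours)."""
    rows = []
    t = start
    for state, hours in spec:
        end = t + pd.Timedelta(hours=hours)
        rows.append(
            {
                "bird_id": bird_id,
                "state": state,
                "start": t,
                "end": end,
                "duration_h": hours,
            }
        )
        t = end
    return pd.DataFrame(rows)


def make_trips(durations_h, bird_id="B1", pair_id="P0", season=2010,
               start=T0, gap_h=0.0, source="observed", stage="unassigned"):
    """Trip frame with given durations laid end to end (gap_h between)."""
    rows = []
    t = start
    for i, d in enumerate(durations_h):
        end = t + pd.Timedelta(hours=float(d))
        rows.append(
            {
                "bird_id": bird_id,
                "pair_id": pair_id,
                "season": season,
                "index": i,
                "start": t,
                "end": end,
                "duration_h": float(d),
                "source": source,
                "stage": stage,
            }
        )
        t = end + pd.Timedelta(hours=float(gap_h))
    columns = [
        "bird_id", "pair_id", "season", "index", "start", "end",
        "duration_h", "source", "stage",
    ]
    return pd.DataFrame(rows, columns=columns)


def zero_effect_config(**overrides):
    """All betas and random SDs zero: every trip in a stage is identical."""
    kwargs = dict(
        n_pairs=1,
        n_years=1,
        n_dual_tagged=0,
        sigma_pair_intercept=0.0,
        sigma_pair_slope=0.0,
        sigma_year=0.0,
        sigma_resid=0.0,
        overlap_lag_mean_h=0.0,
        deployment_offset_min_d=0.0,
        deployment_offset_max_d=0.0,
        beta={k: 0.0 for k in SimulationConfig().beta},
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def low_noise_config(**overrides):
    """Variances small enough that every trip clears the 12-h flight ceiling.

    sqrt-durations stay within ~4 combined SD of the stage intercepts
    (brooding 8.1 - 4*1.3 > sqrt(12)), so schedules are exactly
    resolvable by segmentation.
    """
    kwargs = dict(
        n_dual_tagged=0,
        sigma_pair_intercept=0.4,
        sigma_pair_slope=0.05,
        sigma_year=0.2,
        sigma_resid=1.2,
        deployment_offset_min_d=0.0,
        deployment_offset_max_d=0.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    cfg = SimulationConfig(n_pairs=6, n_years=2, n_dual_tagged=2)
    return cfg, simulate_study(cfg, np.random.default_rng(11))


@pytest.fixture()
def pair_traits():
    cfg = zero_effect_config(first_season=2010)
    return cfg, simulate_traits(cfg, np.random.default_rng(1))[0]
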