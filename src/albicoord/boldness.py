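"""Boldness scores from repeated human-approach assays.

Incubating birds are approached by a human from 5 m and their response
graded on an ordinal 0-5 scale (0 = no response, 1 = raises head,
2 = rises onto tarsus, 3 = vocalizes, 4 = stands up, 5 = vacates nest).
Repeated assays per bird, made by different observers over the years,
are reduced to a single continuous score per bird by a linear model

    response ~ observation_number + observer + bird

with sum-to-zero contrasts for the observer and bird factors, so the
per-bird estimates share a common reference.  Observation number enters
as a continuous covariate absorbing habituation across repeated assays.
The bird estimates are mean-centered across birds; the centered
estimates are the boldness scores (population mean 0, bolder birds
positive).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["score_boldness"]

VALID_RESPONSES = frozenset(range(6))


def score_boldness(observations: pd.DataFrame) -> pd.DataFrame:
    """Fit the scoring model and return one mean-centered score per bird.

    Parameters
    ----------
    observations
        Columns ``bird_id``, ``observer_id``, ``observation_number``
        (rank of the assay for that bird, >= 1), ``response`` (0-5).

    Returns
    -------
    DataFrame with columns ``bird_id``, ``boldness_score``, sorted by
    bird.  Scores sum to zero over scored birds.
    """
    if len(observations) == 0:
        raise ValueError("no boldness observations")
    obs = observations.copy()
    bad = ~obs["response"].isin(VALID_RESPONSES)
    if bad.any():
        raise ValueError(
            f"responses outside the 0-5 scale: {sorted(obs.loc[bad, 'response'].unique())}"
        )
    birds = sorted(obs["bird_id"].unique())
    if len(birds) < 2:
        raise ValueError("boldness scoring needs at least two birds")

    # warn on bird/observer aliasing: a bird seen by exactly one observer
    # who saw no other bird yields an unidentifiable contrast
    by_bird = obs.groupby("bird_id")["observer_id"].agg(set)
    by_observer = obs.groupby("observer_id")["bird_id"].agg(set)
    for bird, seen_by in by_bird.items():
        if len(seen_by) == 1:
            (o,) = seen_by
            if len(by_observer[o]) == 1:
                warnings.warn(
                    f"bird {bird} confounded with observer {o}; "
                    "its score is an aliased contrast",
                    stacklevel=2,
                )

    observers = sorted(obs["observer_id"].unique())
    n = len(obs)
    # sum-to-zero coded design built explicitly: the last level of each
    # factor is minus the sum of the others
    bird_idx = obs["bird_id"].map({b: i for i, b in enumerate(birds)}).to_numpy()
    obsr_idx = obs["observer_id"].map({o: i for i, o in enumerate(observers)}).to_numpy()

    def sum_coded(idx, n_levels):
        if n_levels < 2:
            return np.empty((n, 0))
        x = np.zeros((n, n_levels - 1))
        for j in range(n_levels - 1):
            x[idx == j, j] = 1.0
        x[idx == n_levels - 1, :] = -1.0
        return x

    xb = sum_coded(bird_idx, len(birds))
    xo = sum_coded(obsr_idx, len(observers))
    X = np.column_stack(
        [np.ones(n), obs["observation_number"].to_numpy(dtype=float), xo, xb]
    )
    fit = sm.OLS(obs["response"].to_numpy(dtype=float), X).fit()
    eff = fit.params[2 + xo.shape[1] :]
    effects = np.append(eff, -np.sum(eff))  # implied last level
    scores = effects - np.mean(effects)
    return pd.DataFrame({"bird_id": birds, "boldness_score": scores})
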