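"""Shared reference oracles and fixtures used by several test modules."""

import datetime as dt

import numpy as np
import pandas as pd

from actimediate.accelerometry import EpochSeries

MONDAY = dt.date(2024, 3, 4)


def series_of(counts, date=MONDAY, epoch_len=15):
    return EpochSeries("P1", date, np.asarray(counts), epoch_len)


def brute_force_nonwear(counts, run_epochs):
    """Reference run-length scanner, independent of the vectorized path."""
    wear = np.ones(len(counts), dtype=bool)
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            j = i
            while j < len(counts) and counts[j] == 0:
                j += 1
            if j - i >= run_epochs:
                wear[i:j] = False
            i = j
        else:
            i += 1
    return wear


def exact_mediation_data(seed=0, n=144, a=2.0, b=0.5, c_prime=10.0):
    """Noise-free linear mediation structure on a clustered layout.

    The wear covariates differ between the mediator and outcome stages, so
    both models are exact fits without the design becoming collinear.
    """
    rng = np.random.default_rng(seed)
    n_sch = 12
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "school_id": np.repeat([f"S{k}" for k in range(n_sch)], n // n_sch),
            "arm": np.repeat(np.arange(n_sch) % 2, n // n_sch),
            "sex": rng.integers(0, 2, n),
            "ses_decile": rng.integers(1, 11, n),
            "wear_t0": rng.normal(750, 50, n),
            "wear_t2": rng.normal(750, 50, n),
            "barriers_t0": rng.normal(20, 4, n),
            "sedentary_t0": rng.normal(520, 80, n),
        }
    )
    df["barriers_t1"] = a * df["arm"] + 0.5 * df["barriers_t0"] + 0.01 * df["wear_t0"]
    df["sedentary_t2"] = (
        c_prime * df["arm"]
        + b * df["barriers_t1"]
        + 0.7 * df["sedentary_t0"]
        + 3.0 * df["sex"]
        + 1.0 * df["ses_decile"]
        + 0.02 * df["wear_t2"]
    )
    return df
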