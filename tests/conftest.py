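"""Shared fixtures: small simulated worlds reused across test modules."""

import dataclasses

import numpy as np
import pytest

import vocalaccom as va


@pytest.fixture(scope="session")
def small_scenario():
    """Default social scenario shrunk to a fast schedule (6 weeks, 8 calls)."""
    cfg = va.default_scenario()
    schedule = [("Before", 0.0, 8), ("NewPhys", 0.5, 8)] + [
        ("NewSoc", float(w), 8) for w in (1, 3, 5, 8, 12, 16)
    ]
    return dataclasses.replace(cfg, schedule=schedule)


@pytest.fixture(scope="session")
def small_table(small_scenario):
    table, truth = va.simulate_features(small_scenario, seed=123)
    return table


@pytest.fixture(scope="session")
def trill_records(small_table):
    """Distance records for trills from the small world, via the pipeline."""
    from vocalaccom.pipeline import run_experiment2

    report = run_experiment2(
        small_table, call_types=("trill",), pa_iter=200, n_boot=100, seed=5
    )
    return report.per_call_type["trill"].records


def make_crossed_scores(
    rng, n_ind=8, n_cond=2, n_calls=20, p=4, effect=0.0, ind_sd=1.0
):
    """Score-space crossed design: strong individual effects, optional
    condition shift on the first two variables."""
    rows, y, g = [], [], []
    for i in range(n_ind):
        mu = rng.normal(0.0, ind_sd, p)
        for c in range(n_cond):
            shift = np.zeros(p)
            if c == 1 and effect:
                shift[:2] = effect
            rows.append(mu + shift + rng.normal(0.0, 1.0, (n_calls, p)))
            y += [c] * n_calls
            g += [i] * n_calls
    return np.vstack(rows), np.array(y), np.array(g)
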