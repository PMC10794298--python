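"""Shared fixtures: small seeded sessions and synthetic random trials."""

from __future__ import annotations

import numpy as np
import pytest

import pursuittrack as pt


@pytest.fixture(scope="session")
def small_config() -> pt.GeneratorConfig:
    """Two repeats per condition: a 12-trial session, defaults otherwise."""
    return pt.GeneratorConfig(seed=101, n_repeats_per_condition=2)


@pytest.fixture(scope="session")
def small_session(small_config) -> list[pt.TrialTrajectory]:
    return pt.generate_session(small_config)


@pytest.fixture(scope="session")
def default_session() -> list[pt.TrialTrajectory]:
    """A full 72-trial session at package defaults."""
    return pt.generate_session(pt.GeneratorConfig(seed=202))


def make_random_series(rng: np.random.Generator, n: int) -> pt.TrialTimeSeries:
    """A smooth random target with a noisy lagged cursor, for oracle tests."""
    x = np.cumsum(rng.uniform(0.5, 1.5, n))
    kernel = np.ones(7) / 7.0
    ty = np.convolve(rng.normal(0.0, 40.0, n + 6), kernel, mode="valid")
    lag = int(rng.integers(0, 6))
    cy = np.roll(ty, lag)
    cy[:lag] = ty[0]
    cy = cy + rng.normal(0.0, 4.0, n)
    return pt.TrialTimeSeries(
        target_x=x, target_y=ty, cursor_x=x.copy(), cursor_y=cy,
        segment=np.array(["random1"] * n, dtype=object),
        condition=pt.Condition("medium", "right"))
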