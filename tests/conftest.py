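"""Shared fixtures: parametric phantom suites with known ground truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fetalweight.phantom import PhantomTruth

#: Seed for the randomized phantom suites (study start month, chosen a priori).
PHANTOM_SUITE_SEED = 20210601


def random_phantom(kind: str, rng: np.random.Generator, speckle: float = 0.0) -> PhantomTruth:
    """Draw one plausible phantom of the given kind at obstetric scale."""
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == "head":
        a = rng.uniform(45.0, 80.0)
        b = a * rng.uniform(0.70, 0.85)
        return PhantomTruth(
            kind="head", semi_major_px=a, semi_minor_px=b,
            rim_thickness_px=rng.uniform(5.0, 9.0), speckle_sigma=speckle, seed=seed,
        )
    if kind == "abdomen":
        a = rng.uniform(60.0, 95.0)
        b = a * rng.uniform(0.80, 0.95)
        return PhantomTruth(
            kind="abdomen", semi_major_px=a, semi_minor_px=b,
            rim_thickness_px=rng.uniform(5.0, 9.0), speckle_sigma=speckle, seed=seed,
        )
    if kind == "femur":
        return PhantomTruth(
            kind="femur", bar_length_px=rng.uniform(50.0, 110.0),
            bar_width_px=rng.uniform(7.0, 13.0), bar_angle_deg=rng.uniform(0.0, 180.0),
            speckle_sigma=speckle, seed=seed,
        )
    raise ValueError(kind)


def phantom_suite(kind: str, n: int, speckle: float = 0.0, seed: int = PHANTOM_SUITE_SEED):
    rng = np.random.default_rng(seed)
    return [random_phantom(kind, rng, speckle) for _ in range(n)]


@pytest.fixture(scope="session")
def clean_head():
    return PhantomTruth(kind="head", semi_major_px=60.0, semi_minor_px=45.0, rim_thickness_px=6.0)


@pytest.fixture(scope="session")
def speckled_head():
    return dataclasses.replace(
        PhantomTruth(kind="head", semi_major_px=60.0, semi_minor_px=45.0, rim_thickness_px=6.0),
        speckle_sigma=0.3, seed=7,
    )
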