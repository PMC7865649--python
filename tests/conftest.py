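"""Shared fixtures and geometry helpers for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from deertrack.geodesy import GeoPoint, local_offset_m, offset_point
from deertrack.localization import GridSpec, Station, build_grid
from deertrack.synthetic import forward_detections, oze_fixture, utokyo_fixture


@pytest.fixture(scope="session")
def utokyo():
    return utokyo_fixture()


@pytest.fixture(scope="session")
def oze():
    return oze_fixture()


@pytest.fixture(scope="session")
def utokyo_grid_small(utokyo) -> GridSpec:
    """Fine 0.5 m lattice over a 600 m square — covers the playground
    triangle with margin at a fraction of the published 1.6 km grid cost."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_grid(list(utokyo.stations), spacing_m=0.5, extent_m=600.0)


def sample_in_triangle(
    rng: np.random.Generator, vertices: list[GeoPoint]
) -> GeoPoint:
    """Uniform point inside the triangle spanned by three positions."""
    ref = vertices[0]
    xy = np.array([local_offset_m(ref, v) for v in vertices])
    a, b = rng.random(2)
    if a + b > 1.0:
        a, b = 1.0 - a, 1.0 - b
    e, n = xy[0] + a * (xy[1] - xy[0]) + b * (xy[2] - xy[0])
    return offset_point(ref, float(e), float(n))


def noise_free_detections(position: GeoPoint, stations: list[Station], speed: float,
                          call_id: str = "call"):
    return forward_detections(position, stations, speed, call_id=call_id)
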