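"""Forward simulator: territorial callers, propagation delays, censoring.

Generates ground-truth calls and the detection tables a recorder deployment
would produce: each station hears a call at emission time + distance/speed
plus Gaussian annotation-timing noise (the dominant error source when start
times are read off spectrograms by hand, about 0.018 s), and only if the
source is within the audible range. Callers are territorial — simultaneous
individuals keep a minimum mutual spacing — and drift between call
intervals as a Gaussian random walk.

Simulation is at the detection-time level; no waveforms are synthesized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geodesy import EarthModel, GeoPoint, flat_earth_distance, offset_point, parse_dms
from .localization import DetectionSet, Station

__all__ = [
    "ScenarioConfig",
    "TrueCall",
    "Fixture",
    "ConfigurationError",
    "audibility",
    "detection_probability",
    "forward_detections",
    "simulate",
    "utokyo_fixture",
    "oze_fixture",
]


class ConfigurationError(ValueError):
    """A scenario cannot be realized (e.g. territories do not fit the arena)."""


@dataclass(frozen=True)
class TrueCall:
    """Ground-truth emitted call: who, where, when."""

    call_id: str
    individual_id: str
    position: GeoPoint
    emission_time_s: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated session.

    Defaults mirror a rutting-season deployment: 0.018 s timing noise,
    450 m reliable detection range, ten-minute call intervals over a
    two-hour session, and three territorial males averaging two calls per
    interval each (six calls per interval in total).
    """

    stations: Sequence[Station]
    speed_mps: float = 340.0
    timing_noise_sd_s: float = 0.018
    detection_range_m: float = 450.0
    n_individuals: int = 3
    min_individual_spacing_m: float = 100.0
    movement_step_sd_m: float = 10.0
    call_rate: float = 2.0  # expected calls per individual per interval
    interval_s: float = 600.0
    duration_s: float = 7200.0
    arena_half_extent_m: float = 300.0
    audibility_model: Literal["step", "three_state"] = "step"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "speed_mps",
            "interval_s",
            "duration_s",
            "arena_half_extent_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "timing_noise_sd_s",
            "detection_range_m",
            "min_individual_spacing_m",
            "movement_step_sd_m",
            "call_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be non-negative")

    @property
    def n_intervals(self) -> int:
        return max(1, int(round(self.duration_s / self.interval_s)))


def detection_probability(
    distance_m: float,
    model: Literal["step", "three_state"] = "step",
    detection_range_m: float = 450.0,
) -> float:
    """Probability that a call at the given range is audible in the recording.

    'step': audible iff within ``detection_range_m``. 'three_state': reliable
    out to 423 m, marginal (p = 0.5) out to 545 m, inaudible beyond —
    a coarse reading of field audibility trials at 181/297/423/545/761 m.
    """
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    if model == "step":
        return 1.0 if distance_m <= detection_range_m else 0.0
    if model == "three_state":
        if distance_m <= 423.0:
            return 1.0
        if distance_m <= 545.0:
            return 0.5
        return 0.0
    raise ValueError(f"unknown audibility model {model!r}")


def audibility(
    distance_m: float,
    model: Literal["step", "three_state"] = "step",
    detection_range_m: float = 450.0,
    rng: np.random.Generator | None = None,
) -> bool:
    """Sample the detected/not-detected flag for one call at one station."""
    p = detection_probability(distance_m, model, detection_range_m)
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    if rng is None:
        rng = np.random.default_rng()
    return bool(rng.random() < p)


def forward_detections(
    position: GeoPoint,
    stations: Sequence[Station],
    speed_mps: float,
    call_id: str = "call",
    emission_time_s: float = 0.0,
    timing_noise_sd_s: float = 0.0,
    detection_range_m: float = float("inf"),
    audibility_model: Literal["step", "three_state"] = "step",
    rng: np.random.Generator | None = None,
    earth: EarthModel = EarthModel(),
) -> DetectionSet:
    """Detection table one call would produce at the given stations.

    Detection time at a station is emission time + distance/speed plus
    optional Gaussian timing noise; stations beyond the audible range are
    omitted. The inverse of localization: with zero noise and no censoring,
    the lags reproduce the exact geometric range differences.
    """
    if rng is None:
        rng = np.random.default_rng()
    det: dict[str, float] = {}
    for st in stations:
        dist = flat_earth_distance(position, st.position, earth)
        heard = audibility(dist, audibility_model, detection_range_m, rng)
        # draw noise unconditionally so censoring does not shift the
        # random stream consumed by later stations
        eps = (
            rng.normal(0.0, timing_noise_sd_s) if timing_noise_sd_s > 0 else 0.0
        )
        if heard:
            det[st.id] = float(emission_time_s + dist / speed_mps + eps)
    return DetectionSet(call_id=call_id, detections=det)


def _place_individuals(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Initial (east, north) positions with territorial spacing, by rejection."""
    placed: list[tuple[float, float]] = []
    h = cfg.arena_half_extent_m
    for _ in range(cfg.n_individuals):
        for _attempt in range(2000):
            e, n = rng.uniform(-h, h, size=2)
            if all(
                math.hypot(e - pe, n - pn) >= cfg.min_individual_spacing_m
                for pe, pn in placed
            ):
                placed.append((float(e), float(n)))
                break
        else:
            raise ConfigurationError(
                f"cannot place {cfg.n_individuals} individuals with "
                f"{cfg.min_individual_spacing_m} m spacing in a "
                f"{2 * h:.0f} m arena"
            )
    return np.array(placed).reshape(cfg.n_individuals, 2)


def _step_positions(
    pos: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """One random-walk step per individual, re-drawn if spacing is violated."""
    h = cfg.arena_half_extent_m
    new = pos.copy()
    for i in range(len(pos)):
        for _attempt in range(200):
            cand = pos[i] + rng.normal(0.0, cfg.movement_step_sd_m, size=2)
            cand = np.clip(cand, -h, h)
            others = np.delete(new, i, axis=0)
            if len(others) == 0 or np.all(
                np.hypot(*(others - cand).T) >= cfg.min_individual_spacing_m
            ):
                new[i] = cand
                break
        # on repeated failure the individual simply stays put this interval
    return new


def _station_centroid(stations: Sequence[Station], earth: EarthModel) -> GeoPoint:
    from .localization import _station_centroid as _sc

    return _sc(stations, earth)


def simulate(
    cfg: ScenarioConfig, earth: EarthModel = EarthModel()
) -> tuple[list[TrueCall], list[DetectionSet]]:
    """Run one session; returns (ground truth, per-call detection tables).

    Detection sets with fewer than three audible stations are still emitted
    (their ``localizable`` property is False), matching what a field pipeline
    would see. Identical seeds give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    center = _station_centroid(list(cfg.stations), earth)
    truth: list[TrueCall] = []
    detections: list[DetectionSet] = []
    if cfg.n_individuals == 0:
        return truth, detections
    pos = _place_individuals(cfg, rng)
    call_no = 0
    for k in range(cfg.n_intervals):
        t0 = k * cfg.interval_s
        for i in range(cfg.n_individuals):
            n_calls = rng.poisson(cfg.call_rate)
            times = np.sort(rng.uniform(t0, t0 + cfg.interval_s, size=n_calls))
            for t in times:
                call_no += 1
                call_id = f"call{call_no:04d}"
                p = offset_point(center, pos[i, 0], pos[i, 1], earth)
                truth.append(
                    TrueCall(
                        call_id=call_id,
                        individual_id=f"ind{i + 1}",
                        position=p,
                        emission_time_s=float(t),
                    )
                )
                detections.append(
                    forward_detections(
                        p,
                        cfg.stations,
                        cfg.speed_mps,
                        call_id=call_id,
                        emission_time_s=float(t),
                        timing_noise_sd_s=cfg.timing_noise_sd_s,
                        detection_range_m=cfg.detection_range_m,
                        audibility_model=cfg.audibility_model,
                        rng=rng,
                        earth=earth,
                    )
                )
        pos = _step_positions(pos, cfg, rng)
    return truth, detections


@dataclass(frozen=True)
class Fixture:
    """A recorder deployment plus surveyed reference points."""

    name: str
    stations: tuple[Station, ...]
    references: dict[str, GeoPoint] = field(default_factory=dict)


def _st(sid: str, lat: str, lon: str) -> Station:
    return Station(id=sid, position=GeoPoint(parse_dms(lat), parse_dms(lon)))


def utokyo_fixture() -> Fixture:
    """Three-recorder playground deployment with five surveyed points A-E."""
    return Fixture(
        name="utokyo",
        stations=(
            _st("Rec1", "35°39′38.12″ N", "139°40′54.13″ E"),
            _st("Rec2", "35°39′36.19″ N", "139°40′55.57″ E"),
            _st("Rec3", "35°39′37.63″ N", "139°40′57.72″ E"),
        ),
        references={
            "A": GeoPoint(parse_dms("35°39′37.38″ N"), parse_dms("139°40′57.09″ E")),
            "B": GeoPoint(parse_dms("35°39′36.48″ N"), parse_dms("139°40′55.63″ E")),
            "C": GeoPoint(parse_dms("35°39′37.61″ N"), parse_dms("139°40′54.96″ E")),
            "D": GeoPoint(parse_dms("35°39′37.23″ N"), parse_dms("139°40′54.66″ E")),
            "E": GeoPoint(parse_dms("35°39′37.06″ N"), parse_dms("139°40′55.76″ E")),
        },
    )


def oze_fixture() -> Fixture:
    """Four-recorder marshland deployment with five surveyed points A-E."""
    return Fixture(
        name="oze",
        stations=(
            _st("Rec1", "36°56′31.91″ N", "139°13′38.43″ E"),
            _st("Rec2", "36°56′34.92″ N", "139°13′22.63″ E"),
            _st("Rec3", "36°56′23.49″ N", "139°13′24.27″ E"),
            _st("Rec4", "36°56′27.78″ N", "139°13′08.86″ E"),
        ),
        references={
            "A": GeoPoint(parse_dms("36°56′38.62″ N"), parse_dms("139°13′18.70″ E")),
            "B": GeoPoint(parse_dms("36°56′30.14″ N"), parse_dms("139°13′23.51″ E")),
            "C": GeoPoint(parse_dms("36°56′28.36″ N"), parse_dms("139°13′25.95″ E")),
            "D": GeoPoint(parse_dms("36°56′30.29″ N"), parse_dms("139°13′29.18″ E")),
            "E": GeoPoint(parse_dms("36°56′19.48″ N"), parse_dms("139°13′25.56″ E")),
        },
    )
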