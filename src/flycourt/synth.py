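"""Synthetic courtship-assay data with known ground truth.

Everything the analysis pipeline consumes can be generated here: frame stacks
of a two-fly assay in a circular 8-mm chamber (with the exact behavioral event
log that produced them), genitalia landmark sets at chosen true deviation
angles, and per-male outcome tables drawn from per-class success
probabilities.

The assay simulation renders both flies as filled dark ellipses on a light
background.  A male behavioral state machine (semi-Markov with exponential
dwell times, or a fixed script) drives courtship: during courtship components
the male pursues the female; during copulation the male is clamped onto the
female's posterior so the two silhouettes form a single connected region —
the signal the copulation detector keys on.  Wings are not rendered: the
detector deliberately operates below the level of individual courtship steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .angle import AngleClass, LandmarkSet, class_order, wrap_angle_deg
from .detect import AssayRecording
from .metrics import EventLog

__all__ = [
    "ArenaSpec",
    "FlyAgent",
    "SimConfig",
    "ClassProbabilities",
    "simulate_assay",
    "make_landmarks",
    "make_outcome_table",
    "DEFAULT_OFFSPRING_PROBS",
    "DEFAULT_COPULATION_PROBS",
]

BEHAVIOR_STATES = (
    "idle",
    "orientation",
    "tapping",
    "following",
    "wing_vibration",
    "licking",
    "attempted_copulation",
    "copulation",
)

_COURTSHIP_CHAIN = (
    "orientation",
    "tapping",
    "following",
    "wing_vibration",
    "licking",
    "attempted_copulation",
)


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and sampling of the recorded mating chamber."""

    diameter_mm: float = 8.0
    height_mm: float = 3.0
    pixels_per_mm: float = 10.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.pixels_per_mm < 4:
            raise ValueError("pixels_per_mm must be >= 4 so a fly spans >= 8 px")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2

    @property
    def image_side_px(self) -> int:
        return int(math.ceil(self.diameter_mm * self.pixels_per_mm))


@dataclass
class FlyAgent:
    """One fly: an oriented ellipse with a position inside the arena disk."""

    position: np.ndarray  # (x, y) mm, arena centre at origin
    heading_deg: float
    body_length_mm: float = 2.5
    body_width_mm: float = 1.0
    sex: str = "female"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.body_length_mm > self.body_width_mm > 0:
            raise ValueError("need body_length_mm > body_width_mm > 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated assay.

    ``scripted_events`` fixes the male state sequence exactly — (state,
    start_s, end_s) tuples, non-overlapping, inside the recording — which
    gives detector tests exact ground truth.  Without a script the male runs
    a semi-Markov chain: exponential dwell in each state (``state_exit_rates``
    per second), courtship components in their natural order, and a single
    copulation opportunity after a mounting attempt.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    duration_s: float = 3600.0
    seed: int = 0
    noise_sigma: float = 6.0
    fly_length_mm: float = 2.5
    fly_width_mm: float = 1.0
    background_level: int = 200
    fly_level: int = 40
    scripted_events: tuple[tuple[str, float, float], ...] | None = None
    state_exit_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "idle": 1 / 40,
            "orientation": 1 / 8,
            "tapping": 1 / 5,
            "following": 1 / 15,
            "wing_vibration": 1 / 12,
            "licking": 1 / 5,
            "attempted_copulation": 1 / 6,
            "copulation": 1 / 1200,
        }
    )
    copulation_prob: float = 0.35  # P(mounting attempt -> copulation)
    assay_id: str = "assay"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.scripted_events is not None:
            evs = sorted(self.scripted_events, key=lambda e: e[1])
            for state, s, e in evs:
                if state not in BEHAVIOR_STATES:
                    raise ValueError(f"unknown state {state!r}")
                if s < 0 or e > self.duration_s or e <= s:
                    raise ValueError(
                        f"scripted event {state!r} [{s}, {e}] outside [0, {self.duration_s}]"
                    )
            for (_, _, e1), (_, s2, _) in zip(evs, evs[1:]):
                if s2 < e1:
                    raise ValueError("scripted events overlap")
            object.__setattr__(self, "scripted_events", tuple(evs))


# ---------------------------------------------------------------------------
# behavioral state sequence


def _scripted_timeline(cfg: SimConfig) -> list[tuple[str, float, float]]:
    """Fill the gaps of the script with idle; returns full coverage of [0, T]."""
    events = list(cfg.scripted_events or ())
    timeline: list[tuple[str, float, float]] = []
    t = 0.0
    for state, s, e in events:
        if s > t:
            timeline.append(("idle", t, s))
        timeline.append((state, s, e))
        t = e
    if t < cfg.duration_s:
        timeline.append(("idle", t, cfg.duration_s))
    return timeline


def _sampled_timeline(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, float, float]]:
    """Semi-Markov male state sequence over [0, duration]."""
    timeline: list[tuple[str, float, float]] = []
    t = 0.0
    state = "idle"
    copulated = False
    while t < cfg.duration_s:
        rate = cfg.state_exit_rates.get(state, 1 / 30)
        dwell = rng.exponential(1.0 / rate)
        end = min(t + dwell, cfg.duration_s)
        timeline.append((state, t, end))
        t = end
        if t >= cfg.duration_s:
            break
        if copulated:
            state = "idle"  # post-copulatory quiescence: one copulation per assay
        elif state == "idle":
            state = "orientation"
        elif state == "attempted_copulation":
            if rng.random() < cfg.copulation_prob:
                state = "copulation"
                copulated = True
            else:
                state = "idle"
        elif state == "copulation":
            state = "idle"
        else:
            state = _COURTSHIP_CHAIN[_COURTSHIP_CHAIN.index(state) + 1]
    return timeline


def _timeline_to_log(cfg: SimConfig, timeline: Sequence[tuple[str, float, float]]) -> EventLog:
    rows = []
    for state, s, e in timeline:
        if state == "idle":
            continue
        truncated = int(state == "copulation" and e >= cfg.duration_s - 1e-9)
        rows.append(
            {
                "assay_id": cfg.assay_id,
                "fly": "pair" if state == "copulation" else "male",
                "event_type": state,
                "start_s": s,
                "end_s": e,
                "truncated": truncated,
            }
        )
    df = pd.DataFrame(rows, columns=["assay_id", "fly", "event_type", "start_s", "end_s", "truncated"])
    return EventLog(df=df, assay_id=cfg.assay_id)


# ---------------------------------------------------------------------------
# motion and rendering


def _ellipse_mask(
    side: int, ppm: float, radius_mm: float, center_mm: np.ndarray,
    heading_deg: float, length_mm: float, width_mm: float,
) -> np.ndarray:
    """Rasterize a filled rotated ellipse; x→columns, y→rows."""
    cx = (center_mm[0] + radius_mm) * ppm
    cy = (center_mm[1] + radius_mm) * ppm
    a = length_mm / 2 * ppm
    b = width_mm / 2 * ppm
    th = math.radians(heading_deg)
    rows, cols = np.ogrid[:side, :side]
    dx = (cols + 0.5) - cx
    dy = (rows + 0.5) - cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _step_walk(
    pos: np.ndarray, heading: float, rng: np.random.Generator,
    dt: float, margin_mm: float, speed_mm_s: float = 1.5, turn_sd_deg: float = 40.0,
) -> tuple[np.ndarray, float]:
    """One random-walk step confined to a disk of radius ``margin_mm``."""
    heading = heading + rng.normal(0.0, turn_sd_deg) * math.sqrt(dt)
    step = speed_mm_s * dt
    new = pos + step * np.array([math.cos(math.radians(heading)), math.sin(math.radians(heading))])
    r = float(np.hypot(*new))
    if r > margin_mm:
        new = new * (margin_mm / r)
        heading = heading + 180.0 + rng.normal(0.0, 30.0)  # bounce inward
    return new, wrap_angle_deg(heading)


def simulate_assay(cfg: SimConfig) -> tuple[AssayRecording, EventLog]:
    """Simulate one male–female assay; returns the recording and its ground truth.

    Frames are rendered every ``arena.frame_interval_s`` from t = 0 to
    ``duration_s`` inclusive.  The event log is the exact state-machine output
    (scripted or sampled); copulation intervals still running at the end of
    the recording carry the truncated flag.  The same config and seed always
    produce bit-identical frames and logs; the behavioral/motion random
    stream is independent of the pixel-noise stream, so the geometry is
    unchanged when only ``noise_sigma`` differs.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_behavior, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    timeline = (
        _scripted_timeline(cfg) if cfg.scripted_events is not None
        else _sampled_timeline(cfg, rng_behavior)
    )
    log = _timeline_to_log(cfg, timeline)

    arena = cfg.arena
    dt = arena.frame_interval_s
    n_frames = int(math.floor(cfg.duration_s / dt)) + 1
    side = arena.image_side_px
    # two confinement margins: free-walking flies only need their own
    # half-length of clearance; a mounted pair (male offset 0.4 body lengths
    # behind the female) needs the stricter copulation margin so every
    # rendered pixel stays inside the arena disk
    walk_margin = arena.radius_mm - 0.55 * cfg.fly_length_mm
    cop_margin = arena.radius_mm - 0.9 * cfg.fly_length_mm
    if cop_margin <= 0:
        raise ValueError("arena too small for the fly size")
    # outside copulation the flies are kept at least this far apart, which is
    # always achievable inside the walking disk and exceeds the touch
    # distance (one body length), so silhouettes merge only during copulation
    min_sep = walk_margin

    # initial placement: female centre-left, male centre-right
    female_pos = np.array([-walk_margin / 2, 0.0])
    male_pos = np.array([walk_margin / 2, 0.0])
    female_hd = float(rng_behavior.uniform(-180, 180))
    male_hd = float(rng_behavior.uniform(-180, 180))

    state_starts = np.array([s for _, s, _ in timeline])
    state_names = [name for name, _, _ in timeline]

    frames = np.empty((n_frames, side, side), dtype=np.uint8)
    timestamps = np.empty(n_frames)
    track = np.empty((n_frames, 4))  # female_x, female_y, male_x, male_y (mm)
    for k in range(n_frames):
        t = k * dt
        idx = int(np.searchsorted(state_starts, t + 1e-9) - 1)
        state = state_names[max(idx, 0)]

        female_margin = cop_margin if state == "copulation" else walk_margin
        if k > 0:
            female_pos, female_hd = _step_walk(
                female_pos, female_hd, rng_behavior, dt, female_margin
            )
            if state == "copulation":
                pass  # male position is slaved to the female below
            elif state == "idle":
                male_pos, male_hd = _step_walk(male_pos, male_hd, rng_behavior, dt, walk_margin)
            else:
                # courtship: pursue the female but hold a standoff just above
                # the separation floor
                to_f = female_pos - male_pos
                dist = float(np.hypot(*to_f))
                male_hd = math.degrees(math.atan2(to_f[1], to_f[0]))
                gap = dist - 1.1 * min_sep
                if abs(gap) > 0.05:
                    step = np.clip(gap, -2.0 * dt, 2.0 * dt)
                    male_pos = male_pos + (to_f / max(dist, 1e-9)) * step
                r = float(np.hypot(*male_pos))
                if r > walk_margin:
                    male_pos = male_pos * (walk_margin / r)

        if state == "copulation":
            # mount: male clamped on the female's posterior, 60% overlap
            r = float(np.hypot(*female_pos))
            if r > cop_margin:
                female_pos = female_pos * (cop_margin / r)
            back = -np.array(
                [math.cos(math.radians(female_hd)), math.sin(math.radians(female_hd))]
            )
            male_pos = female_pos + 0.4 * cfg.fly_length_mm * back
            male_hd = female_hd
        else:
            # collision avoidance: outside copulation the flies never come
            # closer than min_sep (> one body length), so they cannot touch
            to_f = female_pos - male_pos
            dist = float(np.hypot(*to_f))
            if dist < min_sep:
                away = -to_f / max(dist, 1e-9)
                cand = female_pos + min_sep * away
                r = float(np.hypot(*cand))
                if r > walk_margin:
                    cand = cand * (walk_margin / r)
                if float(np.hypot(*(cand - female_pos))) >= min_sep - 1e-9:
                    male_pos = cand
                else:
                    # fall back: the point diametrically opposite the female
                    # is always at least walk_margin away
                    rf = float(np.hypot(*female_pos))
                    u = female_pos / rf if rf > 1e-9 else np.array([1.0, 0.0])
                    male_pos = -walk_margin * u

        track[k] = (*female_pos, *male_pos)
        img = np.full((side, side), cfg.background_level, dtype=float)
        for pos, hd in ((female_pos, female_hd), (male_pos, male_hd)):
            m = _ellipse_mask(side, arena.pixels_per_mm, arena.radius_mm,
                              pos, hd, cfg.fly_length_mm, cfg.fly_width_mm)
            img[m] = cfg.fly_level
        if cfg.noise_sigma > 0:
            img = img + rng_noise.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)
        timestamps[k] = t

    rec = AssayRecording(
        frames=frames,
        timestamps_s=timestamps,
        arena={
            "diameter_mm": arena.diameter_mm,
            "height_mm": arena.height_mm,
            "pixels_per_mm": arena.pixels_per_mm,
            "frame_interval_s": dt,
        },
        assay_id=cfg.assay_id,
        trajectory=pd.DataFrame(
            track, columns=["female_x", "female_y", "male_x", "male_y"]
        ).assign(t_s=timestamps),
    )
    return rec, log


def single_fly_area_px(cfg: SimConfig) -> float:
    """Analytic pixel area of one rendered fly ellipse."""
    ppm = cfg.arena.pixels_per_mm
    return math.pi * (cfg.fly_length_mm / 2 * ppm) * (cfg.fly_width_mm / 2 * ppm)


# ---------------------------------------------------------------------------
# landmark generation


def make_landmarks(
    true_deviation_deg: float, noise_deg: float = 0.0, seed: int = 0
) -> LandmarkSet:
    """Landmark set whose measured deviation is the true angle plus noise.

    A canonical set (vertical midline, anus at its posterior end, penis 30 px
    away along the genitalia axis) is built at deviation ``true_deviation_deg
    + ε`` with ε ~ N(0, noise_deg²), then hidden behind a random similarity
    transform (rotation, uniform scale, translation) which the measurement is
    invariant to.
    """
    if not -180 < true_deviation_deg <= 180:
        raise ValueError("true_deviation_deg must lie in (-180, 180]")
    rng = np.random.default_rng(seed)
    dev = true_deviation_deg + (rng.normal(0.0, noise_deg) if noise_deg > 0 else 0.0)

    mid_a = np.array([0.0, 0.0])
    mid_b = np.array([0.0, 80.0])  # image frame: posterior is down
    anus = mid_b.copy()
    th = math.radians(dev)
    # genitalia axis at signed angle `dev` from the midline direction (0, 1)
    axis = np.array([-math.sin(th), math.cos(th)])
    penis = anus + 30.0 * axis

    phi = math.radians(rng.uniform(-180, 180))
    scale = rng.uniform(0.5, 2.0)
    shift = rng.uniform(-50, 50, size=2)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])

    def tf(p: np.ndarray) -> tuple[float, float]:
        q = scale * rot @ p + shift
        return (float(q[0]), float(q[1]))

    return LandmarkSet(anus=tf(anus), penis=tf(penis), midline_a=tf(mid_a), midline_b=tf(mid_b))


# ---------------------------------------------------------------------------
# outcome tables

#: default per-class reproduction (offspring) success probabilities after a
#: 4-day mating, for wild-type and Myosin-ID-mutant female backgrounds
DEFAULT_OFFSPRING_PROBS: dict[str, dict[AngleClass, float]] = {
    "wild_type": {
        AngleClass.DEG_0: 0.662,
        AngleClass.RIGHT_45: 0.339,
        AngleClass.RIGHT_90: 0.0196,
        AngleClass.RIGHT_135: 0.0318,
        AngleClass.DEG_180: 0.0,
        AngleClass.LEFT_135: 0.0,
        AngleClass.LEFT_90: 0.0303,
        AngleClass.LEFT_45: 0.462,
    },
    "Myo31DF": {
        AngleClass.DEG_0: 0.75,
        AngleClass.RIGHT_45: 0.60,
        AngleClass.RIGHT_90: 0.098,
        AngleClass.RIGHT_135: 0.0,
        AngleClass.DEG_180: 0.0,
        AngleClass.LEFT_135: 0.0,
        AngleClass.LEFT_90: 0.0,
        AngleClass.LEFT_45: 0.65,
    },
}

#: default copulation-success probabilities in the one-hour video assay
#: (wild-type females; classes measured in that experiment)
DEFAULT_COPULATION_PROBS: dict[AngleClass, float] = {
    AngleClass.DEG_0: 0.889,
    AngleClass.RIGHT_45: 0.0714,
    AngleClass.DEG_180: 0.0,
}

_CLASS_CENTER = {
    AngleClass.DEG_0: 0.0,
    AngleClass.RIGHT_45: 45.0,
    AngleClass.RIGHT_90: 90.0,
    AngleClass.RIGHT_135: 135.0,
    AngleClass.DEG_180: 180.0,
    AngleClass.LEFT_135: -135.0,
    AngleClass.LEFT_90: -90.0,
    AngleClass.LEFT_45: -45.0,
}


@dataclass(frozen=True)
class ClassProbabilities:
    """Per-class Bernoulli success probabilities for outcome-table simulation.

    ``offspring`` maps female genotype → angle class → marginal probability of
    producing offspring.  ``copulation`` (optional) gives the copulation
    probability per class; when omitted it defaults to the offspring
    probability (every copulating pair reproduces).  Offspring success is
    sampled conditionally on copulation so that a male that never copulated
    can never sire offspring.  ``per_day`` (optional) adds a normal-direction
    validation series: day (1–4) → offspring probability.
    """

    offspring: Mapping[str, Mapping[AngleClass, float]]
    copulation: Mapping[str, Mapping[AngleClass, float]] | None = None
    per_day: Mapping[int, float] | None = None
    mating_days: int = 4

    def __post_init__(self) -> None:
        for genotype, probs in self.offspring.items():
            for cls, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"offspring probability {p} for {genotype}/{cls} not in [0,1]")
                pc = self._copulation_prob(genotype, cls)
                if not 0.0 <= pc <= 1.0:
                    raise ValueError(f"copulation probability {pc} not in [0,1]")
                if p > pc + 1e-12:
                    raise ValueError(
                        f"offspring probability {p} exceeds copulation probability {pc}"
                    )
        for d, p in (self.per_day or {}).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"per-day probability {p} for day {d} not in [0,1]")

    def _copulation_prob(self, genotype: str, cls: AngleClass) -> float:
        if self.copulation is None:
            return self.offspring[genotype][cls]
        return self.copulation[genotype][cls]

    @classmethod
    def defaults(cls) -> "ClassProbabilities":
        return cls(offspring=DEFAULT_OFFSPRING_PROBS)


def make_outcome_table(
    probs: ClassProbabilities, n_per_class: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate one outcome record per male from per-class probabilities.

    Each male gets a measured angle drawn uniformly inside his class bin,
    a copulation outcome Bernoulli(p_cop), and — only if he copulated — an
    offspring outcome Bernoulli(p_off / p_cop), so the offspring marginal is
    exactly the requested class probability while offspring without
    copulation never occurs.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    male = 0
    for genotype in probs.offspring:
        for cls in class_order():
            if cls not in probs.offspring[genotype]:
                continue
            p_off = probs.offspring[genotype][cls]
            p_cop = probs._copulation_prob(genotype, cls)
            for _ in range(n_per_class):
                male += 1
                copulated = bool(rng.random() < p_cop)
                offspring = bool(copulated and p_cop > 0 and rng.random() < p_off / p_cop)
                center = _CLASS_CENTER[cls]
                measured = wrap_angle_deg(center + rng.uniform(-20, 20))
                rows.append(
                    {
                        "male_id": f"m{male:05d}",
                        "angle_class": cls.value,
                        "measured_angle_deg": round(measured, 1),
                        "female_genotype": genotype,
                        "mating_days": probs.mating_days,
                        "copulated": int(copulated),
                        "offspring": int(offspring),
                    }
                )
    if probs.per_day:
        for genotype in probs.offspring:
            for day, p in sorted(probs.per_day.items()):
                for _ in range(n_per_class):
                    male += 1
                    success = bool(rng.random() < p)
                    rows.append(
                        {
                            "male_id": f"m{male:05d}",
                            "angle_class": "normal",
                            "measured_angle_deg": 0.0,
                            "female_genotype": genotype,
                            "mating_days": day,
                            "copulated": int(success),
                            "offspring": int(success),
                        }
                    )
    return pd.DataFrame(rows)
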