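"""Synthetic experiment generator with planted, recoverable effects.

Emulates the statistical structure the downstream analyses assume: a
32-syllable repertoire expressed as a bout-level (semi-Markov) label chain
at 25 Hz with a median bout length of 10 frames, 20-minute recordings in a
453 mm square arena with corner preference, a dyadic context in which a
planted subset of syllables gains stationary usage and incoming transition
mass, coordinated approach/contact/leave episodes coupled to two syntax
families, and experimenter-style contact annotations during which the
syllable composition is biased toward a planted contact repertoire.

Everything is driven by one root seed through named substreams so that the
same configuration always reproduces byte-identical data, and individual
components (matrices, sequences, tracks, contacts) can be regenerated
independently.

Design notes
------------
* Generation is semi-Markov: bout labels follow a zero-diagonal
  row-stochastic transition matrix and bout durations are i.i.d. geometric,
  calibrated so the sample median lands on ``duration_median_frames``.
  A per-frame Markov chain with self-loops would conflate duration and
  syntax structure, which the analyses deliberately separate.
* The base transition matrix is a symmetric-Dirichlet draw whose columns
  are scaled to a graded usage profile (frequencies spanning roughly
  6.5% .. 0.5%, like a real repertoire) before row renormalization.  The
  planted context effect multiplies the planted columns of the dyadic base
  by ``dm_effect * centrality_boost``; for a row-stochastic matrix the
  dominant left eigenvector is the stationary distribution, so usage and
  incoming influence necessarily move together.
* Between-animal variability enters as lognormal per-animal usage
  multipliers (sigma ``animal_usage_sigma``) plus Dirichlet row noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import (
    AnalysisConfig,
    AnnotationBout,
    CentroidTrack,
    Dataset,
    Recording,
    SyllableSequence,
    pool_annotation_bouts,
    write_recording,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "Episode",
    "generate_transition_matrices",
    "generate_sequence",
    "generate_tracks",
    "generate_contacts",
    "generate_experiment",
    "plan_events",
    "write_experiment",
    "geometric_p_for_median",
]

# default traversal syllables: members of the two reference syntax families,
# which the study conditions treat as long-distance movement behaviors
_TRAVERSAL_IDS = (0, 2, 5, 8, 9, 11)


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment."""

    n_syllables: int = 32
    n_animals_per_context: int = 20
    duration_s: float = 1200.0
    frame_rate: float = 25.0
    planted_dm: tuple[int, ...] = (24, 25, 26, 27, 28, 29, 30, 31)
    dm_effect: float = 1.6
    centrality_boost: float = 1.5
    dm_down_effect: float = 0.15   # factor for the down-modulated half
    duration_median_frames: int = 10
    arena_mm: float = 453.0
    contact_mm: float = 100.0
    family_syntaxes: tuple[tuple[int, int, int], ...] = ((9, 0, 5), (11, 2, 8))
    seed: int = 0

    # statistical structure of the repertoire
    usage_decay: float = 0.08          # usage profile ~ exp(-decay * id)
    animal_usage_sigma: float = 0.6    # lognormal per-animal usage spread
    row_concentration: float = 150.0   # Dirichlet concentration of row noise

    # social episode plan and contact scoring
    episode_period_s: float = 60.0
    approach_s: float = 2.0
    dwell_s: float = 2.5
    leave_s: float = 2.0
    active_prob: float = 0.7
    contact_bias: float = 1.0          # prob. a contact bout label is drawn
                                       # from the contact composition
    contact_syntax: tuple[int, int, int] = (24, 25, 26)
    family_coupling: bool = True

    # locomotion
    base_step_mm: float = 2.4          # per-frame step at speed multiplier 1
    stationary_speed: float = 0.1
    traversal_speed: float = 1.6

    def __post_init__(self) -> None:
        if self.n_syllables < 3:
            raise ConfigError("n_syllables must be >= 3")
        if not set(self.planted_dm) <= set(range(self.n_syllables)):
            raise ConfigError("planted_dm must be a subset of syllable ids")
        if self.dm_effect <= 0 or self.centrality_boost <= 0:
            raise ConfigError("effects must be > 0")
        if self.duration_median_frames < 1:
            raise ConfigError("duration_median_frames must be >= 1")
        for fam in self.family_syntaxes:
            if len(fam) != 3 or fam[0] == fam[1] or fam[1] == fam[2]:
                raise ConfigError(f"invalid family reference {fam}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def planted_up(self) -> tuple[int, ...]:
        """Up-modulated half of the planted set."""
        k = (len(self.planted_dm) + 1) // 2
        return self.planted_dm[:k]

    @property
    def planted_down(self) -> tuple[int, ...]:
        """Down-modulated half of the planted set."""
        k = (len(self.planted_dm) + 1) // 2
        return self.planted_dm[k:]

    def usage_profile(self) -> np.ndarray:
        u = np.exp(-self.usage_decay * np.arange(self.n_syllables))
        return u / u.sum()

    def speed_profile(self) -> np.ndarray:
        speed = np.ones(self.n_syllables)
        for i in _TRAVERSAL_IDS:
            if i < self.n_syllables:
                speed[i] = self.traversal_speed
        for i in self.planted_dm:
            speed[i] = self.stationary_speed
        return speed

    def contact_composition(self) -> np.ndarray:
        """Label distribution planted during active contact bouts."""
        usage = self.usage_profile()
        dist = np.zeros(self.n_syllables)
        planted = list(self.planted_up)
        if planted:
            dist[planted] = 0.5 / len(planted)
            others = np.setdiff1d(np.arange(self.n_syllables), planted)
            dist[others] = 0.5 * usage[others] / usage[others].sum()
        else:
            dist[:] = usage
        return dist

    def null(self) -> "SyntheticConfig":
        """The matched null configuration: no planted effects anywhere."""
        return replace(
            self,
            dm_effect=1.0,
            centrality_boost=1.0,
            dm_down_effect=1.0,
            contact_bias=0.0,
            family_coupling=False,
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            frame_rate=self.frame_rate, contact_mm=self.contact_mm
        )


@dataclass(frozen=True)
class Episode:
    """One planned social episode (frame interval, half-open)."""

    kind: str            # approach | contact | leave
    start: int
    end: int
    family: tuple[int, int, int] | None = None


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the planted effects."""

    config: SyntheticConfig
    planted_dm: tuple[int, ...]
    base_matrices: dict[str, np.ndarray]
    animal_matrices: dict[str, list[np.ndarray]]
    episodes: dict[str, list[Episode]]
    contact_composition: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "planted_dm": list(self.planted_dm),
            "base_matrices": {
                k: v.tolist() for k, v in self.base_matrices.items()
            },
            "animal_matrices": {
                k: [m.tolist() for m in v]
                for k, v in self.animal_matrices.items()
            },
            "episodes": {
                k: [asdict(e) for e in v] for k, v in self.episodes.items()
            },
            "contact_composition": self.contact_composition.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

# named substream ids; every random draw flows from (root seed, stream, ...)
_STREAM_BASE = 0
_STREAM_USAGE = 1
_STREAM_ROWS = 2
_STREAM_SEQ = 3
_STREAM_TRACK = 4
_STREAM_EVENTS = 5
_STREAM_CONTACT = 6


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def _renorm_rows(mat: np.ndarray) -> np.ndarray:
    np.fill_diagonal(mat, 0.0)
    return mat / mat.sum(axis=1, keepdims=True)


def generate_transition_matrices(
    cfg: SyntheticConfig, context: str
) -> dict[str, object]:
    """Base and per-animal bout-transition matrices for one context.

    The raw base draw uses a substream independent of context, so with
    ``dm_effect == centrality_boost == 1`` the solitary and dyadic bases are
    identical.  Returns ``{"base": (n, n), "animals": [(n, n), ...]}``; all
    matrices are zero-diagonal with rows summing to 1.
    """
    if context not in ("solitary", "dyadic"):
        raise ConfigError(f"unknown context {context!r}")
    n = cfg.n_syllables
    rng = _rng(cfg.seed, _STREAM_BASE)
    off = rng.dirichlet(np.ones(n - 1), size=n)
    raw = np.zeros((n, n))
    for i in range(n):
        raw[i, np.arange(n) != i] = off[i]
    base = _renorm_rows(raw * cfg.usage_profile()[None, :])
    if context == "dyadic":
        # planted modulation is a redistribution: the first half of the
        # planted set gains incoming mass, the second half loses it, so
        # the unplanted syllables stay (approximately) unmodulated --
        # mirroring a repertoire where increased stationary behavior comes
        # at the expense of locomotion rather than of everything equally
        factor = np.ones(n)
        factor[list(cfg.planted_up)] = cfg.dm_effect * cfg.centrality_boost
        factor[list(cfg.planted_down)] = cfg.dm_down_effect
        if (factor != 1.0).any():
            base = _renorm_rows(base * factor[None, :])

    ctx_idx = 0 if context == "solitary" else 1
    animals = []
    conc = cfg.row_concentration
    for a in range(cfg.n_animals_per_context):
        # per-animal usage multipliers drawn independently per context:
        # the two sessions of one animal are weeks apart, so its session
        # usage profile is treated as a fresh draw around the base
        mult = np.exp(
            cfg.animal_usage_sigma
            * _rng(cfg.seed, _STREAM_USAGE, ctx_idx, a).standard_normal(n)
        )
        tilted = _renorm_rows(base * mult[None, :])
        rng_rows = _rng(cfg.seed, _STREAM_ROWS, ctx_idx, a)
        mat = np.zeros((n, n))
        idx = np.arange(n)
        for i in range(n):
            alpha = np.clip(tilted[i, idx != i] * conc, 1e-3, None)
            mat[i, idx != i] = rng_rows.dirichlet(alpha)
        animals.append(_renorm_rows(mat))
    return {"base": base, "animals": animals}


def geometric_p_for_median(median_frames: int) -> float:
    """Success probability of a geometric bout-duration law (support 1, 2, ...)
    whose sample median is ``median_frames``."""
    return 1.0 - 0.5 ** (1.0 / max(median_frames - 0.5, 0.5))


def _validate_stochastic(matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ConfigError("transition matrix must be square")
    if (matrix < 0).any():
        raise ConfigError("transition matrix has negative entries")
    if np.abs(np.diagonal(matrix)).max() > 1e-12:
        raise ConfigError("transition matrix diagonal must be zero")
    if np.abs(matrix.sum(axis=1) - 1.0).max() > 1e-9:
        raise ConfigError("transition matrix rows must sum to 1")


def generate_bout_chain(
    matrix: np.ndarray, n_frames: int, cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (bout_labels, bout_durations) covering at least ``n_frames``."""
    _validate_stochastic(matrix)
    n = matrix.shape[0]
    p = geometric_p_for_median(cfg.duration_median_frames)
    import bisect

    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0
    cum_rows = cum.tolist()
    labels: list[int] = []
    durations: list[int] = []
    total = 0
    state = int(rng.integers(n))
    chunk = max(256, int(n_frames * p * 1.5))
    while total < n_frames:
        us = rng.random(chunk)
        ds = rng.geometric(p, size=chunk)
        for u, d in zip(us, ds):
            labels.append(state)
            durations.append(int(d))
            total += int(d)
            if total >= n_frames:
                break
            state = bisect.bisect_right(cum_rows[state], u)
    return np.asarray(labels, dtype=np.int64), np.asarray(durations, dtype=np.int64)


def generate_sequence(
    matrix: np.ndarray,
    cfg: SyntheticConfig,
    seed_key: tuple[int, ...] | np.random.Generator,
) -> np.ndarray:
    """Semi-Markov frame-label sequence of ``cfg.n_frames`` frames."""
    rng = (
        seed_key
        if isinstance(seed_key, np.random.Generator)
        else _rng(cfg.seed, _STREAM_SEQ, *seed_key)
    )
    labels, durations = generate_bout_chain(matrix, cfg.n_frames, cfg, rng)
    return np.repeat(labels, durations)[: cfg.n_frames]


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------


def _corners(cfg: SyntheticConfig, margin: float = 40.0) -> np.ndarray:
    w = cfg.arena_mm
    return np.array(
        [
            [margin, margin],
            [w - margin, margin],
            [margin, w - margin],
            [w - margin, w - margin],
        ]
    )


def _frame_speeds(
    labels: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    speed = cfg.speed_profile()[labels] * cfg.base_step_mm
    return np.maximum(speed * rng.lognormal(0.0, 0.3, size=labels.size), 0.02)


def _free_walk(
    pos: np.ndarray,
    t0: int,
    t1: int,
    p: np.ndarray,
    speeds: np.ndarray,
    corner_ids: Sequence[int],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill pos[t0:t1] with a corner-seeking waypoint walk starting at p."""
    corners = _corners(cfg)
    w = cfg.arena_mm
    t = t0
    while t < t1:
        if rng.random() < 0.75:
            target = corners[corner_ids[int(rng.integers(len(corner_ids)))]]
            target = target + rng.normal(0.0, 15.0, size=2)
        else:
            target = rng.uniform(60.0, w - 60.0, size=2)
        target = np.clip(target, 5.0, w - 5.0)
        dist = float(np.linalg.norm(target - p))
        seg = speeds[t:t1]
        cum = np.cumsum(seg)
        n_travel = int(np.searchsorted(cum, dist)) + 1
        n_travel = min(n_travel, t1 - t)
        frac = np.minimum(cum[:n_travel] / max(dist, 1e-9), 1.0)
        pts = p + frac[:, None] * (target - p)
        pts += rng.normal(0.0, 1.5, size=pts.shape)
        pts = np.clip(pts, 0.0, w)
        pos[t : t + n_travel] = pts
        p = pos[t + n_travel - 1].copy()
        t += n_travel
        if t < t1 and cum[n_travel - 1] >= dist:
            dwell = min(int(rng.exponential(2.0 * cfg.frame_rate)) + 5, t1 - t)
            pts = p + rng.normal(0.0, 1.0, size=(dwell, 2))
            pos[t : t + dwell] = np.clip(pts, 0.0, w)
            p = pos[t + dwell - 1].copy()
            t += dwell
    return p


def _forced_path(
    p: np.ndarray,
    target: np.ndarray,
    n: int,
    rng: np.random.Generator,
    w: float,
    jitter: float = 1.5,
) -> np.ndarray:
    """Travel from p to exactly target in n frames with uneven progress."""
    weights = rng.lognormal(0.0, 0.3, size=n) + 0.05
    frac = np.cumsum(weights) / weights.sum()
    pts = p + frac[:, None] * (target - p)
    if n > 1:
        pts[:-1] += rng.normal(0.0, jitter, size=(n - 1, 2))
    return np.clip(pts, 0.0, w)


def plan_events(cfg: SyntheticConfig, rng: np.random.Generator) -> list[Episode]:
    """Schedule approach/contact/leave cycles through one recording."""
    fr = cfg.frame_rate
    period = int(round(cfg.episode_period_s * fr))
    af = int(round(cfg.approach_s * fr))
    df = int(round(cfg.dwell_s * fr))
    lf = int(round(cfg.leave_s * fr))
    episodes: list[Episode] = []
    fam = cfg.family_syntaxes
    n_cycles = cfg.n_frames // period
    for k in range(n_cycles):
        t0 = int(k * period + 0.3 * period + rng.integers(-period // 10, period // 10))
        if t0 + af + df + lf >= cfg.n_frames:
            break
        episodes.append(
            Episode("approach", t0, t0 + af, fam[0] if fam else None)
        )
        episodes.append(Episode("contact", t0 + af, t0 + af + df, None))
        episodes.append(
            Episode(
                "leave",
                t0 + af + df,
                t0 + af + df + lf,
                fam[1] if len(fam) > 1 else None,
            )
        )
    if not episodes:
        return episodes
    if episodes[-1].end > cfg.n_frames:
        raise ConfigError("episode plan extends past the recording")
    return episodes


def _overwrite_family(
    labels: np.ndarray,
    start: int,
    end: int,
    family: tuple[int, int, int],
    n_syllables: int,
    rng: np.random.Generator,
) -> None:
    """Write one family-member triple into labels[start:end] (in place)."""
    window = min(end - start, 36)
    if window < 6:
        return
    triple = list(family)
    if rng.random() < 0.5:  # hamming-1 member of the family
        pos = int(rng.integers(3))
        choices = [
            s
            for s in range(n_syllables)
            if s != triple[pos]
            and (pos == 0 or s != triple[pos - 1])
            and (pos == 2 or s != triple[pos + 1])
        ]
        triple[pos] = int(choices[int(rng.integers(len(choices)))])
    edges = np.linspace(0, window, 4).astype(int)
    for j in range(3):
        labels[start + edges[j] : start + edges[j + 1]] = triple[j]


def generate_tracks(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    event_plan: Sequence[Episode],
    labels_a: np.ndarray,
    labels_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired dyadic tracks; returns (pos_a, pos_b, labels_a).

    Mouse B follows a corner-seeking walk that holds still through each
    episode cycle; mouse A is scripted toward/away from B during episodes
    and walks freely otherwise.  During family-coupled episode phases A's
    label sequence is overwritten with triples from the configured family,
    so the returned ``labels_a`` replaces the input.
    """
    for ep in event_plan:
        if ep.start < 0 or ep.end > cfg.n_frames:
            raise ConfigError(f"episode {ep} outside the recording")
    n = cfg.n_frames
    w = cfg.arena_mm
    labels_a = labels_a.copy()
    speeds_a = _frame_speeds(labels_a, cfg, rng)
    speeds_b = _frame_speeds(labels_b, cfg, rng)

    cycles = [
        (ap, co, lv)
        for ap, co, lv in zip(event_plan[::3], event_plan[1::3], event_plan[2::3])
    ]

    # ---- mouse B: free walk with holds around each cycle
    pos_b = np.empty((n, 2))
    holds = [(max(c[0].start - 12, 0), c[2].end) for c in cycles]
    p = np.array([w - 60.0, w - 60.0]) + rng.normal(0, 10, 2)
    t = 0
    for h0, h1 in holds:
        if t < h0:
            p = _free_walk(pos_b, t, h0, p, speeds_b, (2, 3), cfg, rng)
        pts = p + rng.normal(0.0, 1.2, size=(h1 - h0, 2))
        pos_b[h0:h1] = np.clip(pts, 0.0, w)
        p = pos_b[h1 - 1].copy()
        t = h1
    if t < n:
        _free_walk(pos_b, t, n, p, speeds_b, (2, 3), cfg, rng)

    # ---- mouse A: scripted episodes against the finished B track
    pos_a = np.empty((n, 2))
    corners = _corners(cfg)
    p = np.array([60.0, 60.0]) + rng.normal(0, 10, 2)
    t = 0
    for ap, co, lv in cycles:
        if t < ap.start:
            p = _free_walk(pos_a, t, ap.start, p, speeds_a, (0, 1), cfg, rng)
        # approach: arrive next to B by the end of the approach window
        angle = rng.uniform(0, 2 * np.pi)
        offset = 27.0 * np.array([np.cos(angle), np.sin(angle)])
        target = np.clip(pos_b[ap.end - 1] + offset, 0.0, w)
        pos_a[ap.start : ap.end] = _forced_path(
            p, target, ap.end - ap.start, rng, w
        )
        # contact dwell: ride along next to B
        dwell = pos_b[co.start : co.end] + offset
        dwell = dwell + rng.normal(0.0, 2.0, size=dwell.shape)
        pos_a[co.start : co.end] = np.clip(dwell, 0.0, w)
        # leave: retreat to the own-half corner farthest from B
        b_now = pos_b[lv.start]
        far = corners[(0, 1), :][
            int(np.argmax(np.linalg.norm(corners[(0, 1), :] - b_now, axis=1)))
        ]
        far = np.clip(far + rng.normal(0, 10, 2), 5.0, w - 5.0)
        pos_a[lv.start : lv.end] = _forced_path(
            pos_a[lv.start - 1], far, lv.end - lv.start, rng, w
        )
        p = pos_a[lv.end - 1].copy()
        t = lv.end
        if cfg.family_coupling:
            if ap.family is not None:
                _overwrite_family(
                    labels_a,
                    max(ap.start, ap.end - 36),
                    ap.end,
                    ap.family,
                    cfg.n_syllables,
                    rng,
                )
            if lv.family is not None:
                _overwrite_family(
                    labels_a, lv.start, min(lv.end, lv.start + 36),
                    lv.family, cfg.n_syllables, rng,
                )
    if t < n:
        _free_walk(pos_a, t, n, p, speeds_a, (0, 1), cfg, rng)
    return pos_a, pos_b, labels_a


def generate_solitary_track(
    cfg: SyntheticConfig, rng: np.random.Generator, labels: np.ndarray
) -> np.ndarray:
    """Single-mouse corner-seeking walk over the whole recording."""
    pos = np.empty((cfg.n_frames, 2))
    speeds = _frame_speeds(labels, cfg, rng)
    start = rng.uniform(60.0, cfg.arena_mm - 60.0, size=2)
    _free_walk(pos, 0, cfg.n_frames, start, speeds, (0, 1, 2, 3), cfg, rng)
    return pos


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _proximity_runs(imd: np.ndarray, threshold: float, min_len: int = 5):
    prox = (imd < threshold).astype(np.int8)
    edges = np.diff(np.concatenate(([0], prox, [0])))
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def _overwrite_contact(
    labels: np.ndarray,
    start: int,
    end: int,
    dist: np.ndarray,
    usage: np.ndarray,
    p_geom: float,
    bias: float,
    rng: np.random.Generator,
) -> None:
    t = start
    prev = -1
    while t < end:
        d = int(rng.geometric(p_geom))
        src = dist if rng.random() < bias else usage
        lab = int(rng.choice(len(src), p=src))
        if lab == prev:
            lab = int(rng.choice(len(src), p=src))
            if lab == prev:
                lab = (lab + 1) % len(src)
        labels[t : min(t + d, end)] = lab
        prev = lab
        t += d


def generate_contacts(
    track_a: np.ndarray,
    track_b: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    labels_a: np.ndarray | None = None,
    labels_b: np.ndarray | None = None,
    recording_id: str = "rec",
) -> tuple[list[AnnotationBout], np.ndarray | None, np.ndarray | None]:
    """Score proximity runs as active/passive contact bouts.

    Frames with inter-mouse distance below ``contact_mm`` form candidate
    runs; each run is scored active with probability ``active_prob``.  With
    ``contact_bias > 0`` both animals' labels during active runs are
    rewritten from the planted contact composition, which is what the
    contact-aligned divergence analyses later recover.
    """
    if len(track_a) != len(track_b):
        raise ConfigError("tracks must have equal length")
    imd = np.linalg.norm(track_a - track_b, axis=1)
    runs = _proximity_runs(imd, cfg.contact_mm)
    labels_a = None if labels_a is None else labels_a.copy()
    labels_b = None if labels_b is None else labels_b.copy()
    dist = cfg.contact_composition()
    usage = cfg.usage_profile()
    p_geom = geometric_p_for_median(cfg.duration_median_frames)
    bouts = []
    for s, e in runs:
        active = rng.random() < cfg.active_prob
        ctype = "active" if active else "passive"
        bouts.append(AnnotationBout(recording_id, ctype, s, e))
        if active and cfg.contact_bias > 0:
            for lab in (labels_a, labels_b):
                if lab is not None:
                    _overwrite_contact(
                        lab, s, e, dist, usage, p_geom, cfg.contact_bias, rng
                    )
            # stereotyped greeting syntax at contact onset
            if labels_a is not None and e - s >= 9:
                window = min(36, e - s)
                edges = np.linspace(0, window, 4).astype(int)
                for j in range(3):
                    labels_a[s + edges[j] : s + edges[j + 1]] = (
                        cfg.contact_syntax[j]
                    )
    return bouts, labels_a, labels_b


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


def generate_experiment(
    cfg: SyntheticConfig,
) -> tuple[Dataset, SyntheticGroundTruth]:
    """Generate the full synthetic study.

    ``n_animals_per_context`` solitary recordings (one animal each) and
    ``n_animals_per_context / 2`` dyadic recordings (pairs of the same
    animals), with annotations on the dyadic recordings.  The first half of
    the animals is assigned the normal light cycle, the second half the
    reversed one; dyads pair animals within a light-cycle group.
    """
    n_animals = cfg.n_animals_per_context
    if n_animals % 2:
        raise ConfigError("n_animals_per_context must be even (dyads)")
    mats = {
        ctx: generate_transition_matrices(cfg, ctx)
        for ctx in ("solitary", "dyadic")
    }
    arena = (cfg.arena_mm, cfg.arena_mm)
    half = n_animals // 2

    def cycle(a: int) -> str:
        return "normal" if a < half else "reversed"

    recordings: list[Recording] = []
    episodes_log: dict[str, list[Episode]] = {}

    for a in range(n_animals):
        rid, aid = f"sol{a:02d}", f"m{a:02d}"
        labels = generate_sequence(mats["solitary"]["animals"][a], cfg, (0, a))
        pos = generate_solitary_track(cfg, _rng(cfg.seed, _STREAM_TRACK, 0, a), labels)
        seq = SyllableSequence(rid, aid, "solitary", cycle(a), labels, cfg.frame_rate)
        track = CentroidTrack(rid, aid, pos, arena)
        recordings.append(
            Recording(rid, "solitary", cycle(a), {aid: seq}, {aid: track})
        )

    for k in range(half):
        a, b = 2 * k, 2 * k + 1
        rid = f"dya{k:02d}"
        ida, idb = f"m{a:02d}", f"m{b:02d}"
        lab_a = generate_sequence(mats["dyadic"]["animals"][a], cfg, (1, a))
        lab_b = generate_sequence(mats["dyadic"]["animals"][b], cfg, (1, b))
        plan = plan_events(cfg, _rng(cfg.seed, _STREAM_EVENTS, k))
        pos_a, pos_b, lab_a = generate_tracks(
            cfg, _rng(cfg.seed, _STREAM_TRACK, 1, k), plan, lab_a, lab_b
        )
        bouts, lab_a, lab_b = generate_contacts(
            pos_a,
            pos_b,
            cfg,
            _rng(cfg.seed, _STREAM_CONTACT, k),
            lab_a,
            lab_b,
            recording_id=rid,
        )
        gap = cfg.analysis_config().pooling_gap_frames
        rec = Recording(
            rid,
            "dyadic",
            cycle(a),
            {
                ida: SyllableSequence(rid, ida, "dyadic", cycle(a), lab_a, cfg.frame_rate),
                idb: SyllableSequence(rid, idb, "dyadic", cycle(b), lab_b, cfg.frame_rate),
            },
            {
                ida: CentroidTrack(rid, ida, pos_a, arena),
                idb: CentroidTrack(rid, idb, pos_b, arena),
            },
            annotations=pool_annotation_bouts(bouts, gap) if bouts else [],
        )
        recordings.append(rec)
        episodes_log[rid] = plan

    gt = SyntheticGroundTruth(
        config=cfg,
        planted_dm=cfg.planted_dm,
        base_matrices={ctx: mats[ctx]["base"] for ctx in mats},
        animal_matrices={ctx: mats[ctx]["animals"] for ctx in mats},
        episodes=episodes_log,
        contact_composition=cfg.contact_composition(),
    )
    return Dataset(recordings, cfg.analysis_config()), gt


def write_experiment(
    dataset: Dataset, gt: SyntheticGroundTruth, out_dir: str | Path
) -> Path:
    """Write the io file set plus ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        write_recording(rec, out_dir)
    gt.to_json(out_dir / "ground_truth.json")
    return out_dir
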