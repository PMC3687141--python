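"""Synthetic observers for the 4AFC spiral-tail task.

Two kinds of observer stand in for human subjects:

* a *parametric* observer whose probability of a correct response is a
  product of monotone salience factors in orientation jitter, contour
  spacing, stimulus duration and relative spacing, floored at the 4AFC
  guessing rate and shaved by a lapse rate.  This is the generator the
  analysis pipeline assumes: per-condition Bernoulli correctness with
  known structure.
* a *grouping* observer that actually operates on the element list: it
  scores pairwise association-field-style affinities (proximity +
  co-circularity), extracts the best simple chain by beam search, and
  reports the sector of the chain endpoint farthest from the pattern
  centroid.  It is a mechanistic alternative, not a model of the human
  data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .field_fill import Condition, StimulusField

__all__ = [
    "ObserverParams",
    "AffinityParams",
    "YOUNGER_DEFAULTS",
    "OLDER_DEFAULTS",
    "default_params",
    "psychometric_prob",
    "respond",
    "simulate_cell_counts",
    "grouping_observer_respond",
    "ParametricObserver",
    "GroupingObserver",
    "OracleObserver",
    "RandomObserver",
    "TAIL_LABELS",
]

TAIL_LABELS = ("up", "down", "left", "right")

REFERENCE_SPACING_LAMBDA = 2.0  # salience factor is 1 at 2-lambda spacing


@dataclass(frozen=True)
class ObserverParams:
    """Parametric psychometric observer.

    guess_rate : 4AFC floor (0.25).  lapse : stimulus-independent error
    rate in [0, 0.1].  jitter_scale : orientation jitter (deg) at which
    the jitter factor halves.  spacing_penalty : multiplicative salience
    factor per wavelength of spacing beyond 2 lambda.  duration_tau :
    saturating time constant (s).  relspace_mid / relspace_slope :
    midpoint and width of the logistic decline in relative spacing.
    iso_bonus : salience multiplier applied to the relative-spacing
    factor for iso-oriented backgrounds (capped at 1).
    """

    guess_rate: float = 0.25
    lapse: float = 0.01
    jitter_scale: float = 45.0
    spacing_penalty: float = 0.93
    duration_tau: float = 0.030
    relspace_slope: float = 0.25
    relspace_mid: float = 2.0
    iso_bonus: float = 8.0
    group: str = "younger"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must be in [0, 0.1]")
        for name in ("jitter_scale", "spacing_penalty", "duration_tau",
                     "relspace_slope", "relspace_mid", "iso_bonus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Defaults emulating the two subject groups.  The older group carries a
#: larger lapse (overall accuracy deficit), a slower duration constant
#: (the age-by-duration interaction) and a steeper, earlier decline in
#: relative spacing (greater vulnerability to dense distracters).
YOUNGER_DEFAULTS = ObserverParams(group="younger")
OLDER_DEFAULTS = ObserverParams(
    lapse=0.05, jitter_scale=42.0, spacing_penalty=0.90,
    duration_tau=0.140, relspace_slope=0.30, relspace_mid=1.70,
    iso_bonus=8.0, group="older",
)


def default_params(group: str) -> ObserverParams:
    try:
        return {"younger": YOUNGER_DEFAULTS, "older": OLDER_DEFAULTS}[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}") from None


def _salience(condition: Condition, params: ObserverParams) -> float:
    j = condition.jitter_deg
    s_j = math.exp(-math.log(2.0) * (j / params.jitter_scale) ** 2)
    s_space = min(1.0, params.spacing_penalty
                  ** (condition.spacing_lambda - REFERENCE_SPACING_LAMBDA))
    s_dur = 1.0 - math.exp(-condition.duration_s / params.duration_tau)
    rel = condition.relative_spacing
    logistic = lambda r: 1.0 / (1.0 + math.exp((r - params.relspace_mid)
                                               / params.relspace_slope))
    s_rel = min(1.0, logistic(rel) / logistic(1.0))
    if condition.background.mode == "iso":
        s_rel = min(1.0, params.iso_bonus * s_rel)
    return min(1.0, max(0.0, s_j * s_space * s_dur * s_rel))


def psychometric_prob(condition: Condition, params: ObserverParams) -> float:
    """Probability correct: pc = gamma + (1 - gamma - lapse) * S."""
    s = _salience(condition, params)
    return params.guess_rate + (1.0 - params.guess_rate - params.lapse) * s


def respond(true_tail: str, pc: float, rng: np.random.Generator) -> str:
    """4AFC response: the true tail with probability pc, else a uniform
    draw among the three wrong labels."""
    if not (0.0 <= pc <= 1.0):
        raise ValueError("pc must be in [0, 1]")
    if true_tail not in TAIL_LABELS:
        raise ValueError(f"unknown tail label {true_tail!r}")
    if rng.random() < pc:
        return true_tail
    wrong = [lab for lab in TAIL_LABELS if lab != true_tail]
    return wrong[int(rng.integers(3))]


def simulate_cell_counts(pc: float, n_trials: int,
                         rng: np.random.Generator) -> int:
    """Correct-response count for one subject-condition cell.

    Distributionally identical to ``n_trials`` independent
    :func:`respond` calls at the same pc."""
    return int(rng.binomial(n_trials, pc))


# ---------------------------------------------------------------------------
# grouping (association-field) observer


@dataclass(frozen=True)
class AffinityParams:
    """Pairwise-affinity scales for the grouping observer.

    sigma_d : distance scale (deg); sigma_theta : co-circularity
    tolerance (deg); beam_width : width of the chain beam search;
    w_floor : smallest edge affinity a chain may take (extension stops
    below it); max_links : safety cap on chain length; trim_frac :
    terminal links weaker than this fraction of the chain's median edge
    affinity are trimmed away (they are background continuations, not
    contour evidence); max_turn_deg : largest direction change allowed
    between successive links -- chance-aligned distracter chains are
    jagged, smooth contours are not, so a turn limit suppresses false
    continuations that local pairwise affinity cannot.
    """

    sigma_d: float = 1.2
    sigma_theta: float = 25.0
    beam_width: int = 8
    w_floor: float = 0.02
    max_links: int = 40
    trim_frac: float = 0.5
    max_turn_deg: float = 75.0

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_theta <= 0:
            raise ValueError("affinity scales must be positive")
        if self.beam_width < 1 or self.max_links < 1:
            raise ValueError("beam_width and max_links must be >= 1")
        if not (0.0 < self.w_floor < 1.0):
            raise ValueError("w_floor must be in (0, 1)")


def _wrap_half(a: np.ndarray) -> np.ndarray:
    """Wrap angles (deg) to [-90, 90) -- axial (mod 180) differences."""
    return (a + 90.0) % 180.0 - 90.0


def _affinity_matrix(positions: np.ndarray, orientations: np.ndarray,
                     params: AffinityParams) -> np.ndarray:
    """w(i,j) = exp(-d^2 / 2 sd^2) * exp(-(ai^2 + aj^2) / 2 st^2).

    ai, aj are each element's angular deviation from the co-circular
    ideal of the pair: with axial deviations u_i, u_j of the element
    orientations from the chord direction (each in [-90, 90)), the
    co-circular configuration has u_i = -u_j, so each element deviates
    by (u_i + u_j) / 2.  The sum is deliberately *not* re-wrapped: two
    near-perpendicular, parallel elements (a side-by-side "ladder" pair,
    u_i = u_j = +-90) support parallelism, not contour continuation, and
    must score low -- re-wrapping would alias them onto perfect
    co-circularity and let chains hop between spiral windings.
    """
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = (diff * diff).sum(-1)
    chord = np.degrees(np.arctan2(-diff[..., 1], -diff[..., 0]))  # angle i->j
    u_i = _wrap_half(orientations[:, None] - chord)
    u_j = _wrap_half(orientations[None, :] - chord)
    dev = (u_i + u_j) / 2.0
    w = np.exp(-d2 / (2.0 * params.sigma_d ** 2)) * np.exp(
        -(2.0 * dev ** 2) / (2.0 * params.sigma_theta ** 2))
    np.fill_diagonal(w, 0.0)
    return w


def _best_chain(w: np.ndarray, positions: np.ndarray,
                params: AffinityParams) -> list[int]:
    """Highest-total-affinity simple chain by greedy beam search.

    States are ordered paths scored by the sum of edge affinities and
    extended at both ends; an extension is admitted only while its edge
    clears ``w_floor`` and its direction change from the previous link
    stays within ``max_turn_deg``, so the chain ends where the contour
    evidence ends instead of wandering into the background.  Ties are
    broken lexicographically on the path itself, making the search
    fully deterministic.
    """
    n = w.shape[0]
    max_links = min(params.max_links, n - 1)
    cos_turn_min = math.cos(math.radians(params.max_turn_deg))

    def turn_ok(a: int, b: int, c: int) -> bool:
        # direction change at b along a -> b -> c
        v1 = positions[b] - positions[a]
        v2 = positions[c] - positions[b]
        denom = float(np.linalg.norm(v1) * np.linalg.norm(v2))
        if denom == 0.0:
            return False
        return float(v1 @ v2) / denom >= cos_turn_min
    # seed beam with the best ordered pairs
    iu, ju = np.unravel_index(np.argsort(w, axis=None)[::-1], w.shape)
    beam: list[tuple[float, tuple[int, ...]]] = []
    seen = set()
    for i, j in zip(iu, ju):
        if (i, j) in seen or w[i, j] < params.w_floor:
            continue
        seen.add((i, j))
        beam.append((float(w[i, j]), (int(i), int(j))))
        if len(beam) >= 2 * params.beam_width:
            break
    if not beam:
        raise ValueError("no affinity above the floor; cannot extract a chain")
    beam.sort(key=lambda s: (-s[0], s[1]))
    beam = beam[: params.beam_width]
    finished: list[tuple[float, tuple[int, ...]]] = []
    for _ in range(max_links - 1):
        candidates: list[tuple[float, tuple[int, ...]]] = []
        for score, path in beam:
            used = set(path)
            extended = False
            for end, prev, attach in ((path[-1], path[-2], "tail"),
                                      (path[0], path[1], "head")):
                order = np.argsort(w[end])[::-1]
                added = 0
                for nxt in order:
                    nxt = int(nxt)
                    if nxt in used:
                        continue
                    if w[end, nxt] < params.w_floor:
                        break  # sorted: nothing better follows
                    if not turn_ok(prev, end, nxt):
                        continue
                    new = (path + (nxt,) if attach == "tail"
                           else (nxt,) + path)
                    candidates.append((score + float(w[end, nxt]), new))
                    extended = True
                    added += 1
                    if added >= params.beam_width:
                        break
            if not extended:
                finished.append((score, path))
        if not candidates:
            break
        candidates.sort(key=lambda s: (-s[0], s[1]))
        beam = candidates[: params.beam_width]
    finished.extend(beam)
    finished.sort(key=lambda s: (-s[0], s[1]))
    chain = list(finished[0][1])
    # trim weak terminal links: the sum score always rewards extra
    # edges, so the raw chain overshoots the contour into the background
    while len(chain) > 2:
        edges = [w[chain[i], chain[i + 1]] for i in range(len(chain) - 1)]
        cut = params.trim_frac * float(np.median(edges))
        if edges[0] < cut and edges[0] <= edges[-1]:
            chain.pop(0)
        elif edges[-1] < cut:
            chain.pop()
        else:
            break
    return chain


def _sector(x: float, y: float) -> str:
    if abs(x) >= abs(y):
        return "right" if x >= 0 else "left"
    return "up" if y >= 0 else "down"


def grouping_observer_respond(field: StimulusField,
                              params: AffinityParams | None = None,
                              rng: np.random.Generator | None = None) -> str:
    """Tail report of the grouping observer (deterministic given field).

    The response is the sector (relative to the field center) of the
    extracted chain's endpoint farthest from the pattern centroid.
    """
    params = params or AffinityParams()
    positions = field.positions()
    if len(positions) < 2:
        raise ValueError("need at least 2 elements")
    orientations = field.orientations()
    w = _affinity_matrix(positions, orientations, params)
    chain = _best_chain(w, positions, params)
    centroid = positions.mean(axis=0)
    ends = positions[[chain[0], chain[-1]]]
    far = ends[int(np.argmax(np.linalg.norm(ends - centroid, axis=1)))]
    # report the sector of the far endpoint relative to the extracted
    # chain's own centroid: the judgement is about the perceived object,
    # so it must not inherit the pattern's random center offset
    ref = positions[chain].mean(axis=0)
    return _sector(float(far[0] - ref[0]), float(far[1] - ref[1]))


# ---------------------------------------------------------------------------
# observer objects used by the session runner


class ParametricObserver:
    """Condition-driven observer; never needs the rendered stimulus."""

    needs_stimulus = False

    def __init__(self, params: ObserverParams):
        self.params = params

    def probability_correct(self, condition: Condition) -> float:
        return psychometric_prob(condition, self.params)

    def respond(self, condition: Condition, true_tail: str,
                rng: np.random.Generator) -> str:
        return respond(true_tail, self.probability_correct(condition), rng)


class GroupingObserver:
    """Element-list observer; requires the generated stimulus field."""

    needs_stimulus = True

    def __init__(self, params: AffinityParams | None = None):
        self.params = params or AffinityParams()

    def respond_field(self, field: StimulusField,
                      rng: np.random.Generator) -> str:
        return grouping_observer_respond(field, self.params, rng)


class OracleObserver:
    """Always correct (reads the true tail); a session-runner control."""

    needs_stimulus = False

    def respond(self, condition: Condition, true_tail: str,
                rng: np.random.Generator) -> str:
        return true_tail


class RandomObserver:
    """Uniform guessing at the 4AFC chance level."""

    needs_stimulus = False

    def respond(self, condition: Condition, true_tail: str,
                rng: np.random.Generator) -> str:
        return TAIL_LABELS[int(rng.integers(4))]
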