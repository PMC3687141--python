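"""Trial-sequence construction and session simulation.

Builders reproduce the three experimental designs (and the preliminary
distracter-free staircase) at their printed cell sizes; randomization
happens only within the printed blocking structure.  ``run_session``
plays a trial list against an observer, generating the stimulus on the
fly only when the observer needs it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .field_fill import (
    GABOR_WAVELENGTH_DEG,
    BackgroundCondition,
    Condition,
    FieldSpec,
    StimulusField,
    make_stimulus,
)
from .geometry import TAIL_LABELS_CCW, SpiralSpec, place_contour
from .render import frames_for_duration

__all__ = [
    "TrialSpec",
    "StaircaseState",
    "StaircaseResult",
    "TRIAL_TIMING",
    "EXP2_DURATIONS_S",
    "EXP3_BACKGROUND_TABLE",
    "tail_for",
    "rotation_for_tail",
    "build_experiment1_session",
    "build_experiment2_session",
    "build_experiment3_session",
    "run_session",
    "run_staircase",
]

#: Fixed trial-timing metadata (s): fixation flicker, post-stimulus
#: blank, inter-trial interval; the fixation flicker rate is 10 Hz.
TRIAL_TIMING = {
    "fixation_flicker_s": 0.3,
    "flicker_rate_hz": 10.0,
    "post_stimulus_blank_s": 0.5,
    "inter_trial_interval_s": 1.5,
}

EXP1_SPACINGS_LAMBDA = (2.0, 4.0, 6.0, 8.0)
EXP1_JITTERS_DEG = (0.0, 15.0, 30.0, 45.0, 60.0)
EXP1_TRIALS_PER_CELL = 25
EXP1_DURATION_S = 1.0

EXP2_SPACINGS_LAMBDA = (2.0, 6.0)
EXP2_JITTERS_DEG = (0.0, 30.0)
EXP2_DURATIONS_S = (0.04, 0.093, 0.20, 0.40, 0.80)
EXP2_TRIALS_PER_DURATION = 30

#: Experiment 3: nominal relative-spacing level -> distracter spacing
#: (multiples of lambda) for each contour spacing.
EXP3_BACKGROUND_TABLE = {
    3.0: ((1.0, 2.9), (1.2, 2.4), (1.5, 2.0), (1.8, 1.7), (2.1, 1.5)),
    6.0: ((1.0, 6.1), (1.2, 5.0), (1.5, 4.0), (1.8, 3.4), (2.1, 2.9)),
}
EXP3_ISO_REL_LEVELS = (1.0, 2.1)
EXP3_TRIALS_PER_CELL = 50
EXP3_DURATION_S = 0.4


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: condition, global pose (reflect + rotation;
    the center offset is drawn at stimulus time), and bookkeeping."""

    experiment: str
    block_index: int
    trial_index: int
    condition: Condition
    reflect: bool
    rotation: int
    true_tail: str


def tail_for(reflect: bool, rotation: int) -> str:
    """Tail label of the canonical spiral under (reflect, rotation)."""
    base = "left" if reflect else "right"
    idx = (TAIL_LABELS_CCW.index(base) + rotation // 90) % 4
    return TAIL_LABELS_CCW[idx]


def rotation_for_tail(label: str, reflect: bool) -> int:
    """Rotation placing the tail at ``label`` given the reflection."""
    base = "left" if reflect else "right"
    steps = (TAIL_LABELS_CCW.index(label) - TAIL_LABELS_CCW.index(base)) % 4
    return 90 * steps


def _balanced_tails(n: int, rng: np.random.Generator) -> list[str]:
    """n tail labels, each appearing floor(n/4) or ceil(n/4) times."""
    reps = -(-n // 4)
    labels = (list(TAIL_LABELS_CCW) * reps)[:n]
    rng.shuffle(labels)
    return labels


def _make_trial(experiment: str, block: int, index: int, condition: Condition,
                tail: str, rng: np.random.Generator) -> TrialSpec:
    reflect = bool(rng.integers(2))
    return TrialSpec(experiment=experiment, block_index=block,
                     trial_index=index, condition=condition, reflect=reflect,
                     rotation=rotation_for_tail(tail, reflect), true_tail=tail)


def build_experiment1_session(rng: np.random.Generator) -> list[TrialSpec]:
    """Four spacing blocks (2, 4, 6, 8 lambda) in random order; within
    each block 25 trials at each of five jitter levels, intermixed;
    stimulus duration 1 s; distracter spacing equals contour spacing."""
    trials: list[TrialSpec] = []
    spacing_order = rng.permutation(len(EXP1_SPACINGS_LAMBDA))
    index = 0
    for block, si in enumerate(spacing_order):
        lam = EXP1_SPACINGS_LAMBDA[si]
        cell: list[tuple[float, str]] = []
        for j in EXP1_JITTERS_DEG:
            cell += [(j, t) for t in
                     _balanced_tails(EXP1_TRIALS_PER_CELL, rng)]
        rng.shuffle(cell)
        for j, tail in cell:
            cond = Condition(spacing_deg=lam * GABOR_WAVELENGTH_DEG,
                             jitter_deg=j, duration_s=EXP1_DURATION_S)
            trials.append(_make_trial("exp1", block, index, cond, tail, rng))
            index += 1
    return trials


def build_experiment2_session(rng: np.random.Generator) -> list[TrialSpec]:
    """Four blocks ({2, 6} lambda x {0, 30} deg jitter) in random order;
    150 trials per block, 30 at each of five durations, intermixed."""
    blocks = [(lam, j) for lam in EXP2_SPACINGS_LAMBDA
              for j in EXP2_JITTERS_DEG]
    order = rng.permutation(len(blocks))
    trials: list[TrialSpec] = []
    index = 0
    for block, bi in enumerate(order):
        lam, j = blocks[bi]
        cell: list[tuple[float, str]] = []
        for dur in EXP2_DURATIONS_S:
            cell += [(dur, t) for t in
                     _balanced_tails(EXP2_TRIALS_PER_DURATION, rng)]
        rng.shuffle(cell)
        for dur, tail in cell:
            cond = Condition(spacing_deg=lam * GABOR_WAVELENGTH_DEG,
                             jitter_deg=j, duration_s=dur)
            trials.append(_make_trial("exp2", block, index, cond, tail, rng))
            index += 1
    return trials


def build_experiment3_session(rng: np.random.Generator,
                              design_variant: str = "full_crossing"
                              ) -> list[TrialSpec]:
    """Two contour-spacing blocks (3 and 6 lambda, order randomized);
    within a block, random backgrounds at five relative-spacing levels
    plus iso backgrounds at the two stated levels, 50 trials per cell,
    intermixed; duration 0.4 s.

    ``full_crossing`` keeps every printed cell (700 trials);
    ``printed_total`` drops the iso cell at relative spacing 1.0 in each
    block, matching the printed 600-trial total.
    """
    if design_variant not in ("full_crossing", "printed_total"):
        raise ValueError(f"unknown design_variant {design_variant!r}")
    iso_levels = (EXP3_ISO_REL_LEVELS if design_variant == "full_crossing"
                  else EXP3_ISO_REL_LEVELS[1:])
    spacing_order = rng.permutation(len(EXP3_BACKGROUND_TABLE))
    spacings = sorted(EXP3_BACKGROUND_TABLE)
    trials: list[TrialSpec] = []
    index = 0
    for block, si in enumerate(spacing_order):
        lam = spacings[si]
        conds: list[Condition] = []
        for rel_label, dist_lam in EXP3_BACKGROUND_TABLE[lam]:
            bg = BackgroundCondition(d_min=dist_lam * GABOR_WAVELENGTH_DEG,
                                     mode="random")
            conds.append(Condition(spacing_deg=lam * GABOR_WAVELENGTH_DEG,
                                   background=bg, duration_s=EXP3_DURATION_S,
                                   rel_label=rel_label))
        for rel_label, dist_lam in EXP3_BACKGROUND_TABLE[lam]:
            if rel_label in iso_levels:
                bg = BackgroundCondition(d_min=dist_lam * GABOR_WAVELENGTH_DEG,
                                         mode="iso")
                conds.append(Condition(spacing_deg=lam * GABOR_WAVELENGTH_DEG,
                                       background=bg,
                                       duration_s=EXP3_DURATION_S,
                                       rel_label=rel_label))
        cell: list[tuple[Condition, str]] = []
        for cond in conds:
            cell += [(cond, t) for t in
                     _balanced_tails(EXP3_TRIALS_PER_CELL, rng)]
        rng.shuffle(cell)
        for cond, tail in cell:
            trials.append(_make_trial("exp3", block, index, cond, tail, rng))
            index += 1
    return trials


def run_session(trials: Sequence[TrialSpec], observer,
                rng: np.random.Generator, subject: str = "s01",
                group: str = "younger",
                spiral_spec: SpiralSpec | None = None,
                field_spec: FieldSpec | None = None) -> pd.DataFrame:
    """Play a trial list against an observer; one record per trial.

    Stimulus fields are generated only for observers that need them
    (``observer.needs_stimulus``); parametric observers respond from the
    condition alone.  Fully reproducible from the generator state.
    """
    rows = []
    for trial in trials:
        if getattr(observer, "needs_stimulus", False):
            fieldobj = make_stimulus(trial.condition, rng,
                                     spiral_spec=spiral_spec,
                                     field_spec=field_spec,
                                     reflect=trial.reflect,
                                     rotation=trial.rotation)
            true_tail = fieldobj.tail
            try:
                response = observer.respond_field(fieldobj, rng)
            except Exception as exc:  # surface the trial context
                raise RuntimeError(
                    f"observer failed on trial {trial.trial_index} "
                    f"(block {trial.block_index}, {trial.experiment})"
                ) from exc
        else:
            true_tail = trial.true_tail
            response = observer.respond(trial.condition, true_tail, rng)
        cond = trial.condition
        rows.append({
            "subject": subject,
            "group": group,
            "experiment": trial.experiment,
            "block": trial.block_index,
            "trial": trial.trial_index,
            "spacing_lambda": cond.spacing_lambda,
            "spacing_deg": cond.spacing_deg,
            "jitter_deg": cond.jitter_deg,
            "duration_s": cond.duration_s,
            "frames": frames_for_duration(cond.duration_s),
            "background_mode": cond.background.mode,
            "d_min_deg": cond.background.d_min,
            "rel_label": (cond.rel_label if cond.rel_label is not None
                          else round(cond.relative_spacing, 1)),
            "rel_exact": cond.relative_spacing,
            "reflect": trial.reflect,
            "rotation": trial.rotation,
            "true_tail": true_tail,
            "response": response,
            "correct": response == true_tail,
            **TRIAL_TIMING,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# preliminary staircase (distracter-free partial contours)


@dataclass
class StaircaseState:
    """Adaptive track state: current element count, the 2-down/1-up
    counters, reversal values, trial history and the per-trial segment
    location (head, tail or middle of the spiral)."""

    n_elements: int
    n_min: int
    n_max: int
    step: int = 1
    correct_streak: int = 0
    last_direction: int = 0
    reversals: list[int] = dc_field(default_factory=list)
    history: list[tuple[int, bool, str]] = dc_field(default_factory=list)
    segment_location: str = "middle"

    def update(self, correct: bool) -> None:
        direction = 0
        if correct:
            self.correct_streak += 1
            if self.correct_streak >= 2:
                direction = -1
                self.correct_streak = 0
        else:
            self.correct_streak = 0
            direction = +1
        if direction:
            if self.last_direction and direction != self.last_direction:
                self.reversals.append(self.n_elements)
            self.last_direction = direction
            self.n_elements = int(np.clip(self.n_elements + direction * self.step,
                                          self.n_min, self.n_max))


@dataclass(frozen=True)
class StaircaseResult:
    """Threshold (element count at the target accuracy), the fitted
    Weibull parameters, a status flag ('ok', 'fallback' for the
    reversal-mean fallback, 'floor' when performance never leaves
    ceiling) and the raw track."""

    threshold: float
    alpha: float | None
    beta: float | None
    flag: str
    reversals: tuple[int, ...]
    trials: pd.DataFrame


_GUESS = 0.25
_LAPSE_FIXED = 0.01


def _weibull_pc(n: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    s = 1.0 - np.exp(-np.power(np.asarray(n, dtype=float) / alpha, beta))
    return _GUESS + (1.0 - _GUESS - _LAPSE_FIXED) * s


def _weibull_threshold(alpha: float, beta: float, target: float = 0.75) -> float:
    frac = (target - _GUESS) / (1.0 - _GUESS - _LAPSE_FIXED)
    return alpha * (-math.log(1.0 - frac)) ** (1.0 / beta)


def _fit_weibull(ns: np.ndarray, correct: np.ndarray,
                 n_max: int) -> tuple[float, float] | None:
    def nll(theta: np.ndarray) -> float:
        pc = np.clip(_weibull_pc(ns, theta[0], theta[1]), 1e-9, 1 - 1e-9)
        return -float(np.sum(np.where(correct, np.log(pc), np.log1p(-pc))))

    best = None
    for a0, b0 in ((np.median(ns), 3.0), (n_max / 2.0, 1.5), (4.0, 5.0)):
        res = minimize(nll, x0=np.array([a0, b0]), method="L-BFGS-B",
                       bounds=[(0.5, 4.0 * n_max), (0.2, 20.0)])
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return None
    return float(best.x[0]), float(best.x[1])


def run_staircase(pc_of_n: Callable[[int], float], spacing_deg: float,
                  rng: np.random.Generator, n_reversals: int = 12,
                  max_trials: int = 400, target: float = 0.75,
                  spiral_spec: SpiralSpec | None = None) -> StaircaseResult:
    """2-down/1-up staircase on the number of visible contour elements.

    ``pc_of_n`` gives the observer's probability of a correct tail
    report when ``n`` adjacent elements of the distracter-free contour
    are shown.  The track starts from the full chain, steps by one
    element, and stops after ``n_reversals`` reversals (or
    ``max_trials``).  The threshold is the ``target`` point of a Weibull
    psychometric function fitted to every trial by maximum likelihood;
    if the fit fails, the mean of the last reversals is reported and
    flagged.
    """
    spiral_spec = spiral_spec or SpiralSpec()
    n_max = len(place_contour(spiral_spec, spacing_deg, t_jitter=0.0))
    state = StaircaseState(n_elements=n_max, n_min=2, n_max=n_max)
    locations = ("head", "tail", "middle")
    while len(state.reversals) < n_reversals and len(state.history) < max_trials:
        state.segment_location = locations[int(rng.integers(3))]
        n = state.n_elements
        correct = bool(rng.random() < pc_of_n(n))
        state.history.append((n, correct, state.segment_location))
        state.update(correct)

    trials = pd.DataFrame(state.history,
                          columns=["n_elements", "correct", "segment_location"])
    ns = trials["n_elements"].to_numpy()
    corr = trials["correct"].to_numpy()

    fit = _fit_weibull(ns, corr, n_max)
    if fit is not None:
        alpha, beta = fit
        threshold = _weibull_threshold(alpha, beta, target)
        flag = "ok"
        if threshold <= state.n_min:
            flag = "floor"
        elif threshold > n_max:
            flag = "ceiling"
    else:
        alpha = beta = None
        threshold = float(np.mean(state.reversals)) if state.reversals else float(n_max)
        flag = "fallback"
    return StaircaseResult(threshold=float(threshold), alpha=alpha, beta=beta,
                           flag=flag, reversals=tuple(state.reversals),
                           trials=trials)
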