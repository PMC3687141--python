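"""Distracter placement and full stimulus assembly.

Distracters are added by iterative rejection sampling (random sequential
adsorption): uniform candidate positions in the square are accepted iff
they keep a minimum center-to-center distance from every element already
present, and the fill stops after a long run of consecutive rejections,
which operationalizes "until no more elements could be placed".

The minimum distance ``d_min`` governs every pair that involves a
distracter; contour-contour spacing is fixed separately by the chain
construction.  In the equal-spacing configuration (d_min = contour
spacing) the background carries no local density cue to the contour's
location; when d_min is reduced below the contour spacing, distracters
become denser than the contour (relative spacing > 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    ContourChain,
    Element,
    Pose,
    SpiralSpec,
    apply_orientation_jitter,
    draw_pose,
    place_contour,
    pose_pattern,
    tail_location,
)

__all__ = [
    "FieldSpec",
    "BackgroundCondition",
    "Condition",
    "StimulusField",
    "fill_distracters",
    "assign_background_orientations",
    "make_stimulus",
    "min_pairwise_distance",
]

GABOR_WAVELENGTH_DEG = 0.30  # lambda; spacings quoted in multiples of it


@dataclass(frozen=True)
class FieldSpec:
    """Square stimulus region (side in deg) and the sigma of the random
    pattern center offset."""

    extent: float = 9.5
    center_offset_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ValueError("extent must be positive")


@dataclass(frozen=True)
class BackgroundCondition:
    """Distracter placement/orientation condition.

    d_min : minimum pairwise center distance (deg) for any pair involving
    a distracter; mode : 'random' (iid uniform orientations) or 'iso'
    (one random mean orientation per trial, Gaussian spread iso_sigma).
    """

    d_min: float
    mode: str = "random"
    iso_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.mode not in ("random", "iso"):
            raise ValueError(f"unknown background mode {self.mode!r}")

    def relative_spacing(self, contour_spacing: float) -> float:
        """Contour spacing / distracter minimum spacing (dimensionless)."""
        return contour_spacing / self.d_min


@dataclass(frozen=True)
class Condition:
    """Complete per-trial stimulus condition."""

    spacing_deg: float
    jitter_deg: float = 0.0
    background: BackgroundCondition | None = None
    duration_s: float = 1.0
    rel_label: float | None = None  # nominal relative-spacing level

    def __post_init__(self) -> None:
        if self.background is None:
            # equal contour and distracter spacing (Experiments 1-2 default)
            object.__setattr__(self, "background",
                               BackgroundCondition(d_min=self.spacing_deg))

    @property
    def spacing_lambda(self) -> float:
        return self.spacing_deg / GABOR_WAVELENGTH_DEG

    @property
    def relative_spacing(self) -> float:
        return self.background.relative_spacing(self.spacing_deg)


@dataclass(frozen=True)
class StimulusField:
    """One trial's element list plus its condition metadata."""

    field_spec: FieldSpec
    elements: tuple[Element, ...]
    condition: Condition
    tail: str
    pose: Pose | None = None
    seed: int | None = None

    def positions(self, role: str | None = None) -> np.ndarray:
        els = [e for e in self.elements if role is None or e.role == role]
        return np.array([[e.x, e.y] for e in els]).reshape(-1, 2)

    def orientations(self, role: str | None = None) -> np.ndarray:
        return np.array([e.orientation for e in self.elements
                         if role is None or e.role == role])

    @property
    def n_contour(self) -> int:
        return sum(e.role == "contour" for e in self.elements)

    @property
    def n_distracters(self) -> int:
        return sum(e.role == "distracter" for e in self.elements)

    def to_frame(self) -> pd.DataFrame:
        """Element manifest (role, x_deg, y_deg, orientation_deg, path_t)."""
        return pd.DataFrame(
            {
                "role": [e.role for e in self.elements],
                "x_deg": [e.x for e in self.elements],
                "y_deg": [e.y for e in self.elements],
                "orientation_deg": [e.orientation for e in self.elements],
                "path_t": [e.path_t for e in self.elements],
            }
        )

    def to_manifest(self, spiral_spec: "SpiralSpec | None" = None) -> dict:
        """JSON-ready trial metadata: field, pose, condition, tail."""
        from dataclasses import asdict

        cond = self.condition
        return {
            "field": asdict(self.field_spec),
            "spiral": asdict(spiral_spec) if spiral_spec is not None else None,
            "pose": asdict(self.pose) if self.pose is not None else None,
            "condition": {
                "spacing_deg": cond.spacing_deg,
                "spacing_lambda": cond.spacing_lambda,
                "jitter_deg": cond.jitter_deg,
                "duration_s": cond.duration_s,
                "d_min_deg": cond.background.d_min,
                "background_mode": cond.background.mode,
                "iso_sigma_deg": cond.background.iso_sigma,
                "relative_spacing": cond.relative_spacing,
                "rel_label": cond.rel_label,
            },
            "tail": self.tail,
            "seed": self.seed,
            "n_contour": self.n_contour,
            "n_distracters": self.n_distracters,
        }


def _fill_positions(existing: np.ndarray, extent: float, d_min: float,
                    rng: np.random.Generator,
                    max_consecutive_rejects: int) -> np.ndarray:
    """Accepted distracter positions, in acceptance order.

    Candidates are drawn as one sequential uniform stream and screened in
    order; chunking is only a vectorization detail and does not change
    the accept/reject sequence for a given generator state.
    """
    half = extent / 2.0
    placed: list[np.ndarray] = []
    consecutive = 0
    d2 = d_min * d_min
    chunk = 2048
    while consecutive < max_consecutive_rejects:
        cand = rng.uniform(-half, half, size=(chunk, 2))
        if len(existing) or placed:
            base = np.concatenate(
                [existing.reshape(-1, 2)] + ([np.array(placed)] if placed else [])
            )
        else:
            base = np.empty((0, 2))
        if len(base):
            diff = cand[:, None, :] - base[None, :, :]
            ok_base = (diff * diff).sum(-1).min(axis=1) >= d2
        else:
            ok_base = np.ones(chunk, dtype=bool)
        new_in_chunk: list[np.ndarray] = []
        for i in range(chunk):
            if consecutive >= max_consecutive_rejects:
                break
            accept = bool(ok_base[i])
            if accept and new_in_chunk:
                d = cand[i] - np.array(new_in_chunk)
                accept = float((d * d).sum(-1).min()) >= d2
            if accept:
                new_in_chunk.append(cand[i])
                consecutive = 0
            else:
                consecutive += 1
        placed.extend(new_in_chunk)
    return np.array(placed).reshape(-1, 2)


def fill_distracters(field: StimulusField, d_min: float | None = None,
                     rng: np.random.Generator | None = None,
                     max_consecutive_rejects: int = 10_000) -> StimulusField:
    """Add distracters until the field is (near-)saturated.

    A candidate is accepted iff its distance to every existing element --
    contour and distracter alike -- is at least ``d_min``.  Filling stops
    after ``max_consecutive_rejects`` consecutive rejections.
    """
    if rng is None:
        raise ValueError("fill_distracters needs an rng")
    if d_min is None:
        d_min = field.condition.background.d_min
    existing = field.positions()
    pts = _fill_positions(existing, field.field_spec.extent, d_min, rng,
                          max_consecutive_rejects)
    distracters = tuple(
        Element(x=float(p[0]), y=float(p[1]), orientation=0.0,
                role="distracter")
        for p in pts
    )
    return replace(field, elements=field.elements + distracters)


def assign_background_orientations(field: StimulusField,
                                   mode: str | None = None,
                                   iso_sigma: float | None = None,
                                   rng: np.random.Generator | None = None
                                   ) -> StimulusField:
    """Orient the distracters; contour orientations are untouched.

    random mode: iid Uniform[0, 360).  iso mode: one mean mu ~
    Uniform[0, 360) per trial, then iid Normal(mu, iso_sigma) mod 360.
    """
    if rng is None:
        raise ValueError("assign_background_orientations needs an rng")
    bg = field.condition.background
    mode = bg.mode if mode is None else mode
    iso_sigma = bg.iso_sigma if iso_sigma is None else iso_sigma
    n = field.n_distracters
    if mode == "random":
        oris = rng.uniform(0.0, 360.0, size=n)
    elif mode == "iso":
        mu = rng.uniform(0.0, 360.0)
        oris = np.mod(rng.normal(mu, iso_sigma, size=n), 360.0)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    it = iter(oris)
    new = tuple(
        e if e.role == "contour" else replace(e, orientation=float(next(it)))
        for e in field.elements
    )
    return replace(field, elements=new)


def make_stimulus(condition: Condition, rng: np.random.Generator,
                  spiral_spec: SpiralSpec | None = None,
                  field_spec: FieldSpec | None = None,
                  pose: Pose | None = None,
                  reflect: bool | None = None, rotation: int | None = None,
                  max_consecutive_rejects: int = 10_000) -> StimulusField:
    """Build one complete trial stimulus.

    Spiral chain built with per-trial start jitter, orientation-jittered,
    posed (random reflect/rotation/offset unless ``pose`` pins them),
    then background-filled and oriented.
    """
    spiral_spec = spiral_spec or SpiralSpec()
    field_spec = field_spec or FieldSpec()
    chain = place_contour(spiral_spec, condition.spacing_deg, rng=rng)
    chain = apply_orientation_jitter(chain, condition.jitter_deg, rng)
    if pose is None:
        pose = draw_pose(chain.elements, field_spec.extent, rng,
                         offset_sigma=field_spec.center_offset_sigma,
                         reflect=reflect, rotation=rotation)
    posed = pose_pattern(chain.elements, pose, field_spec.extent)
    tail = tail_location(chain, pose)
    fieldobj = StimulusField(field_spec=field_spec, elements=tuple(posed),
                             condition=condition, tail=tail, pose=pose)
    fieldobj = fill_distracters(fieldobj, rng=rng,
                                max_consecutive_rejects=max_consecutive_rejects)
    fieldobj = assign_background_orientations(fieldobj, rng=rng)
    return fieldobj


def min_pairwise_distance(field: StimulusField,
                          involving_distracter: bool = True) -> float:
    """Smallest center-to-center distance, optionally restricted to pairs
    that involve at least one distracter (the pairs governed by d_min)."""
    pts = field.positions()
    n = len(pts)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    iu = np.triu_indices(n, k=1)
    dvals = d[iu]
    if involving_distracter:
        roles = np.array([e.role == "distracter" for e in field.elements])
        mask = roles[iu[0]] | roles[iu[1]]
        dvals = dvals[mask]
    return float(dvals.min()) if len(dvals) else math.inf
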