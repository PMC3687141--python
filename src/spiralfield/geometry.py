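"""Logarithmic-spiral contour geometry.

The contour is an equiangular (logarithmic) spiral ``r = a * exp(b * t)``
with the polar angle tied to the path parameter by ``theta = kappa * t``.
Gabor elements are stepped along the path at a constant arc-length
spacing (the closed-form inverse of the equiangular spiral's cumulative
length), each oriented along the local tangent.  Chord (center-to-center)
distances are then shorter than the arc spacing by the sagitta effect:
under 1% at 2-lambda spacing, up to ~10% at 8-lambda, and nearly constant
along the chain.  The radius law and the parameter range are
fixed stimulus constants; the angular scale ``kappa`` is calibrated once
so that the 2-lambda spacing condition (0.6 deg) holds exactly 26
elements, and is then held fixed for every other spacing.

Coordinates are degrees of visual angle, origin at the field center,
+x right, +y up.  The canonical (unreflected, unrotated) spiral is
phase-aligned so that its tail (the outer end, t = t_max) lies on the
+x axis, i.e. in the "right" response sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpiralSpec",
    "Element",
    "ContourChain",
    "Pose",
    "calibrate_kappa",
    "default_kappa",
    "spiral_point",
    "contour_tangent",
    "arc_length",
    "place_contour",
    "apply_orientation_jitter",
    "pose_pattern",
    "draw_pose",
    "tail_location",
    "TAIL_LABELS_CCW",
]

#: 4AFC response labels in counterclockwise order starting from the
#: canonical tail sector.
TAIL_LABELS_CCW = ("right", "up", "left", "down")


@dataclass(frozen=True)
class SpiralSpec:
    """Parameters of the spiral path.

    a : radial scale (deg); b : dimensionless growth rate;
    t_min, t_max : path-parameter bounds; t_jitter_halfwidth : half-range
    of the uniform per-trial start jitter (t units); kappa : angular scale
    (rad per t unit, calibrated when None); handedness : winding direction
    of the canonical spiral.
    """

    a: float = 1.18
    b: float = 0.20
    t_min: float = 1.25
    t_max: float = 3.0
    t_jitter_halfwidth: float = 0.1
    kappa: float | None = None
    handedness: str = "counterclockwise"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be below t_max")
        if self.t_jitter_halfwidth < 0:
            raise ValueError("t_jitter_halfwidth must be >= 0")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.handedness not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown handedness {self.handedness!r}")

    def resolved_kappa(self) -> float:
        return self.kappa if self.kappa is not None else default_kappa()

    @property
    def t_lo(self) -> float:
        """Lowest admissible path parameter (start jitter included)."""
        return self.t_min - self.t_jitter_halfwidth


@dataclass(frozen=True)
class Element:
    """One oriented micropattern: position (deg), stripe-axis orientation
    (deg CCW from +x, stored in [0, 360)), role, and, for contour
    elements, the path parameter it was placed at."""

    x: float
    y: float
    orientation: float
    role: str = "contour"
    path_t: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", self.orientation % 360.0)
        if self.role not in ("contour", "distracter"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class ContourChain:
    """Ordered contour elements from head (inner end) to tail (outer
    end), spaced at constant path length; successive chord distances
    fall below ``spacing`` by the chord-arc (sagitta) difference, which
    grows with spacing and shrinks slowly along the chain as the local
    curvature radius grows."""

    elements: tuple[Element, ...]
    spacing: float

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("a contour chain needs at least 2 elements")
        object.__setattr__(self, "elements", tuple(self.elements))

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def tail(self) -> Element:
        return self.elements[-1]

    def positions(self) -> np.ndarray:
        return np.array([[e.x, e.y] for e in self.elements])

    def chord_distances(self) -> np.ndarray:
        p = self.positions()
        return np.linalg.norm(np.diff(p, axis=0), axis=1)


@dataclass(frozen=True)
class Pose:
    """Global pattern pose: mirror about the vertical axis, then rotate
    CCW about the field center by a multiple of 90 deg, then translate."""

    reflect: bool = False
    rotation: int = 0
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")


# ---------------------------------------------------------------------------
# spiral path


def _point_raw(a: float, b: float, kappa: float, phase: float, t: float) -> np.ndarray:
    r = a * math.exp(b * t)
    th = kappa * t + phase
    return np.array([r * math.cos(th), r * math.sin(th)])


def _phase(spec: SpiralSpec, kappa: float) -> float:
    # align the tail (t = t_max) with the +x axis
    return -kappa * spec.t_max


def _check_domain(spec: SpiralSpec, t: float) -> None:
    if not (spec.t_lo - 1e-9 <= t <= spec.t_max + 1e-9):
        raise ValueError(
            f"path parameter t={t} outside [{spec.t_lo}, {spec.t_max}]"
        )


def spiral_point(spec: SpiralSpec, t: float) -> np.ndarray:
    """Position (x, y) in deg of the spiral at path parameter ``t``."""
    _check_domain(spec, t)
    kappa = spec.resolved_kappa()
    p = _point_raw(spec.a, spec.b, kappa, _phase(spec, kappa), t)
    if spec.handedness == "clockwise":
        p = p * np.array([-1.0, 1.0])
    return p


def contour_tangent(spec: SpiralSpec, t: float) -> float:
    """Tangent orientation (deg CCW from +x) at ``t``, pointing toward
    increasing t.  Stored in [0, 360); collinearity comparisons should be
    taken mod 180."""
    _check_domain(spec, t)
    kappa = spec.resolved_kappa()
    b = spec.b
    th = kappa * t + _phase(spec, kappa)
    # d/dt of (r cos th, r sin th) with r' = b r, th' = kappa
    dx = b * math.cos(th) - kappa * math.sin(th)
    dy = b * math.sin(th) + kappa * math.cos(th)
    if spec.handedness == "clockwise":
        dx = -dx
    return math.degrees(math.atan2(dy, dx)) % 360.0


def arc_length(spec: SpiralSpec, t_from: float | None = None,
               t_to: float | None = None) -> float:
    """Closed-form path length of the spiral between two parameters."""
    t0 = spec.t_min if t_from is None else t_from
    t1 = spec.t_max if t_to is None else t_to
    kappa = spec.resolved_kappa()
    b, a = spec.b, spec.a
    return (math.sqrt(1.0 + (b / kappa) ** 2) * (a * kappa / b)
            * (math.exp(b * t1) - math.exp(b * t0)))


# ---------------------------------------------------------------------------
# arc-length stepping and kappa calibration
#
# Elements sit at equal increments of path length.  For the equiangular
# spiral the cumulative arc length has the closed form
#   L(t0, t) = C * (exp(b t) - exp(b t0)),  C = (a / b) * sqrt(kappa^2 + b^2),
# so the next element's parameter solves exp(b t') = exp(b t) + spacing / C
# exactly.  The resulting center-to-center (chord) distances fall short
# of the arc spacing by the curvature-dependent sagitta factor
# 2*rho*sin(s / (2*rho)) / s (rho = local curvature radius): <1% at
# 2-lambda spacing, ~10% at 8-lambda.


def _arc_coeff(spec: SpiralSpec, kappa: float) -> float:
    return (spec.a / spec.b) * math.sqrt(kappa * kappa + spec.b * spec.b)


def _next_t(spec: SpiralSpec, kappa: float, t: float, spacing: float) -> float | None:
    """Parameter one arc-length ``spacing`` beyond ``t``, or None if that
    point lies past t_max."""
    if t >= spec.t_max:
        return None
    c = _arc_coeff(spec, kappa)
    t_next = math.log(math.exp(spec.b * t) + spacing / c) / spec.b
    return t_next if t_next <= spec.t_max + 1e-12 else None


def _chain_ts(spec: SpiralSpec, kappa: float, spacing: float,
              t_start: float) -> list[float]:
    ts = [t_start]
    while True:
        t_next = _next_t(spec, kappa, ts[-1], spacing)
        if t_next is None:
            break
        ts.append(t_next)
    return ts


def _count_for_kappa(kappa: float, spacing: float, spec: SpiralSpec) -> int:
    return len(_chain_ts(spec, kappa, spacing, spec.t_min))


@lru_cache(maxsize=8)
def calibrate_kappa(a: float = 1.18, b: float = 0.20, t_min: float = 1.25,
                    t_max: float = 3.0, spacing: float = 0.6,
                    target_count: int = 26) -> float:
    """Angular scale calibrated on the reference spacing condition alone.

    Finds the closed interval of kappa values for which arc-length
    stepping at ``spacing`` (start jitter disabled) places exactly
    ``target_count`` elements, and returns its midpoint.  The element
    counts at all other spacings then follow from the geometry with no
    further freedom.
    """
    spec = SpiralSpec(a=a, b=b, t_min=t_min, t_max=t_max, kappa=1.0)

    def count(k: float) -> int:
        return _count_for_kappa(k, spacing, spec)

    # bracket the target count by scanning, then bisect both boundaries
    k_lo = 0.5
    k_mid_seed = None
    for k in np.arange(0.5, 40.0, 0.05):
        c = count(float(k))
        if c < target_count:
            k_lo = float(k)
        elif c == target_count:
            k_mid_seed = float(k)
            break
        else:
            raise RuntimeError("scan overshot the target element count")
    if k_mid_seed is None:
        raise RuntimeError("could not bracket the target element count")

    def bisect_edge(lo: float, hi: float, below: int) -> float:
        # count(lo) <= below < count(hi); returns the transition point
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if count(mid) <= below:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lower = bisect_edge(k_lo, k_mid_seed, target_count - 1)
    hi_scan = k_mid_seed
    while count(hi_scan) <= target_count:
        hi_scan += 0.25
    upper = bisect_edge(k_mid_seed, hi_scan, target_count)
    return 0.5 * (lower + upper)


def default_kappa() -> float:
    """kappa from the default calibration (2-lambda condition, 26 elements)."""
    return calibrate_kappa()


# ---------------------------------------------------------------------------
# element placement


def place_contour(spec: SpiralSpec, spacing: float,
                  rng: np.random.Generator | None = None,
                  t_jitter: float | None = None) -> ContourChain:
    """Step elements along the spiral at constant spacing.

    The first element sits at ``t_min + tj`` where the start jitter tj is
    drawn Uniform(-halfwidth, +halfwidth) from ``rng`` (or given
    explicitly; defaults to 0).  Each subsequent element lies one
    ``spacing`` of path length beyond its predecessor (closed form);
    placement stops when no further point fits below t_max.  Successive
    center-to-center distances sit below ``spacing`` by the chord-vs-arc
    (sagitta) factor, which varies slowly along the chain with the local
    curvature radius.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing >= arc_length(spec):
        raise ValueError("spacing exceeds the total path length")
    if t_jitter is None:
        if rng is not None and spec.t_jitter_halfwidth > 0:
            t_jitter = float(rng.uniform(-spec.t_jitter_halfwidth,
                                         spec.t_jitter_halfwidth))
        else:
            t_jitter = 0.0
    if abs(t_jitter) > spec.t_jitter_halfwidth + 1e-12:
        raise ValueError("t_jitter outside the configured half-range")

    kappa = spec.resolved_kappa()
    ts = _chain_ts(spec, kappa, spacing, spec.t_min + t_jitter)
    if len(ts) < 2:
        raise ValueError(f"spacing {spacing} deg too large to fit 2 elements")
    elements = []
    for t in ts:
        p = spiral_point(spec, t)
        elements.append(Element(x=float(p[0]), y=float(p[1]),
                                orientation=contour_tangent(spec, t),
                                role="contour", path_t=t))
    return ContourChain(elements=tuple(elements), spacing=spacing)


def apply_orientation_jitter(chain: ContourChain, jitter_halfrange: float,
                             rng: np.random.Generator) -> ContourChain:
    """Add an independent Uniform(-J, +J) offset to each element's
    orientation; positions are untouched."""
    if jitter_halfrange < 0:
        raise ValueError("jitter half-range must be >= 0")
    if jitter_halfrange == 0:
        return chain
    offsets = rng.uniform(-jitter_halfrange, jitter_halfrange, size=len(chain))
    new = tuple(
        replace(e, orientation=(e.orientation + dj) % 360.0)
        for e, dj in zip(chain.elements, offsets)
    )
    return ContourChain(elements=new, spacing=chain.spacing)


# ---------------------------------------------------------------------------
# pose


def _apply_pose_arrays(xy: np.ndarray, ori: np.ndarray, pose: Pose
                       ) -> tuple[np.ndarray, np.ndarray]:
    xy = xy.copy()
    ori = ori.copy()
    if pose.reflect:
        xy[:, 0] = -xy[:, 0]
        ori = (180.0 - ori) % 360.0
    if pose.rotation:
        c = math.cos(math.radians(pose.rotation))
        s = math.sin(math.radians(pose.rotation))
        rot = np.array([[c, -s], [s, c]])
        xy = xy @ rot.T
        ori = (ori + pose.rotation) % 360.0
    xy[:, 0] += pose.offset_x
    xy[:, 1] += pose.offset_y
    return xy, ori


def pose_pattern(elements: Sequence[Element], pose: Pose,
                 field_extent: float | None = None) -> list[Element]:
    """Apply reflection, rotation and offset to a pattern.

    If ``field_extent`` is given, every *contour* element center must land
    inside the centered square of that side; a violation raises (offsets
    are resampled upstream, see :func:`draw_pose`).
    """
    xy = np.array([[e.x, e.y] for e in elements], dtype=float)
    ori = np.array([e.orientation for e in elements], dtype=float)
    xy, ori = _apply_pose_arrays(xy, ori, pose)
    if field_extent is not None:
        half = field_extent / 2.0
        contour = np.array([e.role == "contour" for e in elements])
        if contour.any() and (np.abs(xy[contour]) > half).any():
            raise ValueError("posed contour leaves the stimulus square")
    return [replace(e, x=float(p[0]), y=float(p[1]), orientation=float(o))
            for e, p, o in zip(elements, xy, ori)]


def draw_pose(elements: Sequence[Element], field_extent: float,
              rng: np.random.Generator, offset_sigma: float = 1.5,
              reflect: bool | None = None, rotation: int | None = None,
              max_tries: int = 1000) -> Pose:
    """Draw a random pose whose offsets keep all contour-element centers
    inside the field square, resampling the Normal(0, sigma) offsets up
    to ``max_tries`` times."""
    if reflect is None:
        reflect = bool(rng.integers(2))
    if rotation is None:
        rotation = int(rng.choice((0, 90, 180, 270)))
    for _ in range(max_tries):
        pose = Pose(reflect=reflect, rotation=rotation,
                    offset_x=float(rng.normal(0.0, offset_sigma)),
                    offset_y=float(rng.normal(0.0, offset_sigma)))
        try:
            pose_pattern(elements, pose, field_extent)
        except ValueError:
            continue
        return pose
    raise RuntimeError(
        f"no containing offset found in {max_tries} draws "
        f"(extent {field_extent} deg)")


def tail_location(chain: ContourChain, pose: Pose) -> str:
    """4AFC label of the spiral's tail under a pose.

    Computed from the posed (but not offset) tail position by the
    dominant-axis sign test; for the canonically aligned spiral this is a
    deterministic function of (reflect, rotation): the unreflected,
    unrotated tail is "right", reflection maps it to "left", and each
    90 deg step permutes right -> up -> left -> down.
    """
    xy = np.array([[chain.tail.x, chain.tail.y]])
    ori = np.zeros(1)
    posed, _ = _apply_pose_arrays(xy, ori, replace(pose, offset_x=0.0, offset_y=0.0))
    x, y = posed[0]
    if abs(x) >= abs(y):
        return "right" if x >= 0 else "left"
    return "up" if y >= 0 else "down"
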