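"""Helical thread morphometrics from paired 3D landmarks.

An epidermal thread cell (ETC) stores a single protein thread coiled into a
regular helix.  In confocal image stacks the thread is digitized as paired
landmarks placed on the two bilateral sides of the thread at the peaks and
valleys of its projection (the helix extrema).  From these pairs this module
recovers:

* thread diameter ``phi`` — per-pair landmark distance ``|p_i - p_j|``;
* pitch angle ``theta`` — per half loop, the angle between the half-loop
  centerline displacement and the plane normal to the mean direction of
  increase;
* helical diameter ``D`` — per half loop, ``axial / tan(theta)``;
* extension ratio ``R_ext = 1 - sin(theta)`` — fractional length gain if the
  helix is pulled taut;
* handedness — chirality, recoverable only from a centerline sampled finer
  than the half-loop spacing.

All coordinates are micrometres; angles are degrees at the public surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LandmarkSeries",
    "HalfLoopGeometry",
    "ThreadGeometry",
    "DegenerateGeometryError",
    "pair_midpoints",
    "direction_of_increase",
    "thread_diameter",
    "analyze_half_loops",
    "extension_ratio",
    "centerline_length",
    "detect_handedness",
    "ols_trend",
    "analyze_thread",
]


class DegenerateGeometryError(ValueError):
    """Raised when the landmark geometry admits no well-defined answer."""


@dataclass(frozen=True)
class LandmarkSeries:
    """Ordered paired landmarks along one thread, coordinates in um.

    ``pairs`` has shape (n_pairs, 2, 3): pair index, side (i, j), xyz.
    ``dense_centerline`` optionally holds midpoint-only centerline samples at
    sub-half-loop spacing, required for handedness detection.
    """

    thread_id: str
    pairs: np.ndarray
    dense_centerline: np.ndarray | None = None

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=float)
        if pairs.ndim != 3 or pairs.shape[1:] != (2, 3):
            raise ValueError(f"pairs must have shape (n, 2, 3), got {pairs.shape}")
        if pairs.shape[0] < 1:
            raise ValueError("a LandmarkSeries needs at least one landmark pair")
        if not np.all(np.isfinite(pairs)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "pairs", pairs)
        if self.dense_centerline is not None:
            dense = np.asarray(self.dense_centerline, dtype=float)
            if dense.ndim != 2 or dense.shape[1] != 3:
                raise ValueError("dense_centerline must have shape (m, 3)")
            object.__setattr__(self, "dense_centerline", dense)

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


@dataclass(frozen=True)
class HalfLoopGeometry:
    """Geometry of one extremum-to-extremum half loop."""

    index: int
    axial_length: float  # um, |projection of displacement on v_inc|
    lateral_length: float  # um, |component normal to v_inc|
    theta: float  # degrees, in [0, 90]
    D: float  # um, helical diameter = axial / tan(theta)
    chord_length: float  # um, |displacement| (diagnostic)
    degenerate: bool = False


@dataclass(frozen=True)
class ThreadGeometry:
    """Per-thread summary of helix geometry."""

    thread_id: str
    phi_per_pair: np.ndarray
    phi_mean: float
    v_inc: np.ndarray
    half_loops: list[HalfLoopGeometry]
    theta_mean: float
    D_mean: float
    R_ext_mean: float
    handedness: str = "undetermined"

    @property
    def n_half_loops(self) -> int:
        return len(self.half_loops)


def pair_midpoints(series: LandmarkSeries) -> np.ndarray:
    """Centerline points p_c = (p_i + p_j) / 2, one per pair, in input order."""
    if series.n_pairs < 1:
        raise ValueError("empty landmark series")
    return series.pairs.mean(axis=1)


def direction_of_increase(centerline: np.ndarray) -> np.ndarray:
    """Unit vector from the first to the last centerline point."""
    centerline = np.asarray(centerline, dtype=float)
    if centerline.ndim != 2 or centerline.shape[0] < 2:
        raise ValueError("need at least two centerline points")
    d = centerline[-1] - centerline[0]
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise DegenerateGeometryError("first and last centerline points coincide")
    return d / norm


def thread_diameter(series: LandmarkSeries) -> tuple[np.ndarray, float]:
    """Per-pair thread diameters ``phi = |p_i - p_j|`` and their mean."""
    diffs = series.pairs[:, 0, :] - series.pairs[:, 1, :]
    phi = np.linalg.norm(diffs, axis=1)
    return phi, float(phi.mean())


def analyze_half_loops(
    centerline: np.ndarray, v_inc: np.ndarray
) -> list[HalfLoopGeometry]:
    """Decompose each consecutive centerline segment into helix parameters.

    For each half loop the displacement ``d`` is split into an axial part
    ``a = (d . v_inc) v_inc`` and a lateral part ``l = d - a``.  The pitch
    angle is ``theta = atan2(|a|, |l|)`` and the helical diameter is
    ``D = |a| / tan(theta)``, which on ideal data equals ``|l|``.  Half loops
    with zero axial component (theta == 0, D undefined) or zero length are
    flagged degenerate; callers exclude them from summaries.
    """
    centerline = np.asarray(centerline, dtype=float)
    if centerline.shape[0] < 3:
        raise ValueError("need at least three centerline points (two half loops)")
    v = np.asarray(v_inc, dtype=float)
    v = v / np.linalg.norm(v)

    out: list[HalfLoopGeometry] = []
    for k in range(centerline.shape[0] - 1):
        d = centerline[k + 1] - centerline[k]
        chord = float(np.linalg.norm(d))
        axial = float(abs(d @ v))
        lateral = float(np.linalg.norm(d - (d @ v) * v))
        theta = float(np.arctan2(axial, lateral))
        degenerate = chord == 0.0 or axial == 0.0
        if degenerate:
            warnings.warn(
                f"half loop {k}: degenerate geometry (chord={chord:g} um, "
                f"axial={axial:g} um); excluded from summaries",
                stacklevel=2,
            )
            D = np.nan
        elif lateral == 0.0:
            # straight segment along the axis: theta = 90 deg, D -> 0
            D = 0.0
        else:
            D = axial / np.tan(theta)
        out.append(
            HalfLoopGeometry(
                index=k,
                axial_length=axial,
                lateral_length=lateral,
                theta=float(np.degrees(theta)),
                D=D,
                chord_length=chord,
                degenerate=degenerate,
            )
        )
    return out


def extension_ratio(theta: float) -> float:
    """Fractional length gain ``1 - sin(theta)`` when pulled taut, theta in degrees."""
    if not 0.0 <= theta <= 90.0:
        raise ValueError(f"pitch angle must be in [0, 90] degrees, got {theta}")
    return 1.0 - float(np.sin(np.radians(theta)))


def centerline_length(L_T: float, theta: float) -> float:
    """Helical centerline length ``L_T' = L_T sin(theta)`` (mm), theta in degrees.

    ``L_T`` is the straightened (contour) length of a released thread; the
    helical centerline it occupied in the cell is shorter by sin(theta).
    """
    if L_T <= 0:
        raise ValueError(f"thread length must be positive, got {L_T}")
    return L_T * float(np.sin(np.radians(theta)))


def detect_handedness(
    dense_centerline: np.ndarray, v_inc: np.ndarray, rel_tol: float = 0.1
) -> str:
    """Chirality from a densely sampled centerline: 'right', 'left' or 'undetermined'.

    Projects each point onto the plane normal to ``v_inc`` (after removing the
    mean lateral offset) and takes the mean triple product
    ``(l_k x l_{k+1}) . v_inc`` over consecutive lateral components.  A
    positive mean rotation is a right-handed helix.  Extremum-only input has
    antiparallel consecutive laterals (zero cross products) and returns
    'undetermined' — chirality is never guessed.
    """
    pts = np.asarray(dense_centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        return "undetermined"
    v = np.asarray(v_inc, dtype=float)
    v = v / np.linalg.norm(v)

    lateral = pts - np.outer(pts @ v, v)
    lateral = lateral - lateral.mean(axis=0)
    norms = np.linalg.norm(lateral, axis=1)
    scale = float(np.mean(norms) ** 2)
    if scale == 0.0:
        return "undetermined"

    crosses = np.cross(lateral[:-1], lateral[1:])
    signed = crosses @ v
    mean_signed = float(np.mean(signed))
    if abs(mean_signed) < rel_tol * scale:
        return "undetermined"
    return "right" if mean_signed > 0 else "left"


def ols_trend(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and two-sided p-value of the slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def analyze_thread(series: LandmarkSeries) -> ThreadGeometry:
    """Full per-thread analysis: phi, per-half-loop theta and D, R_ext, handedness.

    Summaries are unweighted means over landmark pairs / non-degenerate half
    loops.  Requires at least three pairs (two half loops).
    """
    if series.n_pairs < 3:
        raise ValueError("half-loop analysis needs at least three landmark pairs")
    midpoints = pair_midpoints(series)
    v_inc = direction_of_increase(midpoints)
    phi_per_pair, phi_mean = thread_diameter(series)
    half_loops = analyze_half_loops(midpoints, v_inc)

    good = [h for h in half_loops if not h.degenerate]
    if good:
        theta_mean = float(np.mean([h.theta for h in good]))
        D_mean = float(np.mean([h.D for h in good]))
        R_ext_mean = float(np.mean([extension_ratio(h.theta) for h in good]))
    else:
        theta_mean = D_mean = R_ext_mean = float("nan")

    if series.dense_centerline is not None:
        handedness = detect_handedness(series.dense_centerline, v_inc)
    else:
        handedness = "undetermined"

    return ThreadGeometry(
        thread_id=series.thread_id,
        phi_per_pair=phi_per_pair,
        phi_mean=phi_mean,
        v_inc=v_inc,
        half_loops=half_loops,
        theta_mean=theta_mean,
        D_mean=D_mean,
        R_ext_mean=R_ext_mean,
        handedness=handedness,
    )
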