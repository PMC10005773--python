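"""Synthetic data with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here: ideal helical
threads digitized as extremum landmark pairs with Gaussian digitization
noise, Poisson transect counts at known true cell densities, truncated-normal
gland axis populations, and wet/dry slime-sample masses at known water
contents.  Defaults reproduce the measured study conditions (thread diameter
~0.5 um, helical diameter ~0.35 um, pitch angle ~63.5 deg, ETC density
~434 mm^-2, full gland axes 3.51/2.45 mm, ...), so parameter-recovery tests
run against known ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .helix import LandmarkSeries
from .slime import GlandGeometry, SlimeSample

__all__ = [
    "RigidMotion",
    "HelixSpec",
    "CensusSpec",
    "GlandPopulationSpec",
    "make_helix_landmarks",
    "make_cell_transects",
    "make_gland_population",
    "make_slime_samples",
    "truncated_normal",
]

#: pitch implied by the mean measured pitch angle 63.5 deg at D = 0.35 um
#: (theta = atan(P / (2 D))  =>  P = 2 D tan theta)
DEFAULT_PITCH_UM = 2 * 0.35 * float(np.tan(np.radians(63.5)))


@dataclass(frozen=True)
class RigidMotion:
    """A proper rotation followed by a translation."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be (3, 3) and translation (3,)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be a proper orthogonal matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, translation_scale: float = 10.0) -> "RigidMotion":
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=translation_scale, size=3)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HelixSpec:
    """Ground-truth helix parameters for one synthetic thread (um).

    ``pitch_P`` is the axial advance per full turn; the implied pitch angle
    of the extremum-to-extremum half-loop displacement is
    atan(P / (2 D)).
    """

    thread_diameter_phi: float = 0.5
    helical_diameter_D: float = 0.35
    pitch_P: float = DEFAULT_PITCH_UM
    n_half_loops: int = 10
    handedness: str = "right"
    noise_sd: float = 0.0
    rigid_motion: RigidMotion = field(default_factory=RigidMotion.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.thread_diameter_phi, self.helical_diameter_D, self.pitch_P) <= 0:
            raise ValueError("phi, D and P must be positive")
        if self.n_half_loops < 2:
            raise ValueError("need at least two half loops")
        if self.handedness not in ("right", "left"):
            raise ValueError(f"handedness must be 'right' or 'left', got {self.handedness!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def theta_true(self) -> float:
        """Half-loop pitch angle implied by (P, D), degrees."""
        return float(np.degrees(np.arctan2(self.pitch_P / 2.0, self.helical_diameter_D)))


def make_helix_landmarks(
    spec: HelixSpec, thread_id: str = "sim", dense: bool = False
) -> LandmarkSeries:
    """Digitized landmark pairs of an ideal helix.

    The centerline is c(t) = (P t / 2 pi) u + (D/2)(cos t v + sin t w) in an
    orthonormal frame with u the helix axis and w the optical axis; a
    left-handed spec mirrors the w component.  One landmark pair is emitted
    per projection extremum t_k = k pi (k = 0..n_half_loops), offset
    +/- phi/2 along v, i.e. within the image plane and perpendicular to the
    projected tangent.  The rigid motion is applied, then i.i.d. Gaussian
    noise of sd ``noise_sd`` is added to every coordinate.

    With ``dense=True`` the series also carries midpoint-only centerline
    samples at quarter-loop spacing, which is fine enough to recover
    chirality (extremum-only landmarks cannot).
    """
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    w = np.array([0.0, 0.0, 1.0])
    chir = 1.0 if spec.handedness == "right" else -1.0

    def centerline(t: np.ndarray) -> np.ndarray:
        return (
            np.outer(spec.pitch_P * t / (2 * np.pi), u)
            + (spec.helical_diameter_D / 2.0)
            * (np.outer(np.cos(t), v) + chir * np.outer(np.sin(t), w))
        )

    t_ext = np.arange(spec.n_half_loops + 1) * np.pi
    mids = centerline(t_ext)
    offset = (spec.thread_diameter_phi / 2.0) * v
    pairs = np.stack([mids + offset, mids - offset], axis=1)

    rng = np.random.default_rng(spec.seed)
    pairs = spec.rigid_motion.apply(pairs)
    pairs = pairs + rng.normal(scale=spec.noise_sd, size=pairs.shape) if spec.noise_sd else pairs

    dense_pts = None
    if dense:
        t_dense = np.arange(2 * spec.n_half_loops + 1) * (np.pi / 2.0)
        dense_pts = spec.rigid_motion.apply(centerline(t_dense))
        if spec.noise_sd:
            dense_pts = dense_pts + rng.normal(scale=spec.noise_sd, size=dense_pts.shape)

    return LandmarkSeries(thread_id=thread_id, pairs=pairs, dense_centerline=dense_pts)


@dataclass(frozen=True)
class CensusSpec:
    """Transect-count generator settings.

    ``true_densities`` maps cell type to true area density sigma (mm^-2);
    counts are drawn per section with linear density lambda = sqrt(sigma),
    so the pipeline's sigma = lambda^2 recovers sigma in expectation.
    ``overdispersion`` switches the count law from Poisson to negative
    binomial with that dispersion (variance = mu + mu^2 / k).
    """

    true_densities: dict[str, float]
    section_lengths: tuple[float, ...]  # mm
    body_positions: tuple[tuple[float, float], ...]  # (P_AP, P_DV) fractions
    seed: int = 0
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.true_densities.values()):
            raise ValueError("densities must be non-negative")
        if any(L <= 0 for L in self.section_lengths):
            raise ValueError("section lengths must be positive")
        if len(self.body_positions) != len(self.section_lengths):
            raise ValueError("need one (P_AP, P_DV) position per section")
        for p_ap, p_dv in self.body_positions:
            if not (0 <= p_ap <= 1 and 0 <= p_dv <= 1):
                raise ValueError("body positions must be fractions in [0, 1]")
        object.__setattr__(self, "section_lengths", tuple(self.section_lengths))
        object.__setattr__(
            self, "body_positions", tuple(tuple(p) for p in self.body_positions)
        )


def make_cell_transects(spec: CensusSpec, animal_id: str = "sim") -> pd.DataFrame:
    """Poisson (or negative-binomial) transect counts at known true densities.

    Returns a tidy frame with columns ``animal_id, cell_type, N_cell,
    L_section_mm, P_AP, P_DV`` — the transect-count table the census module
    reads.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (L, (p_ap, p_dv)) in zip(spec.section_lengths, spec.body_positions):
        for cell_type, sigma in sorted(spec.true_densities.items()):
            mu = np.sqrt(sigma) * L
            if spec.overdispersion is not None and mu > 0:
                k = spec.overdispersion
                n = rng.negative_binomial(k, k / (k + mu))
            else:
                n = rng.poisson(mu)
            rows.append(
                {
                    "animal_id": animal_id,
                    "cell_type": cell_type,
                    "N_cell": int(n),
                    "L_section_mm": L,
                    "P_AP": p_ap,
                    "P_DV": p_dv,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlandPopulationSpec:
    """Normal gland-axis population, truncated at zero (mm)."""

    mean_major: float = 3.51
    sd_major: float = 0.25
    mean_minor: float = 2.45
    sd_minor: float = 0.15
    n: int = 11
    state: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_major <= 0 or self.mean_minor <= 0:
            raise ValueError("axis means must be positive")
        if self.sd_major < 0 or self.sd_minor < 0:
            raise ValueError("axis sds must be non-negative")
        if self.n < 1:
            raise ValueError("population size must be >= 1")


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = 0.0,
    high: float = np.inf,
    max_attempts: int = 1000,
) -> float:
    """One truncated-normal draw by resampling; errors after max_attempts."""
    if sd == 0.0:
        if not low < mean < high:
            raise ValueError(f"degenerate mean {mean} outside ({low}, {high})")
        return mean
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError(
        f"truncated normal ({mean}, {sd}) on ({low}, {high}): "
        f"no draw accepted in {max_attempts} attempts"
    )


def make_gland_population(spec: GlandPopulationSpec) -> list[GlandGeometry]:
    """Glands with independent truncated-normal axes, swapped so major >= minor."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        a = truncated_normal(rng, spec.mean_major, spec.sd_major)
        b = truncated_normal(rng, spec.mean_minor, spec.sd_minor)
        if a < b:
            a, b = b, a
        out.append(GlandGeometry(Phi_a=a, Phi_b=b, state=spec.state))
    return out


def make_slime_samples(
    mean_wc: float,
    sd_wc: float,
    n: int,
    seed: int = 0,
    mean_wet_mg: float = 5.2,
    sd_wet_mg: float = 2.4,
    scraped_area_cm2: float = 18.0,
) -> list[SlimeSample]:
    """Slime samples at a known water content, as consistent wet/dry masses.

    Water contents are normal truncated to (0, 1); wet masses are normal
    truncated to the observed 2-10 mg scraping range; dry mass follows as
    wet * (1 - water content).
    """
    if not 0.0 < mean_wc < 1.0:
        raise ValueError("mean water content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        wc = truncated_normal(rng, mean_wc, sd_wc, low=0.0, high=1.0)
        wet = truncated_normal(rng, mean_wet_mg, sd_wet_mg, low=2.0, high=10.0)
        out.append(
            SlimeSample(
                wet_mass=wet, dry_mass=wet * (1.0 - wc), scraped_area=scraped_area_cm2
            )
        )
    return out
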