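"""Slime composition and fibrosity-index models.

Hagfish make two fibrous hydrogels: a thick *epidermal slime* released by
rupture of epidermal thread cells (ETCs) when the skin is damaged, and the
famous dilute *defensive slime* ejected by slime glands.  Both are mixtures
of protein threads and mucus; they differ enormously in how much water they
hold per unit thread.  The *fibrosity index* r_F quantifies this as total
thread length per unit slime volume (mm of thread per mm^3 of slime).

Epidermal slime (per unit skin area A, epidermis thickness D_epi):

    r_F(unswollen) = L_T * sigma_ETC / D_epi
    r_F(swollen)   = r_F(unswollen) / swelling_factor

Defensive slime (per gland): the ejected exudate volume is the difference
between full and newly-emptied gland volumes (glands modelled as prolate
ellipsoids), the seawater volume follows from the whole-slime w/v thread +
mucin concentration, and

    r_F = L_T,slime * N_GTC,ejected / V_S

where GTC = gland thread cell and V_S = V_seawater + V_ejected.

Units: gland axes and volumes mm / mm^3, fluid volumes tracked in ml where
stated (1 ml = 1000 mm^3), cell-scale lengths um, masses g or mg as noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .units import UM_PER_MM, ml_to_mm3, mm3_to_ml

__all__ = [
    "GlandGeometry",
    "GlandCellModel",
    "CellShape",
    "SlimeComposition",
    "SlimeSample",
    "ellipsoid_volume",
    "thread_volume_fraction",
    "gtc_counts",
    "exudate_and_dilution",
    "gmc_volumes",
    "epidermal_fibrosity",
    "defensive_fibrosity",
    "water_content_and_swelling",
    "productivity",
    "compare_slimes",
]


@dataclass(frozen=True)
class GlandGeometry:
    """One slime gland as an ellipsoid: major axis Phi_a, minor axis Phi_b (mm)."""

    Phi_a: float
    Phi_b: float
    state: str = "full"  # {'full', 'emptied'}

    def __post_init__(self) -> None:
        if self.Phi_b <= 0 or self.Phi_a <= 0:
            raise ValueError("gland axes must be positive")
        if self.Phi_a < self.Phi_b:
            raise ValueError("major axis must be >= minor axis")
        if self.state not in ("full", "emptied"):
            raise ValueError(f"unknown gland state {self.state!r}")

    @property
    def AR(self) -> float:
        return self.Phi_a / self.Phi_b

    @property
    def V_G(self) -> float:
        """Ellipsoid volume (4/3) pi r_a r_b^2 with r = Phi/2, in mm^3."""
        return ellipsoid_volume(self.Phi_a, self.Phi_b)[0]


@dataclass(frozen=True)
class GlandCellModel:
    """GTC counts and mucous-cell volumes for the full/emptied gland pair."""

    N_GTC_full: float
    N_GTC_remaining: float
    sigma_GTC: float | None = None
    V_GMC_ejected: float | None = None

    def __post_init__(self) -> None:
        if self.N_GTC_remaining > self.N_GTC_full:
            raise ValueError("more GTCs remaining than the full gland held")
        if min(self.N_GTC_full, self.N_GTC_remaining) < 0:
            raise ValueError("GTC counts must be non-negative")

    @property
    def N_GTC_ejected(self) -> float:
        return self.N_GTC_full - self.N_GTC_remaining


@dataclass(frozen=True)
class CellShape:
    """ETC modelled as an ellipsoid holding a cylindrical thread (um)."""

    r_a: float  # cell major semi-axis
    r_b: float  # cell minor semi-axis
    r_T: float  # thread radius
    L_T: float  # thread length

    def __post_init__(self) -> None:
        if min(self.r_a, self.r_b, self.r_T, self.L_T) <= 0:
            raise ValueError("all cell/thread dimensions must be positive")
        if self.r_T >= self.r_b:
            raise ValueError("thread radius must be smaller than the cell minor axis")


@dataclass(frozen=True)
class SlimeComposition:
    """Volume/mass bookkeeping of one slime, with its fibrosity index.

    ``V_ejected`` and ``V_S`` in mm^3, ``V_SW_ml`` in ml, ``W`` in g,
    ``total_thread_length`` in mm, ``r_F`` in mm/mm^3.
    """

    label: str
    r_F: float
    V_ejected: float | None = None
    rho: float | None = None  # g/ml
    W: float | None = None
    c_wv: float | None = None  # g/ml (w/v fraction: 0.004% = 4e-5 g/ml)
    V_SW_ml: float | None = None
    V_S: float | None = None
    total_thread_length: float | None = None
    swelling_factor: float | None = None


@dataclass(frozen=True)
class SlimeSample:
    """One scraped slime sample: wet and dry mass in mg."""

    wet_mass: float
    dry_mass: float
    scraped_area: float | None = None  # cm^2

    def __post_init__(self) -> None:
        if not 0 <= self.dry_mass <= self.wet_mass:
            raise ValueError("need 0 <= dry mass <= wet mass")

    @property
    def water_content(self) -> float:
        return (self.wet_mass - self.dry_mass) / self.wet_mass


def ellipsoid_volume(Phi_a: float, Phi_b: float) -> tuple[float, float]:
    """Gland volume and aspect ratio from major/minor axes (mm).

    V = (4/3) pi (Phi_a/2) (Phi_b/2)^2; axes are swapped with a warning if
    given in the wrong order.
    """
    if Phi_a <= 0 or Phi_b <= 0:
        raise ValueError("axes must be positive")
    if Phi_a < Phi_b:
        warnings.warn(
            f"major axis {Phi_a} < minor axis {Phi_b}; swapping", stacklevel=2
        )
        Phi_a, Phi_b = Phi_b, Phi_a
    V = (4.0 / 3.0) * np.pi * (Phi_a / 2.0) * (Phi_b / 2.0) ** 2
    return float(V), Phi_a / Phi_b


def thread_volume_fraction(shape: CellShape) -> float:
    """Fraction of ETC cytoplasm occupied by the thread.

    Cylindrical thread in an ellipsoidal cell:
    V_T / V_ETC = pi r_T^2 L_T / ((4/3) pi r_a r_b^2).
    Warns if the nominal thread volume exceeds the cell volume.
    """
    v_thread = np.pi * shape.r_T**2 * shape.L_T
    v_cell = (4.0 / 3.0) * np.pi * shape.r_a * shape.r_b**2
    frac = float(v_thread / v_cell)
    if frac >= 1.0:
        warnings.warn(
            f"thread volume fraction {frac:.2f} >= 1: thread does not fit the cell",
            stacklevel=2,
        )
    return frac


def gtc_counts(
    sigma_GTC: float | None = None,
    V_full: float | None = None,
    V_emptied: float | None = None,
    N_full: float | None = None,
    N_remaining: float | None = None,
) -> GlandCellModel:
    """GTC counts in full and emptied glands.

    With GTCs distributed evenly through the gland, a cross-sectional area
    density sigma_GTC (mm^-2) implies a number density sigma_GTC^1.5 (mm^-3),
    so N = sigma_GTC^1.5 * V_G.  Direct count overrides take precedence when
    given (the cross-sectional density is a supplementary measurement that is
    often reported only as the resulting counts).
    """
    if N_full is None:
        if sigma_GTC is None or V_full is None:
            raise ValueError("need either N_full or (sigma_GTC, V_full)")
        if sigma_GTC < 0 or V_full < 0:
            raise ValueError("density and volume must be non-negative")
        N_full = sigma_GTC**1.5 * V_full
    if N_remaining is None:
        if sigma_GTC is None or V_emptied is None:
            raise ValueError("need either N_remaining or (sigma_GTC, V_emptied)")
        N_remaining = sigma_GTC**1.5 * V_emptied
    return GlandCellModel(
        N_GTC_full=N_full, N_GTC_remaining=N_remaining, sigma_GTC=sigma_GTC
    )


def exudate_and_dilution(
    V_full: float,
    V_emptied: float,
    rho: float = 1.0,
    c_wv: float = 4e-5,
) -> SlimeComposition:
    """Exudate ejection and seawater dilution bookkeeping for one gland.

    Parameters
    ----------
    V_full, V_emptied : gland volumes in mm^3 (full >= emptied).
    rho : exudate density in g/ml (default 1, a conservative estimate).
    c_wv : combined thread + mucin w/v concentration of fully deployed slime
        in g/ml (default 4e-5, i.e. 0.004 %).

    Returns a :class:`SlimeComposition` with V_ejected = V_full - V_emptied
    (mm^3), exudate weight W = rho * V_ejected (g), seawater volume
    V_SW = W / c_wv (ml) and total slime volume V_S = V_SW + V_ejected (mm^3).
    The fibrosity field is NaN until thread length is attached (see
    :func:`defensive_fibrosity`).
    """
    if V_full < V_emptied:
        raise ValueError("full gland volume must be >= emptied gland volume")
    if c_wv <= 0:
        raise ValueError("w/v concentration must be positive")
    V_ejected = V_full - V_emptied
    W = rho * mm3_to_ml(V_ejected)
    V_SW_ml = W / c_wv
    V_S = ml_to_mm3(V_SW_ml) + V_ejected
    return SlimeComposition(
        label="defensive",
        r_F=float("nan"),
        V_ejected=V_ejected,
        rho=rho,
        W=W,
        c_wv=c_wv,
        V_SW_ml=V_SW_ml,
        V_S=V_S,
    )


def gmc_volumes(
    delta_full: float, delta_emptied: float, V_full: float, V_emptied: float
) -> float:
    """Ejected gland-mucous-cell volume (mm^3) from area fractions delta.

    With mucous cells evenly distributed, their volume in a gland is
    V_GMC = delta * V_G; the ejected volume is the full/emptied difference.
    """
    for name, d in (("delta_full", delta_full), ("delta_emptied", delta_emptied)):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{name} must be an area fraction in [0, 1], got {d}")
    out = delta_full * V_full - delta_emptied * V_emptied
    if out < 0:
        raise ValueError(
            "negative ejected mucous volume: inconsistent fractions/volumes"
        )
    return out


def epidermal_fibrosity(
    L_T: float,
    sigma_ETC: float,
    D_epi: float,
    swelling_factor: float = 1.19,
) -> tuple[float, float]:
    """Fibrosity index of epidermal slime, unswollen and seawater-swollen.

    Parameters
    ----------
    L_T : single-thread length in mm.
    sigma_ETC : ETC area density in mm^-2.
    D_epi : epidermis thickness in um.
    swelling_factor : volume ratio swollen/unswollen (>= 1).

    r_F(unswollen) = L_T * sigma_ETC / D_epi (thread length per volume of
    ruptured epidermis); swelling dilutes it by the swelling factor.
    """
    if min(L_T, sigma_ETC, D_epi) <= 0:
        raise ValueError("all inputs must be positive")
    if swelling_factor < 1.0:
        raise ValueError("swelling factor must be >= 1")
    r_unswollen = L_T * sigma_ETC / (D_epi / UM_PER_MM)
    return r_unswollen, r_unswollen / swelling_factor


def defensive_fibrosity(total_thread_length: float, V_S: float) -> float:
    """Fibrosity r_F = total thread length (mm) / slime volume V_S (mm^3)."""
    if V_S <= 0:
        raise ValueError("slime volume must be positive")
    if total_thread_length < 0:
        raise ValueError("thread length must be non-negative")
    return total_thread_length / V_S


def water_content_and_swelling(
    swollen: list[SlimeSample], unswollen: list[SlimeSample]
) -> tuple[float, float, float]:
    """Group-mean water contents and the implied volumetric swelling factor.

    Water content per sample is (wet - dry) / wet.  The swelling factor is
    1 plus the difference of group means in percentage points / 100 (e.g.
    93.9 % vs 74.7 % gives ~1.19): a fractional volume gain matching the
    extra water the swollen slime holds, assuming near-seawater density.
    """
    if not swollen or not unswollen:
        raise ValueError("need at least one sample in each group")
    w_sw = float(np.mean([s.water_content for s in swollen]))
    w_un = float(np.mean([s.water_content for s in unswollen]))
    return w_sw, w_un, 1.0 + (w_sw - w_un)


def productivity(mass: float, area: float) -> float:
    """Slime yield per scraped skin area, mg/cm^2."""
    if area <= 0:
        raise ValueError("scraped area must be positive")
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass / area


def compare_slimes(
    epidermal: SlimeComposition,
    defensive: SlimeComposition,
    exudate_fibrosity: float | None = None,
) -> dict[str, float]:
    """Headline comparison of the two slimes.

    Returns the epidermal/defensive fibrosity ratio and, when the fibrosity
    of the raw (undiluted) exudate is supplied, the dilution factor of the
    exudate in fully deployed defensive slime.
    """
    if defensive.r_F <= 0 or not np.isfinite(defensive.r_F):
        raise ValueError("defensive fibrosity must be positive and finite")
    out = {"fibrosity_ratio": epidermal.r_F / defensive.r_F}
    if exudate_fibrosity is not None:
        out["dilution_factor"] = exudate_fibrosity / defensive.r_F
    return out
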