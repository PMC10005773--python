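"""End-to-end analysis report: census -> morphometrics -> fibrosity.

``run_report`` runs every stage of the pipeline from one configuration dict
(see :mod:`slimemetrics.config`) and tabulates the headline quantities.
Inputs can come from measured data files named in the config or, where no
file is given, from the default parameter profile; every output row is
tagged with the provenance of its inputs (``measured``, ``paper_default``,
or ``computed`` for quantities derived inside the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import census as census_mod
from . import helix as helix_mod
from . import io as io_mod
from . import slime as slime_mod
from .units import CM_PER_MM

__all__ = ["ResultsTable", "PipelineError", "run_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ResultsTable:
    """Named quantities with value, units and input provenance."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, value: float, units: str, provenance: str) -> None:
        self.rows.append(
            {"quantity": name, "value": value, "units": units, "provenance": provenance}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["quantity", "value", "units", "provenance"])

    def value(self, name: str) -> float:
        for row in self.rows:
            if row["quantity"] == name:
                return row["value"]
        raise KeyError(name)


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


@_stage("census")
def _census_stage(cfg: dict, table: ResultsTable) -> dict:
    c = cfg["census"]
    data_path = cfg["data"].get("transects")
    if data_path:
        summary = census_mod.transect_to_area_density(io_mod.read_transects(data_path))
        provenance = "measured"
        sigma = {t: summary.sigma(t) for t in summary.per_type.index}
    else:
        provenance = "paper_default"
        sigma = {
            "ETC": c["sigma_ETC_per_mm2"],
            "LMC": c["sigma_LMC_per_mm2"],
            "SMC": c["sigma_SMC_per_mm2"],
        }
    for cell_type, s in sigma.items():
        table.add(f"sigma_{cell_type}", s, "mm^-2", provenance)
    if {"ETC", "LMC"} <= sigma.keys():
        table.add("sigma_ETC_over_LMC", sigma["ETC"] / sigma["LMC"], "-", "computed")
    if {"SMC", "ETC"} <= sigma.keys():
        table.add("sigma_SMC_over_ETC", sigma["SMC"] / sigma["ETC"], "-", "computed")

    body = census_mod.BodyModel(
        body_length=c["body_length_mm"],
        body_diameter=c["body_diameter_mm"],
        epidermis_thickness=c["epidermis_thickness_um"],
        n_glands=c["n_glands"],
    )
    area, n_etc = census_mod.body_totals(body, sigma["ETC"])
    table.add("skin_area", area, "mm^2", "computed")
    table.add("N_ETC_total", n_etc, "cells", "computed")
    return {"sigma": sigma, "body": body, "N_ETC_total": n_etc}


@_stage("morphometrics")
def _morphometrics_stage(cfg: dict, table: ResultsTable) -> dict:
    t = cfg["thread"]
    data_path = cfg["data"].get("landmarks")
    if data_path:
        series_list = io_mod.read_landmarks(
            data_path, dense_path=cfg["data"].get("dense_centerlines")
        )
        geoms = [helix_mod.analyze_thread(s) for s in series_list]
        phi = float(np.mean([g.phi_mean for g in geoms]))
        theta = float(np.mean([g.theta_mean for g in geoms]))
        D = float(np.mean([g.D_mean for g in geoms]))
        provenance = "measured"
    else:
        phi, theta, D = t["phi_um"], t["theta_deg"], t["D_um"]
        provenance = "paper_default"
    table.add("phi_mean", phi, "um", provenance)
    table.add("theta_mean", theta, "deg", provenance)
    table.add("D_mean", D, "um", provenance)

    L_T = t["L_T_mm"]
    table.add("L_T", L_T, "mm", "paper_default")
    L_T_prime = helix_mod.centerline_length(L_T, theta)
    table.add("L_T_prime", L_T_prime, "mm", "computed")
    table.add("R_ext", helix_mod.extension_ratio(theta), "-", "computed")

    shape = slime_mod.CellShape(
        r_a=t["cell_major_semiaxis_um"],
        r_b=t["cell_minor_semiaxis_um"],
        r_T=phi / 2.0,
        L_T=L_T * 1000.0,
    )
    table.add(
        "thread_volume_fraction", slime_mod.thread_volume_fraction(shape), "-", "computed"
    )
    return {"phi": phi, "theta": theta, "D": D, "L_T": L_T, "L_T_prime": L_T_prime}


@_stage("fibrosity")
def _fibrosity_stage(cfg: dict, table: ResultsTable, ctx: dict) -> None:
    g, s = cfg["gland"], cfg["slime"]
    sigma_etc = ctx["sigma"]["ETC"]
    body = ctx["body"]

    # gland geometry: measured populations if given, otherwise the mean axes
    def gland_volume(state_key: str, defaults: tuple[float, float]) -> tuple[float, float]:
        path = cfg["data"].get(f"glands_{state_key}")
        if path:
            glands = io_mod.read_glands(path)
            return (
                float(np.mean([gl.V_G for gl in glands])),
                float(np.mean([gl.AR for gl in glands])),
            )
        V, ar = slime_mod.ellipsoid_volume(*defaults)
        return V, ar

    V_full, AR_full = gland_volume("full", (g["full_major_mm"], g["full_minor_mm"]))
    V_emptied, AR_emptied = gland_volume(
        "emptied", (g["emptied_major_mm"], g["emptied_minor_mm"])
    )
    table.add("V_G_full", V_full, "mm^3", "computed")
    table.add("AR_full", AR_full, "-", "computed")
    table.add("V_G_emptied", V_emptied, "mm^3", "computed")
    table.add("AR_emptied", AR_emptied, "-", "computed")
    table.add("V_ejected_from_axes", V_full - V_emptied, "mm^3", "computed")
    table.add("V_ejected", g["V_ejected_mm3"], "mm^3", "paper_default")

    counts = slime_mod.gtc_counts(
        N_full=g["N_GTC_full"], N_remaining=g["N_GTC_remaining"]
    )
    table.add("N_GTC_full", counts.N_GTC_full, "cells", "paper_default")
    table.add("N_GTC_ejected", counts.N_GTC_ejected, "cells", "computed")
    n_gtc_total = counts.N_GTC_full * body.n_glands
    table.add("N_GTC_total", n_gtc_total, "cells", "computed")
    table.add("N_ETC_over_N_GTC", ctx["N_ETC_total"] / n_gtc_total, "-", "computed")

    # defensive slime: dilute the reported ejected volume in seawater
    comp = slime_mod.exudate_and_dilution(
        V_full=V_emptied + g["V_ejected_mm3"],
        V_emptied=V_emptied,
        rho=s["rho_g_per_ml"],
        c_wv=s["c_wv_g_per_ml"],
    )
    table.add("W_exudate", comp.W, "g", "computed")
    table.add("V_SW", comp.V_SW_ml, "ml", "computed")
    table.add("V_S_defensive", comp.V_S, "mm^3", "computed")
    total_thread = g["slime_thread_length_mm"] * counts.N_GTC_ejected
    table.add("defensive_thread_length_per_gland", total_thread, "mm", "computed")
    r_def = slime_mod.defensive_fibrosity(total_thread, comp.V_S)
    table.add("r_F_defensive", r_def, "mm/mm^3", "computed")

    # epidermal slime: water content and swelling, then the fibrosity index
    samples_path = cfg["data"].get("slime_samples")
    if samples_path:
        groups = io_mod.read_slime_samples(samples_path)
        w_sw, w_un, factor = slime_mod.water_content_and_swelling(
            groups.get("swollen", []), groups.get("unswollen", [])
        )
        provenance = "measured"
    else:
        w_sw = s["water_content_swollen"]
        w_un = s["water_content_unswollen"]
        factor = s["swelling_factor"]
        provenance = "paper_default"
    table.add("water_content_swollen", w_sw, "-", provenance)
    table.add("water_content_unswollen", w_un, "-", provenance)
    table.add("swelling_factor", factor, "-", provenance)

    r_un, r_sw = slime_mod.epidermal_fibrosity(
        L_T=ctx["L_T"],
        sigma_ETC=sigma_etc,
        D_epi=cfg["census"]["epidermis_thickness_um"],
        swelling_factor=factor,
    )
    table.add("r_F_unswollen", r_un, "mm/mm^3", "computed")
    table.add("r_F_swollen", r_sw, "mm/mm^3", "computed")

    sigma_t = census_mod.thread_area_density(sigma_etc, ctx["L_T"])
    table.add("sigma_T", sigma_t, "mm/mm^2", "computed")
    table.add("sigma_T_cm", sigma_t * CM_PER_MM, "cm/mm^2", "computed")

    comparison = slime_mod.compare_slimes(
        slime_mod.SlimeComposition(label="epidermal", r_F=r_sw, swelling_factor=factor),
        slime_mod.SlimeComposition(
            label="defensive",
            r_F=r_def,
            V_ejected=comp.V_ejected,
            V_S=comp.V_S,
            total_thread_length=total_thread,
        ),
        exudate_fibrosity=s["exudate_fibrosity_mm_per_mm3"],
    )
    table.add("fibrosity_ratio", comparison["fibrosity_ratio"], "-", "computed")
    table.add("dilution_factor", comparison["dilution_factor"], "-", "computed")

    table.add(
        "productivity",
        slime_mod.productivity(s["slime_mass_mg"], s["scraped_area_cm2"]),
        "mg/cm^2",
        "computed",
    )


def run_report(config: dict) -> ResultsTable:
    """Run the full pipeline and return the table of headline quantities."""
    table = ResultsTable()
    ctx = _census_stage(config, table)
    ctx.update(_morphometrics_stage(config, table))
    _fibrosity_stage(config, table, ctx)
    return table
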