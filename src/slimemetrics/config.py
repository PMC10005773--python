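"""Default analysis configuration and config-file loading.

``PAPER_DEFAULTS`` is the fully documented default profile: every headline
parameter of the reference study, grouped by pipeline stage, in the units
the pipeline uses internally.  A user config (YAML or JSON) is deep-merged
over it, so a config file only needs the keys it changes.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PAPER_DEFAULTS", "load_config", "merge_config"]

PAPER_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "census": {
        # measured epidermal cell area densities, mm^-2
        "sigma_ETC_per_mm2": 434.0,
        "sigma_LMC_per_mm2": 92.0,
        "sigma_SMC_per_mm2": 4.3e5,
        # whole-animal cylinder model; 20 mm diameter is the value consistent
        # with the reported whole-body ETC total
        "body_length_mm": 450.0,
        "body_diameter_mm": 20.0,
        "epidermis_thickness_um": 100.0,
        "n_glands": 163,
    },
    "thread": {
        # epidermal thread geometry (means over digitized helices)
        "phi_um": 0.52,         # thread diameter
        "theta_deg": 63.5,      # helical pitch angle
        "D_um": 0.35,           # helical diameter
        "L_T_mm": 2.2,          # straightened thread length (two free ends)
        # ETC modelled as an ellipsoid, semi-axes in um
        "cell_major_semiaxis_um": 27.0,
        "cell_minor_semiaxis_um": 23.0,
    },
    "gland": {
        # slime-gland ellipsoid axes, mm (mean, sd)
        "full_major_mm": 3.51,
        "full_major_sd_mm": 0.25,
        "full_minor_mm": 2.45,
        "full_minor_sd_mm": 0.15,
        "emptied_major_mm": 2.47,
        "emptied_major_sd_mm": 0.25,
        "emptied_minor_mm": 1.71,
        "emptied_minor_sd_mm": 0.17,
        # GTC counts (cross-section density is a supplementary measurement;
        # the resulting counts are used directly)
        "N_GTC_full": 19300.0,
        "N_GTC_remaining": 4100.0,
        # reported ejected exudate volume, mm^3; differs from the value the
        # mean axes imply (~7.25 mm^3), which the report also shows
        "V_ejected_mm3": 9.37,
        # single slime (GTC) thread length, mm
        "slime_thread_length_mm": 180.0,
    },
    "slime": {
        "rho_g_per_ml": 1.0,          # exudate density, conservative
        "c_wv_g_per_ml": 4e-5,        # 0.004 % w/v thread+mucin in deployed slime
        "swelling_factor": 1.19,      # V(swollen) / V(unswollen)
        "water_content_swollen": 0.939,
        "water_content_swollen_sd": 0.012,
        "water_content_unswollen": 0.747,
        "water_content_unswollen_sd": 0.068,
        "slime_mass_mg": 5.2,         # yield of one coverslip scrape
        "scraped_area_cm2": 18.0,
        # fibrosity of raw (undiluted) exudate, mm/mm^3; an upstream literature
        # value that is not derivable from the parameters above
        "exudate_fibrosity_mm_per_mm3": 6.5e5,
    },
    "data": {
        # optional measured-input tables (CSV paths); None -> defaults only
        "landmarks": None,
        "dense_centerlines": None,
        "transects": None,
        "glands_full": None,
        "glands_emptied": None,
        "slime_samples": None,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """The default profile, optionally overridden by a YAML or JSON file."""
    if path is None:
        return copy.deepcopy(PAPER_DEFAULTS)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        user = json.loads(text)
    else:
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(PAPER_DEFAULTS, user)
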