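"""CSV readers and writers for the pipeline's tabular interchange formats.

Landmark table: ``thread_id, pair_index, side, x_um, y_um, z_um`` with side
in {i, j}; each (thread_id, pair_index) must appear exactly once per side.
Dense centerline table: ``thread_id, point_index, x_um, y_um, z_um``.
Transect table: ``animal_id, cell_type, N_cell, L_section_mm, P_AP, P_DV``.
Gland table: ``gland_id, Phi_a_mm, Phi_b_mm, state``.
Slime-sample table: ``sample_id, group, wet_mass_mg, dry_mass_mg,
scraped_area_cm2`` with group in {swollen, unswollen}.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .census import validate_transects
from .helix import LandmarkSeries
from .slime import GlandGeometry, SlimeSample

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_dense_centerlines",
    "write_dense_centerlines",
    "read_transects",
    "write_transects",
    "read_glands",
    "write_glands",
    "read_slime_samples",
    "write_slime_samples",
]

LANDMARK_COLUMNS = ["thread_id", "pair_index", "side", "x_um", "y_um", "z_um"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_landmarks(series_list: list[LandmarkSeries], path: str | Path) -> None:
    rows = []
    for series in series_list:
        for k, pair in enumerate(series.pairs):
            for side, point in zip(("i", "j"), pair):
                rows.append(
                    {
                        "thread_id": series.thread_id,
                        "pair_index": k,
                        "side": side,
                        "x_um": point[0],
                        "y_um": point[1],
                        "z_um": point[2],
                    }
                )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(
    path: str | Path, dense_path: str | Path | None = None
) -> list[LandmarkSeries]:
    """Landmark pairs grouped by thread, ordered by pair index.

    Raises a row-level error naming the thread and pair when one side of a
    pair is missing; an empty file returns an empty list with a warning.
    """
    df = _read_csv(path, LANDMARK_COLUMNS)
    if df.empty:
        warnings.warn(f"{path}: no landmarks found", stacklevel=2)
        return []
    for col in ("x_um", "y_um", "z_um"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric coordinates in column {col}")

    dense_by_thread: dict[str, np.ndarray] = {}
    if dense_path is not None:
        dense_by_thread = read_dense_centerlines(dense_path)

    out = []
    for thread_id, group in df.groupby("thread_id", sort=False):
        pairs = []
        for pair_index, pair_rows in group.groupby("pair_index", sort=True):
            sides = dict(
                (row.side, np.array([row.x_um, row.y_um, row.z_um]))
                for row in pair_rows.itertuples()
            )
            if set(sides) != {"i", "j"} or len(pair_rows) != 2:
                raise ValueError(
                    f"{path}: thread {thread_id!r} pair {pair_index}: "
                    f"expected exactly one side-i and one side-j row, "
                    f"got sides {sorted(pair_rows['side'])}"
                )
            pairs.append([sides["i"], sides["j"]])
        out.append(
            LandmarkSeries(
                thread_id=str(thread_id),
                pairs=np.array(pairs),
                dense_centerline=dense_by_thread.get(str(thread_id)),
            )
        )
    return out


def write_dense_centerlines(
    centerlines: dict[str, np.ndarray], path: str | Path
) -> None:
    rows = []
    for thread_id, points in centerlines.items():
        for k, p in enumerate(np.asarray(points)):
            rows.append(
                {
                    "thread_id": thread_id,
                    "point_index": k,
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                }
            )
    pd.DataFrame(
        rows, columns=["thread_id", "point_index", "x_um", "y_um", "z_um"]
    ).to_csv(path, index=False)


def read_dense_centerlines(path: str | Path) -> dict[str, np.ndarray]:
    df = _read_csv(path, ["thread_id", "point_index", "x_um", "y_um", "z_um"])
    out = {}
    for thread_id, group in df.groupby("thread_id", sort=False):
        group = group.sort_values("point_index")
        out[str(thread_id)] = group[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    return out


def read_transects(path: str | Path) -> pd.DataFrame:
    return validate_transects(
        _read_csv(path, ["animal_id", "cell_type", "N_cell", "L_section_mm", "P_AP", "P_DV"])
    )


def write_transects(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def write_glands(glands: list[GlandGeometry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gland_id": range(len(glands)),
            "Phi_a_mm": [g.Phi_a for g in glands],
            "Phi_b_mm": [g.Phi_b for g in glands],
            "state": [g.state for g in glands],
        }
    ).to_csv(path, index=False)


def read_glands(path: str | Path) -> list[GlandGeometry]:
    df = _read_csv(path, ["Phi_a_mm", "Phi_b_mm", "state"])
    return [
        GlandGeometry(Phi_a=row.Phi_a_mm, Phi_b=row.Phi_b_mm, state=row.state)
        for row in df.itertuples()
    ]


def write_slime_samples(
    samples: list[SlimeSample], path: str | Path, group: str | list[str] = "unswollen"
) -> None:
    groups = [group] * len(samples) if isinstance(group, str) else list(group)
    pd.DataFrame(
        {
            "sample_id": range(len(samples)),
            "group": groups,
            "wet_mass_mg": [s.wet_mass for s in samples],
            "dry_mass_mg": [s.dry_mass for s in samples],
            "scraped_area_cm2": [s.scraped_area for s in samples],
        }
    ).to_csv(path, index=False)


def read_slime_samples(path: str | Path) -> dict[str, list[SlimeSample]]:
    """Samples keyed by group ('swollen' / 'unswollen')."""
    df = _read_csv(path, ["group", "wet_mass_mg", "dry_mass_mg"])
    out: dict[str, list[SlimeSample]] = {}
    for row in df.itertuples():
        area = getattr(row, "scraped_area_cm2", None)
        out.setdefault(str(row.group), []).append(
            SlimeSample(
                wet_mass=row.wet_mass_mg,
                dry_mass=row.dry_mass_mg,
                scraped_area=None if area is None or pd.isna(area) else float(area),
            )
        )
    return out
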