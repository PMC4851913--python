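"""Regional aggregation of parameter maps over a labeled atlas.

Produces the long-format table (one row per subject x region x parameter)
of regional means and standard deviations that feeds the trajectory and
association statistics. The SD convention is population SD (divide by n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Column order of the tidy region table.
TABLE_COLUMNS = ["subject_id", "age_days", "region", "hemisphere",
                 "parameter", "mean", "sd", "n_voxels"]


@dataclass(frozen=True)
class RegionDefinition:
    """One atlas label: integer id, base region name, hemisphere tag."""

    region_id: int
    name: str
    hemisphere: str  # "left" | "right" | "midline"

    def __post_init__(self):
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer label")
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")


def regional_summary(volume: np.ndarray, labels: np.ndarray,
                     defined_mask: np.ndarray,
                     regions: list[RegionDefinition]) -> list[dict]:
    """Mean and population SD of one map over each labeled region.

    Only voxels with a matching label AND ``defined_mask`` true contribute.
    Regions with zero defined voxels are omitted with a logged warning.
    """
    volume = np.asarray(volume)
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError("label volume must have an integer dtype")
    defined_mask = np.asarray(defined_mask, dtype=bool)
    if not (volume.shape == labels.shape == defined_mask.shape):
        raise ValueError("volume, labels and defined_mask must share one grid")

    rows = []
    for region in regions:
        sel = (labels == region.region_id) & defined_mask
        n = int(np.count_nonzero(sel))
        if n == 0:
            log.warning("region %s (%s): no defined voxels, row omitted",
                        region.name, region.hemisphere)
            continue
        values = volume[sel]
        rows.append({
            "region": region.name,
            "hemisphere": region.hemisphere,
            "mean": float(np.mean(values)),
            "sd": float(np.std(values)),  # population SD
            "n_voxels": n,
        })
    return rows


def summarize_subject(subject_id: str, age_days: float,
                      param_volumes: dict[str, np.ndarray],
                      labels: np.ndarray, defined_mask: np.ndarray,
                      regions: list[RegionDefinition]) -> pd.DataFrame:
    """Regional summary rows for all of one subject's parameter maps.

    ``param_volumes`` maps parameter name (g, vfm, vff, nu_ic, nu_iso) to
    its volume on the shared grid.
    """
    frames = []
    for parameter, volume in param_volumes.items():
        for row in regional_summary(volume, labels, defined_mask, regions):
            frames.append({"subject_id": subject_id, "age_days": age_days,
                           "parameter": parameter, **row})
    return pd.DataFrame(frames, columns=TABLE_COLUMNS)


def merge_hemispheres(table: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Append hemisphere-combined rows for every bilateral region.

    The combined mean is the voxel-count-weighted mean of the two
    hemispheres (equivalently: the mean over the pooled voxels); the
    combined SD is the pooled population SD. With ``weighted=False`` the
    two hemisphere means are averaged with equal weight instead.
    Midline regions pass through unchanged. A bilateral region present in
    only one hemisphere is a configuration error.
    """
    combined_rows = []
    lateral = table[table["hemisphere"].isin(["left", "right"])]
    for (subject_id, region, parameter), grp in lateral.groupby(
            ["subject_id", "region", "parameter"], sort=False):
        hemis = set(grp["hemisphere"])
        if hemis != {"left", "right"}:
            raise ValueError(
                f"bilateral region {region!r} for subject {subject_id!r} "
                f"present only as {sorted(hemis)}")
        n = grp["n_voxels"].to_numpy(dtype=float)
        m = grp["mean"].to_numpy()
        sd = grp["sd"].to_numpy()
        w = n if weighted else np.ones_like(n)
        mean_c = float(np.sum(w * m) / np.sum(w))
        # pooled population variance: E[x^2] - (E[x])^2 over the union
        ex2 = float(np.sum(n * (sd ** 2 + m ** 2)) / np.sum(n))
        sd_c = float(np.sqrt(max(ex2 - (np.sum(n * m) / np.sum(n)) ** 2, 0.0)))
        combined_rows.append({
            "subject_id": subject_id,
            "age_days": float(grp["age_days"].iloc[0]),
            "region": region, "hemisphere": "combined",
            "parameter": parameter, "mean": mean_c, "sd": sd_c,
            "n_voxels": int(np.sum(n)),
        })
    if not combined_rows:
        return table.copy()
    return pd.concat([table, pd.DataFrame(combined_rows, columns=TABLE_COLUMNS)],
                     ignore_index=True)
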