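"""Measurement-table assembly and animal/voxel exclusion rules.

The long-format measurement table is the hand-off point between image
processing and group statistics: one row per (animal, day, ROI, metric)
with the design factors attached.  Exclusions are *flags with reasons*,
never silent deletion — the statistics layer refuses tables that still
contain excluded rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "ExclusionConfig",
    "mad_filter",
    "apply_exclusions",
    "assemble_table",
    "require_clean",
    "read_table",
    "write_table",
]

TABLE_COLUMNS = [
    "animal_id", "sex", "injury", "regimen", "day", "roi", "metric",
    "value", "muscle_auc_raw", "n_voxels", "excluded", "exclusion_reason",
]

KEY = ["animal_id", "day", "roi", "metric"]


@dataclass(frozen=True)
class ExclusionConfig:
    """Exclusion thresholds.

    ``min_muscle_auc``: sessions whose raw muscle-reference AUC falls below
    this are excluded outright (poor contrast uptake makes normalization
    meaningless).  ``mad_k``: ROI voxels outside median +/- mad_k * MAD are
    dropped before summarizing.  ``min_voxels``: ROI summaries built from
    fewer surviving voxels than this are excluded (likely ROI-drawing error).
    """

    min_muscle_auc: float = 0.01
    mad_k: float = 4.0
    min_voxels: int = 5


def mad_filter(values: np.ndarray, k: float = 4.0) -> Tuple[np.ndarray, int]:
    """Drop values outside median +/- k * MAD (raw median absolute deviation).

    Returns ``(kept, n_dropped)``.  When the MAD is zero (at least half the
    values identical) no robust scale exists and all values are kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v, 0
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return v, 0
    keep = np.abs(v - med) <= k * mad
    return v[keep], int((~keep).sum())


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("animal_id", "day", "roi", "metric", "value")
               if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    dup = table.duplicated(subset=KEY)
    if dup.any():
        first = table.loc[dup.idxmax(), KEY].tolist()
        raise ValueError(f"duplicate measurement row for {tuple(first)}")
    return table


def assemble_table(records: Iterable[Mapping], design_meta: Optional[pd.DataFrame] = None,
                   ) -> pd.DataFrame:
    """Build the long-format table from per-session ROI summary records.

    ``records`` yield dicts with at least (animal_id, day, roi, metric,
    value); ``design_meta`` (one row per animal: sex, injury, regimen) is
    merged in when the records do not already carry the factors.  Missing
    visits are simply absent rows; duplicate keys are a hard error.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no measurement records")
    if design_meta is not None:
        meta_cols = [c for c in ("sex", "injury", "regimen") if c not in df.columns]
        if meta_cols:
            df = df.merge(design_meta[["animal_id"] + meta_cols], on="animal_id",
                          how="left", validate="many_to_one")
    for col, default in (("muscle_auc_raw", np.nan), ("n_voxels", np.nan),
                         ("excluded", False), ("exclusion_reason", "")):
        if col not in df.columns:
            df[col] = default
    df["excluded"] = df["excluded"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    _validate(df)
    cols = [c for c in TABLE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra].reset_index(drop=True)


def apply_exclusions(table: pd.DataFrame, rules: ExclusionConfig) -> pd.DataFrame:
    """Flag excluded rows according to ``rules``.  Idempotent.

    Session-level: any (animal, day) whose ``muscle_auc_raw`` is missing or
    below ``rules.min_muscle_auc`` has *all* its rows excluded with reason
    ``poor_uptake``.  ROI-level: rows whose ``n_voxels`` (voxels surviving
    the MAD filter applied at summary time) is below ``rules.min_voxels``
    are excluded with reason ``roi_too_small``.  Pre-existing flags are
    recomputed from scratch so applying the rules twice equals once.
    """
    t = _validate(table.copy())
    excluded = np.zeros(len(t), dtype=bool)
    reason = np.array([""] * len(t), dtype=object)

    if "muscle_auc_raw" in t.columns:
        muscle = pd.to_numeric(t["muscle_auc_raw"], errors="coerce")
        bad = muscle.isna() | (muscle < rules.min_muscle_auc)
        excluded |= bad.to_numpy()
        reason[bad.to_numpy()] = "poor_uptake"

    if "n_voxels" in t.columns:
        nv = pd.to_numeric(t["n_voxels"], errors="coerce")
        small = nv.notna() & (nv < rules.min_voxels) & ~excluded
        excluded |= small.to_numpy()
        reason[small.to_numpy()] = "roi_too_small"

    bad_value = t["value"].isna().to_numpy() & ~excluded
    excluded |= bad_value
    reason[bad_value] = "missing_value"

    t["excluded"] = excluded
    t["exclusion_reason"] = reason
    return t


def require_clean(table: pd.DataFrame) -> pd.DataFrame:
    """Guard used by the statistics layer: drop flagged rows, refuse tables
    that were never run through :func:`apply_exclusions`."""
    if "excluded" not in table.columns:
        raise ValueError("table has no exclusion flags; run apply_exclusions first")
    return table[~table["excluded"].astype(bool)].copy()


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    if "exclusion_reason" in df.columns:
        df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    return _validate(df)
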