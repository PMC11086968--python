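"""Reading long-format curve tables, region scanning and result output."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import DesignPoints, rescale_positions
from .waldtest import bh_adjust, parallelism_test

__all__ = ["ColumnMap", "read_long_table", "read_regions", "scan_regions",
           "write_results", "read_results"]

logger = logging.getLogger("parcurve")

#: display precision of result tables; full double precision is kept on disk.
_DISPLAY_DIGITS = 6
_WRITE_FORMAT = "%.17g"


@dataclass
class ColumnMap:
    position: str = "position"
    group: str = "group"
    subject: str = "subject"
    value: str = "value"


class TableFormatError(ValueError):
    """The long-format table violates the expected layout."""


def _frame_to_design(df: pd.DataFrame, cols: ColumnMap,
                     group_labels: dict | None = None,
                     rescale: bool = True) -> DesignPoints:
    counts = df.groupby([cols.position, cols.subject]).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index[0]
        raise TableFormatError(f"duplicate observation at (position, subject) = {dup}")
    pivot_val = df.pivot(index=cols.position, columns=cols.subject, values=cols.value)
    if pivot_val.isna().any().any():
        missing = int(pivot_val.isna().sum().sum())
        raise TableFormatError(
            f"incomplete position x subject grid: {missing} missing cells"
        )

    n_levels = df.groupby(cols.subject)[cols.group].nunique()
    if (n_levels > 1).any():
        bad = n_levels[n_levels > 1].index[0]
        raise TableFormatError(f"subject {bad} carries multiple group labels")
    groups_raw = df.groupby(cols.subject)[cols.group].first()

    levels = sorted(pd.unique(groups_raw), key=str)
    if group_labels is None:
        if set(levels) <= {0, 1}:
            group_labels = {0: 0, 1: 1}
        elif len(levels) == 2:
            group_labels = {levels[0]: 0, levels[1]: 1}
            logger.info("mapped group labels %s -> 0, %s -> 1", levels[0], levels[1])
        else:
            raise TableFormatError(
                f"group column has {len(levels)} levels {levels}; expected two"
            )
    unmapped = [l for l in levels if l not in group_labels]
    if unmapped:
        raise TableFormatError(f"group level {unmapped[0]!r} has no 0/1 mapping")

    positions = pivot_val.index.to_numpy(dtype=float)
    if rescale and (positions.min() < 0 or positions.max() > 1):
        positions, (lo, hi) = rescale_positions(positions)
        logger.info("rescaled positions from [%g, %g] to [0, 1]", lo, hi)
    subjects = pivot_val.columns
    groups = np.array([group_labels[groups_raw[s]] for s in subjects], dtype=int)
    return DesignPoints(positions=positions,
                        subject_groups=groups,
                        responses=pivot_val.to_numpy(dtype=float))


def read_long_table(path, column_map: ColumnMap | dict | None = None,
                    group_labels: dict | None = None,
                    sep: str | None = None) -> DesignPoints:
    """Read a delimited long-format table into validated DesignPoints.

    Expected columns (configurable): position, group, subject, value.
    Positions outside [0,1] are min-max rescaled (logged); group labels are
    mapped to {0,1} (supply ``group_labels`` for non-numeric labels, e.g.
    {"control": 0, "case": 1}).
    """
    if column_map is None:
        cols = ColumnMap()
    elif isinstance(column_map, dict):
        cols = ColumnMap(**column_map)
    else:
        cols = column_map
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in (cols.position, cols.group, cols.subject, cols.value)
               if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns {missing}; found {list(df.columns)}")
    for c in (cols.position, cols.value):
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
            raise TableFormatError(f"unparseable numeric in column {c!r} at file row {row}")
        df[c] = pd.to_numeric(df[c])
    return _frame_to_design(df, cols, group_labels=group_labels)


def read_regions(path) -> pd.DataFrame:
    """BED-like region file: chrom, start, end (half-open, 0-based), no header."""
    reg = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                      names=["chrom", "start", "end"], usecols=[0, 1, 2])
    if (reg["start"] >= reg["end"]).any():
        i = int(np.flatnonzero(reg["start"] >= reg["end"])[0])
        raise TableFormatError(f"region {i} has start >= end")
    return reg


def scan_regions(
    data_path,
    regions_path,
    alpha: float = 0.05,
    m: int = 2,
    min_obs_per_group: int = 20,
    column_map: ColumnMap | dict | None = None,
    group_labels: dict | None = None,
    chrom_column: str | None = None,
) -> pd.DataFrame:
    """Test every region and BH-adjust across regions.

    Positions are rescaled to [0,1] *within* each region.  Regions with fewer
    than ``min_obs_per_group`` positions are reported with NA statistics and a
    logged skip reason — never silently dropped.  Output order follows the
    region file.
    """
    cols = ColumnMap(**column_map) if isinstance(column_map, dict) else (column_map or ColumnMap())
    df = pd.read_csv(data_path, sep=None, engine="python")
    regions = read_regions(regions_path)

    records = []
    for idx, reg in regions.iterrows():
        sel = (df[cols.position] >= reg["start"]) & (df[cols.position] < reg["end"])
        if chrom_column is not None:
            sel &= df[chrom_column] == reg["chrom"]
        sub = df[sel].copy()
        n_pos = sub[cols.position].nunique()
        rec = dict(chrom=reg["chrom"], start=reg["start"], end=reg["end"],
                   n_obs=int(sel.sum()), statistic=np.nan, z=np.nan,
                   p_value=np.nan, lambda_star=np.nan)
        if n_pos < min_obs_per_group:
            logger.warning("region %s:%s-%s skipped: %d positions < %d required",
                           reg["chrom"], reg["start"], reg["end"], n_pos, min_obs_per_group)
            records.append(rec)
            continue
        span = reg["end"] - reg["start"]
        sub[cols.position] = (sub[cols.position] - reg["start"]) / span
        points = _frame_to_design(sub, cols, group_labels=group_labels, rescale=False)
        res = parallelism_test(points, alpha=alpha, m=m)
        rec.update(statistic=res.statistic, z=res.z, p_value=res.p_value,
                   lambda_star=res.lambda_star)
        records.append(rec)

    out = pd.DataFrame(records)
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.any():
        out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with 17 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=_WRITE_FORMAT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def format_results(df: pd.DataFrame) -> str:
    """Human-readable rendering (6 significant digits)."""
    with pd.option_context("display.float_format", lambda v: f"{v:.6g}"):
        return df.to_string(index=False)
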