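"""Reading and writing the pipeline's tabular formats.

Count matrices travel as a pair of wide TSVs (sites as rows, fish as
columns) sharing a site-metadata block, or as per-fish coverage files in the
Bismark style (``chrom  start  end  %meth  count_meth  count_unmeth``,
1-based inclusive coordinates). Fish metadata is CSV with ISO 8601 dates.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .aging import FishRecord
from .qc import MethylationCountMatrix

_SITE_COLS = ["site_id", "chromosome", "position", "strand"]


def write_count_matrix(matrix: MethylationCountMatrix, meth_path, total_path) -> None:
    for arr, path in ((matrix.meth, meth_path), (matrix.total, total_path)):
        counts = pd.DataFrame(arr.T, columns=matrix.fish_ids)
        df = pd.concat([matrix.sites[_SITE_COLS].reset_index(drop=True), counts], axis=1)
        df.to_csv(path, sep="\t", index=False)


def read_count_matrix(meth_path, total_path) -> MethylationCountMatrix:
    meth_df = pd.read_csv(meth_path, sep="\t")
    total_df = pd.read_csv(total_path, sep="\t")
    for df, name in ((meth_df, meth_path), (total_df, total_path)):
        missing = [c for c in _SITE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{name}: missing site columns {missing}")
    fish_ids = [c for c in meth_df.columns if c not in _SITE_COLS]
    if fish_ids != [c for c in total_df.columns if c not in _SITE_COLS]:
        raise ValueError("meth and total matrices have different fish columns")
    if not meth_df["site_id"].equals(total_df["site_id"]):
        raise ValueError("meth and total matrices have different site rows")
    meth = meth_df[fish_ids].to_numpy(dtype=np.int64).T
    total = total_df[fish_ids].to_numpy(dtype=np.int64).T
    return MethylationCountMatrix(
        fish_ids=fish_ids, sites=meth_df[_SITE_COLS].copy(), meth=meth, total=total
    )


def read_coverage_files(paths: dict[str, str | Path]) -> MethylationCountMatrix:
    """Assemble a count matrix from per-fish coverage files.

    Each file has columns chrom, start, end, percent_meth, count_meth,
    count_unmeth (no header), 1-based inclusive; start == end for a CpG.
    Sites missing from a fish's file are missing cells.
    """
    per_fish: dict[str, pd.DataFrame] = {}
    all_sites: dict[tuple, None] = {}
    for fish_id, path in paths.items():
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chromosome", "start", "end", "pct", "count_meth", "count_unmeth"],
        )
        if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
            raise ValueError(f"{path}: negative counts")
        df["position"] = df["start"]
        key = df[["chromosome", "position"]]
        if key.duplicated().any():
            raise ValueError(f"{path}: duplicate site keys")
        per_fish[fish_id] = df
        for tup in key.itertuples(index=False):
            all_sites.setdefault((tup.chromosome, tup.position))
    site_list = sorted(all_sites)
    index = {k: j for j, k in enumerate(site_list)}
    n_fish, n_sites = len(per_fish), len(site_list)
    meth = np.zeros((n_fish, n_sites), dtype=np.int64)
    total = np.zeros((n_fish, n_sites), dtype=np.int64)
    fish_ids = list(per_fish)
    for i, fid in enumerate(fish_ids):
        df = per_fish[fid]
        j = np.array([index[(c, p)] for c, p in zip(df["chromosome"], df["position"])])
        meth[i, j] = df["count_meth"]
        total[i, j] = df["count_meth"] + df["count_unmeth"]
    sites = pd.DataFrame(
        {
            "site_id": [f"{c}:{p}" for c, p in site_list],
            "chromosome": [c for c, _ in site_list],
            "position": [p for _, p in site_list],
            "strand": "+",
        }
    )
    return MethylationCountMatrix(fish_ids=fish_ids, sites=sites, meth=meth, total=total)


def read_count_data(
    meth_path=None, total_path=None, coverage_paths: dict | None = None
) -> MethylationCountMatrix:
    """Load counts from wide TSVs or per-fish coverage files (one of the two)."""
    if coverage_paths is not None:
        return read_coverage_files(coverage_paths)
    if meth_path is None or total_path is None:
        raise ValueError("provide meth_path and total_path, or coverage_paths")
    return read_count_matrix(meth_path, total_path)


# --------------------------------------------------------------------------
# fish metadata
# --------------------------------------------------------------------------

def write_fish_metadata(records: list[FishRecord], path) -> None:
    pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "water_body": [r.water_body for r in records],
            "capture_date": [r.capture_date.isoformat() for r in records],
            "reader1_zones": [r.reader1_zones for r in records],
            "reader2_zones": [r.reader2_zones for r in records],
            "total_length_mm": [r.total_length for r in records],
            "weight_g": [r.weight for r in records],
        }
    ).to_csv(path, index=False)


def read_fish_metadata(path) -> list[FishRecord]:
    df = pd.read_csv(path)
    required = {"fish_id", "water_body", "capture_date", "reader1_zones", "reader2_zones"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            FishRecord(
                fish_id=str(row.fish_id),
                water_body=str(row.water_body),
                capture_date=_dt.date.fromisoformat(str(row.capture_date)),
                reader1_zones=None if pd.isna(row.reader1_zones) else int(row.reader1_zones),
                reader2_zones=None if pd.isna(row.reader2_zones) else int(row.reader2_zones),
                total_length=getattr(row, "total_length_mm", None),
                weight=getattr(row, "weight_g", None),
            )
        )
    return records


def write_substitution_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_substitution_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "untreated_reads", "substituted_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
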