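"""Reading and writing long-format paired-measurement tables.

The on-disk format is a delimited text file (CSV by default, header
required) with one row per subject / device / time point carrying the
reference and test readings.  The reader applies the study exclusion rules:
the first pair of every subject-device series is dropped by default (it is
typically consumed to calibrate the test device) and pairs with a missing
member are dropped; every exclusion is logged with a reason.  Excluded
pairs leave a gap in the time index, so downstream classification never
forms a change bridging them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import PairedSeries

__all__ = ["ColumnMap", "read_series", "write_series", "series_to_frame"]

EXCLUDED_FIRST = "calibration_first_pair"
EXCLUDED_MISSING = "missing_value"


@dataclass(frozen=True)
class ColumnMap:
    """Column mapping from file headers to the long-record schema.

    ``device`` may be None for single-device files (label defaults to "TM").
    """

    subject: str = "subject"
    device: str | None = "device"
    time: str = "time"
    rm: str = "rm"
    tm: str = "tm"


def read_series(
    path,
    *,
    columns: ColumnMap | None = None,
    delimiter: str = ",",
    exclude_first: bool = True,
) -> tuple[list[PairedSeries], pd.DataFrame]:
    """Read a delimited long-format file into per-subject-device series.

    Returns ``(series_list, exclusion_log)``.  The log has one row per
    excluded pair with columns subject/device/time/reason, so
    ``rows_in == pairs_used + pairs_excluded`` always holds.

    Raises on unparseable rows, missing mapped columns, or duplicate
    (subject, device, time) keys.
    """
    columns = columns or ColumnMap()
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    needed = [columns.subject, columns.time, columns.rm, columns.tm]
    if columns.device is not None:
        needed.insert(1, columns.device)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing column(s) {missing_cols}; found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    work = pd.DataFrame(
        {
            "subject": df[columns.subject].astype(str),
            "device": (
                df[columns.device].astype(str)
                if columns.device is not None
                else "TM"
            ),
            "time": df[columns.time],
            "rm": pd.to_numeric(df[columns.rm], errors="coerce"),
            "tm": pd.to_numeric(df[columns.tm], errors="coerce"),
        }
    )
    if work["time"].isna().any():
        bad = work.index[work["time"].isna()][0] + 2  # 1-based incl. header
        raise ValueError(f"{path}: missing time index at line {bad}")
    work["time"] = pd.to_numeric(work["time"], errors="raise").astype(int)

    dup = work.duplicated(subset=["subject", "device", "time"])
    if dup.any():
        first = work.loc[dup.idxmax()]
        raise ValueError(
            f"{path}: duplicate key (subject={first['subject']}, "
            f"device={first['device']}, time={first['time']})"
        )

    series_list: list[PairedSeries] = []
    log_rows: list[dict] = []
    for (subject, device), grp in work.groupby(["subject", "device"], sort=True):
        grp = grp.sort_values("time")
        # rank rows 0..n-1 so adjacency reflects the file's own ordering;
        # exclusions then leave holes in the rank sequence
        grp = grp.assign(rank=range(len(grp)))
        kept = []
        for _, row in grp.iterrows():
            if exclude_first and row["rank"] == 0:
                log_rows.append(
                    dict(subject=subject, device=device, time=row["time"],
                         reason=EXCLUDED_FIRST)
                )
                continue
            if pd.isna(row["rm"]) or pd.isna(row["tm"]):
                log_rows.append(
                    dict(subject=subject, device=device, time=row["time"],
                         reason=EXCLUDED_MISSING)
                )
                continue
            kept.append((float(row["rm"]), float(row["tm"]), int(row["rank"])))
        if kept:
            series_list.append(
                PairedSeries(subject_id=subject, device=device, values=tuple(kept))
            )
    log = pd.DataFrame(log_rows, columns=["subject", "device", "time", "reason"])
    return series_list, log


def series_to_frame(series_list: list[PairedSeries]) -> pd.DataFrame:
    """Flatten series into the long-format table the reader understands."""
    rows = [
        {"subject": s.subject_id, "device": s.device, "time": t, "rm": rm, "tm": tm}
        for s in series_list
        for rm, tm, t in s.values
    ]
    return pd.DataFrame(rows, columns=["subject", "device", "time", "rm", "tm"])


def write_series(series_list: list[PairedSeries], path, *, delimiter: str = ",") -> None:
    """Write series as a delimited long-format text file (RFC-4180 quoting)."""
    series_to_frame(series_list).to_csv(path, sep=delimiter, index=False)
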