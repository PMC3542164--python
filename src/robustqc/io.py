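"""Tabular ingest and report writing for the screening pipeline.

Input is tidy CSV with columns ``unit_id, indicator, value`` (one row per
reporting unit per indicator; extra columns are ignored). Output is a summary
CSV with one row per indicator x method plus a per-unit flags CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sample import IndicatorSample
from .screening import ScreeningResult

logger = logging.getLogger("robustqc")

REQUIRED_COLUMNS = ("unit_id", "indicator", "value")


class TableFormatError(ValueError):
    """Malformed indicator table (missing column or non-numeric value)."""


@dataclass(frozen=True)
class ScreeningReportRow:
    indicator: str
    method: str
    n: int
    n_flagged: int
    flag_rate: float
    status: str


def read_indicator_table(path) -> dict[str, IndicatorSample]:
    """Read a tidy indicator CSV into one sample per indicator.

    Rows with an empty value are dropped (with a logged count); a value that
    is present but not numeric is an error naming its line number. Unit order
    within each indicator follows file order.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )
    stripped = frame["value"].str.strip()
    empty = stripped == ""
    if empty.any():
        logger.info(
            "dropped %d row(s) with empty value from %s", int(empty.sum()), path
        )
    frame = frame[~empty]
    numeric = pd.to_numeric(frame["value"], errors="coerce")
    bad = numeric.isna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing.
        idx = int(frame.index[bad][0])
        raise TableFormatError(
            f"non-numeric value {frame['value'].iloc[int(np.where(bad)[0][0])]!r} "
            f"on line {idx + 2}"
        )
    # numpy's parser is correctly rounded, so written samples round-trip.
    frame = frame.assign(value=frame["value"].to_numpy(dtype=str).astype(float))
    samples: dict[str, IndicatorSample] = {}
    for indicator, grp in frame.groupby("indicator", sort=False):
        samples[str(indicator)] = IndicatorSample(
            values=grp["value"].to_numpy(dtype=float),
            unit_ids=grp["unit_id"].to_numpy(dtype=object),
        )
    return samples


def write_screening_report(
    results: Mapping[str, Mapping[str, ScreeningResult]],
    samples: Mapping[str, IndicatorSample],
    summary_path,
    flags_path,
) -> list[ScreeningReportRow]:
    """Write the indicator x method summary CSV and the per-unit flags CSV.

    Failed screens (degenerate scale) appear with zero flags and status
    ``failed`` — the tabular analogue of a dash in a report. Numeric columns
    are fixed to 4 decimals.
    """
    if not results:
        raise ValueError("results must be nonempty")
    summary_rows: list[ScreeningReportRow] = []
    flag_rows: list[dict] = []
    for indicator, per_method in results.items():
        sample = samples[indicator]
        n = len(sample)
        unit_ids = (
            sample.unit_ids
            if sample.unit_ids is not None
            else np.array([f"u{i + 1:04d}" for i in range(n)], dtype=object)
        )
        for method, result in per_method.items():
            summary_rows.append(
                ScreeningReportRow(
                    indicator=indicator,
                    method=method,
                    n=n,
                    n_flagged=result.n_flagged,
                    flag_rate=result.n_flagged / n if n else 0.0,
                    status=result.status,
                )
            )
            stats_ = result.statistics
            for i in range(n):
                flag_rows.append(
                    {
                        "unit_id": unit_ids[i],
                        "indicator": indicator,
                        "method": method,
                        "statistic": ""
                        if stats_ is None
                        else f"{stats_[i]:.4f}",
                        "flagged": int(result.flags[i]),
                    }
                )
    summary = pd.DataFrame([vars(r) for r in summary_rows])
    summary["flag_rate"] = summary["flag_rate"].map(lambda v: f"{v:.4f}")
    summary.to_csv(summary_path, index=False)
    pd.DataFrame(flag_rows).to_csv(flags_path, index=False)
    return summary_rows


def read_config(path) -> dict[str, str]:
    """Read a plain ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise TableFormatError(
                    f"malformed config line {lineno}: {raw.rstrip()!r}"
                )
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
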