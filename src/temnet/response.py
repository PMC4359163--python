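"""Replicate-structured treatment-response tables.

Measurements are receptor expression (flow-cytometry MFI) or cytokine
secretion changes of treated cells, expressed as a percentage of the
untreated control (untreated = 100).  Analysis happens on the log2-ratio
scale, ``log2(percent / 100)``, where untreated = 0, doubling = +1 and
halving = -1.

The on-disk dialect is a UTF-8 TSV with header
``replicate<TAB>treatment<TAB>readout<TAB>value``; combined-treatment names
join their ligand components with ``+`` (e.g. ``TGFB+PLGF``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Readout",
    "Treatment",
    "ResponseTable",
    "ResponseParseError",
    "ResponseValidationError",
    "read_response_table",
    "write_response_table",
    "convert_supplementary_workbook",
    "to_log2_ratio",
    "from_log2_ratio",
    "summarize_effects",
]

RECEPTOR = "receptor"
CYTOKINE = "cytokine"

PERCENT_SCALE = "percent-of-untreated"
LOG2_SCALE = "log2-ratio"

_COLUMNS = ("replicate", "treatment", "readout", "value")


class ResponseParseError(ValueError):
    """Malformed input file (wrong header, unreadable value)."""


class ResponseValidationError(ValueError):
    """Structurally valid file with invalid content (e.g. negative percent)."""


@dataclass(frozen=True)
class Readout:
    """A measured quantity: a surface receptor or a secreted cytokine."""

    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (RECEPTOR, CYTOKINE):
            raise ResponseValidationError(f"unknown readout kind {self.kind!r}")


@dataclass(frozen=True)
class Treatment:
    """A single- or combined-ligand treatment (components joined by '+')."""

    name: str

    @property
    def components(self) -> frozenset[str]:
        return frozenset(part for part in self.name.split("+") if part)

    @property
    def is_combined(self) -> bool:
        return len(self.components) >= 2

    def __post_init__(self) -> None:
        if not self.components:
            raise ResponseValidationError("treatment must have at least one component")
        if len(self.components) > 3:
            raise ResponseValidationError("treatments combine at most three ligands")


@dataclass
class ResponseTable:
    """Per-replicate effect values for one readout kind.

    ``data`` has columns replicate, treatment, readout, value; one row per
    (replicate, treatment, readout) entry.  ``value_scale`` is either
    percent-of-untreated (values >= 0, untreated = 100) or log2-ratio
    (untreated = 0).
    """

    data: pd.DataFrame
    kind: str
    value_scale: str = PERCENT_SCALE

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ResponseValidationError(f"missing columns: {missing}")
        if self.kind not in (RECEPTOR, CYTOKINE):
            raise ResponseValidationError(f"unknown readout kind {self.kind!r}")
        if self.value_scale not in (PERCENT_SCALE, LOG2_SCALE):
            raise ResponseValidationError(f"unknown value scale {self.value_scale!r}")
        self.data = self.data.loc[:, list(_COLUMNS)].reset_index(drop=True)
        values = self.data["value"].to_numpy(dtype=float)
        if self.value_scale == PERCENT_SCALE and (values < 0).any():
            bad = self.data.loc[values < 0].iloc[0]
            raise ResponseValidationError(
                f"negative percent value {bad['value']!r} for "
                f"({bad['replicate']!r}, {bad['treatment']!r}, {bad['readout']!r})"
            )
        dupes = self.data.duplicated(subset=["replicate", "treatment", "readout"])
        if dupes.any():
            raise ResponseValidationError("duplicate (replicate, treatment, readout) entries")

    # -- basic accessors ---------------------------------------------------

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["treatment"]))

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["readout"]))

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["replicate"]))

    def values_for(self, treatment: str, readout: str) -> np.ndarray:
        mask = (self.data["treatment"] == treatment) & (self.data["readout"] == readout)
        return self.data.loc[mask, "value"].to_numpy(dtype=float)

    # -- scale conversion --------------------------------------------------

    def to_log2(self) -> "ResponseTable":
        """Return a copy on the log2-ratio scale."""
        if self.value_scale == LOG2_SCALE:
            return ResponseTable(self.data.copy(), self.kind, LOG2_SCALE)
        out = self.data.copy()
        out["value"] = to_log2_ratio(out["value"].to_numpy(dtype=float))
        return ResponseTable(out, self.kind, LOG2_SCALE)

    def to_percent(self) -> "ResponseTable":
        """Return a copy on the percent-of-untreated scale."""
        if self.value_scale == PERCENT_SCALE:
            return ResponseTable(self.data.copy(), self.kind, PERCENT_SCALE)
        out = self.data.copy()
        out["value"] = from_log2_ratio(out["value"].to_numpy(dtype=float))
        return ResponseTable(out, self.kind, PERCENT_SCALE)


def to_log2_ratio(value_percent):
    """percent-of-untreated -> log2 ratio: log2(percent / 100).

    Untreated (100) maps to 0, doubling (200) to +1, halving (50) to -1.
    """
    arr = np.asarray(value_percent, dtype=float)
    if (arr <= 0).any():
        raise ResponseValidationError("log2 ratio requires strictly positive percent values")
    result = np.log2(arr / 100.0)
    return float(result) if np.isscalar(value_percent) or result.ndim == 0 else result


def from_log2_ratio(value_log2):
    """Inverse of :func:`to_log2_ratio`: 100 * 2**x."""
    arr = np.asarray(value_log2, dtype=float)
    result = 100.0 * np.exp2(arr)
    return float(result) if np.isscalar(value_log2) or result.ndim == 0 else result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_response_table(path, kind: str, value_scale: str = PERCENT_SCALE) -> ResponseTable:
    """Read the TSV dialect; rows with missing values are dropped and logged."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"replicate": str, "treatment": str, "readout": str})
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ResponseParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ResponseParseError(f"{path}: missing column(s) {missing}")
    frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    n_bad = int(frame["value"].isna().sum())
    if n_bad:
        logger.warning("%s: dropping %d row(s) with missing values", path, n_bad)
        frame = frame.dropna(subset=["value"])
    return ResponseTable(frame.reset_index(drop=True), kind, value_scale)


def write_response_table(table: ResponseTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def convert_supplementary_workbook(
    path,
    out_path,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Convert a supplementary-table style workbook to the TSV dialect.

    The expected sheet layout is one row per readout, with the first column
    naming the readout and each remaining column headed
    ``treatment|replicate`` holding a percent-of-untreated value.  The
    function writes the long-format TSV and returns the frame.
    """
    from openpyxl import load_workbook

    workbook = load_workbook(path, read_only=True, data_only=True)
    worksheet = workbook.worksheets[sheet] if isinstance(sheet, int) else workbook[sheet]
    rows = list(worksheet.iter_rows(values_only=True))
    if not rows or not rows[0] or len(rows[0]) < 2:
        raise ResponseParseError(f"{path}: empty or headerless sheet")
    header = rows[0]
    records = []
    for row in rows[1:]:
        if row is None or row[0] is None:
            continue
        readout = str(row[0])
        for col, cell in zip(header[1:], row[1:]):
            if col is None or cell is None:
                continue
            if "|" not in str(col):
                raise ResponseParseError(
                    f"{path}: column header {col!r} is not 'treatment|replicate'"
                )
            treatment, _, replicate = str(col).partition("|")
            records.append(
                {"replicate": replicate, "treatment": treatment, "readout": readout, "value": float(cell)}
            )
    frame = pd.DataFrame.from_records(records, columns=list(_COLUMNS))
    frame.to_csv(out_path, sep="\t", index=False)
    return frame


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def sign_counts(values: np.ndarray) -> tuple[int, int, int]:
    """(positive, negative, zero) counts; exact zeros support neither sign."""
    arr = np.asarray(values, dtype=float)
    return int((arr > 0).sum()), int((arr < 0).sum()), int((arr == 0).sum())


def majority_sign(values: np.ndarray) -> tuple[int, float]:
    """Majority sign (+1/-1, 0 on a tie or all zeros) and its replicate share.

    The share is the majority count divided by the total replicate count;
    zeros count toward neither sign but stay in the denominator.
    """
    pos, neg, _ = sign_counts(values)
    total = len(np.asarray(values))
    if total == 0 or (pos == 0 and neg == 0):
        return 0, 0.0
    if pos == neg:
        return 0, pos / total
    sign = 1 if pos > neg else -1
    return sign, max(pos, neg) / total


def summarize_effects(table: ResponseTable) -> pd.DataFrame:
    """Per-(treatment, readout) effect summary on the log2 scale.

    Returns a frame indexed by (treatment, readout) with columns
    ``mean_log2`` (arithmetic mean of per-replicate log2 ratios),
    ``n_replicates`` and ``sign_agreement`` (fraction of replicates sharing
    the majority sign; exact zeros count toward neither sign).
    """
    if len(table.data) == 0:
        raise ResponseValidationError("cannot summarize an empty table")
    log_table = table.to_log2()
    grouped = log_table.data.groupby(["treatment", "readout"], sort=True)["value"]

    def agreement(series: pd.Series) -> float:
        return majority_sign(series.to_numpy())[1]

    def sign(series: pd.Series) -> int:
        return majority_sign(series.to_numpy())[0]

    summary = pd.DataFrame(
        {
            "mean_log2": grouped.mean(),
            "n_replicates": grouped.size().astype(int),
            "sign_agreement": grouped.apply(agreement),
            "majority_sign": grouped.apply(sign).astype(int),
        }
    )
    summary.attrs["log2_interpretation"] = "log2(percent-of-untreated / 100)"
    return summary
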