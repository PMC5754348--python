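"""Plate-reader normalization to relative promoter units (RPU).

Raw wells carry OD600 and YFP fluorescence at 2 h and 4 h after induction.
Per-OD fluorescence gain is

    Fluo = (fluorescence_4h − fluorescence_2h) / OD600,

and promoter strength is standardized against on-plate reference wells:

    RPU_test = Fluo_test × RPU_reference / Fluo_reference.

RPU is therefore invariant under global instrument-gain changes, and the
reference standard's RPU equals its assigned value by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REFERENCE_ID = "reference"
BLANK_ID = "blank"

PLATE_COLUMNS = [
    "plate", "well", "promoter", "condition", "replicate",
    "od600_4h", "fluor_2h", "fluor_4h",
]


class AssayError(ValueError):
    """Invalid plate measurement or missing reference wells."""


@dataclass(frozen=True)
class PlateMeasurement:
    """One raw well."""

    well: str
    promoter: str  # variant id, or "reference" / "blank"
    condition: str
    replicate: int
    od600_4h: float
    fluor_2h: float
    fluor_4h: float
    plate: str = "plate1"

    def __post_init__(self) -> None:
        if self.od600_4h <= 0 and self.promoter != BLANK_ID:
            raise AssayError(f"well {self.well}: od600_4h must be > 0")
        if self.fluor_2h < 0 or self.fluor_4h < 0:
            raise AssayError(f"well {self.well}: fluorescence must be >= 0")


@dataclass(frozen=True)
class RPUResult:
    """Normalized strength of one promoter under one condition."""

    promoter: str
    condition: str
    fluo: float  # mean per-OD fluorescence gain over replicates
    rpu: float  # mean RPU over replicates
    rpu_sd: float
    n: int


def compute_fluo(m: PlateMeasurement) -> float:
    """Per-OD fluorescence gain (fluor_4h − fluor_2h) / od600_4h.

    The 4 h OD reading is used. Negative values (possible for blanks) are
    passed through.
    """
    if m.od600_4h <= 0:
        raise AssayError(f"well {m.well}: od600_4h must be > 0")
    return (m.fluor_4h - m.fluor_2h) / m.od600_4h


def compute_rpu(fluo_test: float, fluo_ref: float, rpu_ref: float = 1.0) -> float:
    """Standardize a per-OD gain against the reference standard."""
    if fluo_ref <= 0:
        raise AssayError("reference per-OD fluorescence must be > 0 (reference failed)")
    return fluo_test * rpu_ref / fluo_ref


def measurements_to_frame(measurements: Iterable[PlateMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate": m.plate, "well": m.well, "promoter": m.promoter,
                "condition": m.condition, "replicate": m.replicate,
                "od600_4h": m.od600_4h, "fluor_2h": m.fluor_2h,
                "fluor_4h": m.fluor_4h,
            }
            for m in measurements
        ],
        columns=PLATE_COLUMNS,
    )


def _as_frame(
    measurements: Iterable[PlateMeasurement] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        missing = set(PLATE_COLUMNS) - set(measurements.columns)
        if missing:
            raise AssayError(f"plate table missing columns: {sorted(missing)}")
        return measurements.copy()
    return measurements_to_frame(measurements)


def rpu_per_well(
    measurements: Iterable[PlateMeasurement] | pd.DataFrame,
    rpu_ref: float = 1.0,
    subtract_blank: bool = False,
) -> pd.DataFrame:
    """Replicate-level RPU for every non-reference, non-blank well.

    Each plate's reference wells are averaged into that plate's Fluo_ref.
    Optional blank subtraction removes the plate-mean blank gain from every
    well before normalization (off by default).
    """
    df = _as_frame(measurements)
    df["fluo"] = (df["fluor_4h"] - df["fluor_2h"]) / df["od600_4h"]
    out_frames = []
    for plate, grp in df.groupby("plate", sort=False):
        ref = grp[grp["promoter"] == REFERENCE_ID]
        if ref.empty:
            raise AssayError(f"plate {plate!r} has no reference wells")
        if subtract_blank:
            blanks = grp[grp["promoter"] == BLANK_ID]
            offset = blanks["fluo"].mean() if not blanks.empty else 0.0
            grp = grp.assign(fluo=grp["fluo"] - offset)
            ref = grp[grp["promoter"] == REFERENCE_ID]
        fluo_ref = float(ref["fluo"].mean())
        if fluo_ref <= 0:
            raise AssayError(f"plate {plate!r}: reference Fluo <= 0")
        test = grp[grp["promoter"] != BLANK_ID].copy()
        test["rpu"] = test["fluo"] * rpu_ref / fluo_ref
        out_frames.append(test)
    return pd.concat(out_frames, ignore_index=True)


def normalize_plate(
    measurements: Iterable[PlateMeasurement] | pd.DataFrame,
    rpu_ref: float = 1.0,
    subtract_blank: bool = False,
) -> list[RPUResult]:
    """Full normalization: per-plate reference scaling, then replicate
    aggregation to mean ± sd per (promoter, condition)."""
    per_well = rpu_per_well(measurements, rpu_ref=rpu_ref,
                            subtract_blank=subtract_blank)
    results: list[RPUResult] = []
    grouped = per_well.groupby(["promoter", "condition"], sort=True)
    for (promoter, condition), grp in grouped:
        rpus = grp["rpu"].to_numpy(dtype=float)
        results.append(
            RPUResult(
                promoter=str(promoter),
                condition=str(condition),
                fluo=float(grp["fluo"].mean()),
                rpu=float(rpus.mean()),
                rpu_sd=float(rpus.std(ddof=1)) if len(rpus) > 1 else 0.0,
                n=len(rpus),
            )
        )
    return results


def results_to_frame(results: Sequence[RPUResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"promoter": r.promoter, "condition": r.condition, "fluo": r.fluo,
             "rpu": r.rpu, "rpu_sd": r.rpu_sd, "n": r.n}
            for r in results
        ],
        columns=["promoter", "condition", "fluo", "rpu", "rpu_sd", "n"],
    )
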