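"""Logic-gate evaluation of multi-input hybrid promoters.

A promoter carrying one activator operator plus one or two repressor
operators behaves as an AND gate over its cognate ligands: σ70 occupancy
is high only when the activator is liganded AND every repressor is
de-repressed. This module enumerates truth tables, scores AND behaviour
(min-ON over max-OFF on replicate means), classifies leak/signal
phenotypes, and ranks −35 × −10 combinations for gate construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .thermo_model import InducerCondition, fold_change, transcription_rate

#: Working inducer concentrations of the standard assay (units per ligand:
#: mM for arabinose/xylose/IPTG, µM for the HSLs, ng/mL for aTc).
WORKING_CONCENTRATIONS: Mapping[str, float] = {
    "arabinose": 5.0,
    "xylose": 5.0,
    "C4-HSL": 10.0,
    "3O-C6-HSL": 0.1,
    "3O-C12-HSL": 0.1,
    "IPTG": 1.0,
    "aTc": 100.0,
}

#: Default score for a "well-behaved" AND gate (ON at least 10× any OFF state).
DEFAULT_MIN_SCORE = 10.0


class GateError(ValueError):
    """Invalid truth table or gate configuration."""


@dataclass(frozen=True)
class TruthTableRow:
    state: tuple[int, ...]  # 0/1 per input ligand
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TruthTable:
    """Complete 2^k panel of rates for one promoter."""

    inputs: tuple[str, ...]
    rows: tuple[TruthTableRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rows", tuple(self.rows))
        states = [r.state for r in self.rows]
        if len(set(states)) != len(states):
            raise GateError("duplicate truth-table states")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {**{l: s for l, s in zip(self.inputs, r.state)},
                 "mean": r.mean, "sd": r.sd, "n": r.n}
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class GateMetrics:
    on_rate: float  # all-inducers-present state
    max_off_rate: float  # worst leak over the other states
    and_score: float  # on_rate / max_off_rate

    @property
    def leakiness(self) -> float:
        return self.max_off_rate

    @property
    def signal(self) -> float:
        return self.on_rate

    @property
    def dynamic_range(self) -> float:
        return self.on_rate - self.max_off_rate


@dataclass(frozen=True)
class PhenotypeClass:
    """Quadrant of the (leak, signal) plane; strictly-below = low."""

    label: str  # e.g. "low-leak/high-signal"
    leak_threshold: float
    signal_threshold: float


def enumerate_conditions(
    inputs: Sequence[str],
    working_concentrations: Mapping[str, float] | None = None,
) -> list[InducerCondition]:
    """All 2^k on/off ligand combinations in canonical binary order
    (all-off first, all-on last; first input is the most significant bit)."""
    working = dict(
        WORKING_CONCENTRATIONS if working_concentrations is None
        else working_concentrations
    )
    missing = [l for l in inputs if l not in working]
    if missing:
        raise GateError(f"no working concentration for: {missing}")
    for l in inputs:
        if working[l] <= 0:
            raise GateError(f"working concentration for {l!r} must be > 0")
    out = []
    for bits in itertools.product((0, 1), repeat=len(inputs)):
        out.append(
            InducerCondition(
                {l: working[l] * b for l, b in zip(inputs, bits) if b}
            )
        )
    return out


def condition_state(
    inputs: Sequence[str], condition: InducerCondition
) -> tuple[int, ...]:
    """0/1 vector of which input ligands are present in a condition."""
    return tuple(int(condition[l] > 0) for l in inputs)


def truth_table_from_rates(
    inputs: Sequence[str],
    rates: pd.DataFrame,
    condition_states: Mapping[str, tuple[int, ...]] | None = None,
) -> TruthTable:
    """Build a truth table from a rate table with columns
    ``condition``, ``rate`` (replicate rows are aggregated).

    By default the condition id itself is parsed as a 0/1 string (the
    synthetic gate datasets name conditions this way); pass
    ``condition_states`` to map arbitrary ids.
    """
    if condition_states is None:
        condition_states = {
            c: tuple(int(ch) for ch in str(c)) for c in rates["condition"].unique()
        }
    rows = []
    for cond, grp in rates.groupby("condition", sort=True):
        vals = grp["rate"].to_numpy(dtype=float)
        state = condition_states[cond]
        if len(state) != len(inputs):
            raise GateError(
                f"state {state} of condition {cond!r} does not match "
                f"{len(inputs)} inputs"
            )
        rows.append(
            TruthTableRow(
                state=tuple(state),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                n=len(vals),
            )
        )
    rows.sort(key=lambda r: r.state)
    return TruthTable(inputs=tuple(inputs), rows=tuple(rows))


def gate_metrics(table: TruthTable) -> GateMetrics:
    """ON rate, worst OFF leak, and their ratio, from replicate means."""
    k = len(table.inputs)
    expected = set(itertools.product((0, 1), repeat=k))
    present = {r.state for r in table.rows}
    missing = sorted(expected - present)
    if missing:
        raise GateError(f"incomplete truth table; missing states: {missing}")
    by_state = {r.state: r.mean for r in table.rows}
    on_state = (1,) * k
    on_rate = by_state[on_state]
    off_rates = [m for s, m in by_state.items() if s != on_state]
    max_off = max(off_rates) if off_rates else 0.0
    score = on_rate / max_off if max_off > 0 else float("inf")
    return GateMetrics(on_rate=on_rate, max_off_rate=max_off, and_score=score)


def is_well_behaved_and(
    metrics: GateMetrics, min_score: float = DEFAULT_MIN_SCORE
) -> bool:
    """True iff the gate is active only with all inducers present,
    operationalised as and_score ≥ min_score (boundary inclusive)."""
    if min_score <= 1:
        raise GateError("min_score must be > 1")
    return metrics.and_score >= min_score


def classify_phenotype(
    leak: float,
    signal: float,
    leak_threshold: float,
    signal_threshold: float,
) -> PhenotypeClass:
    """Quadrant label of the (leak, signal) plane.

    Strictly below a threshold counts as "low", so every point maps to
    exactly one of the four labels (bD-like low/low, dE/dF-like low/high,
    eG-like high/high, and the residual high/low quadrant).
    """
    if leak_threshold <= 0 or signal_threshold <= 0:
        raise GateError("thresholds must be > 0")
    leak_part = "low-leak" if leak < leak_threshold else "high-leak"
    signal_part = "low-signal" if signal < signal_threshold else "high-signal"
    return PhenotypeClass(
        label=f"{leak_part}/{signal_part}",
        leak_threshold=leak_threshold,
        signal_threshold=signal_threshold,
    )


def geometric_thresholds(
    leaks: Sequence[float], signals: Sequence[float]
) -> tuple[float, float]:
    """Default phenotype thresholds: geometric midpoints of the observed
    leak and signal distributions."""
    leaks = np.asarray(leaks, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if (leaks <= 0).any() or (signals <= 0).any():
        raise GateError("geometric thresholds need positive leak/signal values")
    return (
        float(np.exp((np.log(leaks.min()) + np.log(leaks.max())) / 2.0)),
        float(np.exp((np.log(signals.min()) + np.log(signals.max())) / 2.0)),
    )


_OBJECTIVES = ("dynamic_range", "fold_change", "and_score")


def rank_combinations(
    fit: FitResult,
    off: InducerCondition,
    on: InducerCondition,
    objective: str = "dynamic_range",
) -> pd.DataFrame:
    """Rank every fitted −35 × −10 combination for gate construction.

    Scores are model predictions at the OFF/ON conditions. ``and_score``
    here is the two-state ratio ON/OFF (for multi-input tables use
    :func:`gate_metrics` on a full truth table). Descending by objective;
    ties broken by fold change, then lexicographic label.
    """
    if objective not in _OBJECTIVES:
        raise GateError(f"unknown objective {objective!r}; one of {_OBJECTIVES}")
    rows = []
    for m35 in sorted(fit.dg35):
        for m10 in sorted(fit.dg10):
            params = fit.params_for(m35, m10)
            r_off = transcription_rate(params, off)
            r_on = transcription_rate(params, on)
            fc = fold_change(params, off, on)
            score = {
                "dynamic_range": r_on - r_off,
                "fold_change": fc,
                "and_score": fc,
            }[objective]
            rows.append(
                {"minus35": m35, "minus10": m10, "ln_keq": fit.ln_keq(m35, m10),
                 "r_off": r_off, "r_on": r_on, "fold_change": fc, "score": score}
            )
    df = pd.DataFrame(rows)
    df["_label"] = df["minus35"] + df["minus10"]
    df = df.sort_values(
        by=["score", "fold_change", "_label"], ascending=[False, False, True]
    ).drop(columns="_label").reset_index(drop=True)
    return df
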