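"""Least-squares fitting of binding free energies to measured rates.

The model is fitted on log rates: minimise Σ (ln r_obs − ln r_pred)² over
per-site energies (one ΔG per −35 label, one per −10 label, combined
additively into ln K_eq = −(ΔG−35 + ΔG−10)) and shared global parameters
(α, background, ω, one binding weight per regulator). Sharing the globals
across the library is what encodes the additivity assumption: every
variant differs only through its two site energies.

The additive energies carry a gauge freedom — shifting every −35 energy by
+δ and every −10 energy by −δ changes nothing observable — so fits pin
anchor sites (by default the consensus-like "a" and "A") to ΔG = 0, making
all energies relative. :func:`apply_gauge` re-imposes the anchor
convention on any result without touching the ln K_eq values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .thermo_model import (
    ACTIVATOR,
    InducerCondition,
    RegulatorSpec,
    SiteEnergies,
    ThermoParams,
    active_fraction,
    transcription_rate,
)

OBSERVATION_COLUMNS = [
    "variant", "minus35", "minus10", "condition", "replicate", "rate_rpu",
]


class FitError(ValueError):
    """Invalid observation table or fit configuration."""


@dataclass(frozen=True)
class FitConfig:
    """What is fitted, how, and against which conditions.

    ``conditions`` maps each condition id appearing in the observation
    table to its ligand concentrations. Regulator Hill exponents and
    half-maximal concentrations are held fixed at the values given in
    ``regulators``; their binding weights are fitted when listed in
    ``free_globals``.
    """

    conditions: Mapping[str, InducerCondition]
    regulators: tuple[RegulatorSpec, ...] = ()
    anchor35: str = "a"
    anchor10: str = "A"
    free_globals: tuple[str, ...] = ("alpha", "background", "omega", "K")
    fit_energies: bool = True
    fixed_dg35: Mapping[str, float] = field(default_factory=dict)
    fixed_dg10: Mapping[str, float] = field(default_factory=dict)
    alpha0: float = 1e5
    background0: float = 10.0
    omega0: float = 100.0
    multistart: int = 8
    seed: int = 0
    xtol: float = 1e-10
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", dict(self.conditions))
        object.__setattr__(self, "regulators", tuple(self.regulators))
        object.__setattr__(self, "fixed_dg35", dict(self.fixed_dg35))
        object.__setattr__(self, "fixed_dg10", dict(self.fixed_dg10))
        unknown = set(self.free_globals) - {"alpha", "background", "omega", "K"}
        if unknown:
            raise FitError(f"unknown free_globals entries: {sorted(unknown)}")
        if self.multistart < 1:
            raise FitError("multistart must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Recovered site energies plus shared global parameters.

    Energies are gauge-fixed (anchors at 0); ln K_eq of any combination is
    reconstructed exactly as −(ΔG−35 + ΔG−10).
    """

    dg35: Mapping[str, float]
    dg10: Mapping[str, float]
    alpha: float
    background: float
    omega: float
    reg_weights: Mapping[str, float]  # regulator name -> fitted K
    regulators: tuple[RegulatorSpec, ...]
    loss: float
    converged: bool
    n_starts: int
    anchor35: str
    anchor10: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "dg35", dict(self.dg35))
        object.__setattr__(self, "dg10", dict(self.dg10))
        object.__setattr__(self, "reg_weights", dict(self.reg_weights))

    def ln_keq(self, m35: str, m10: str) -> float:
        return -(self.dg35[m35] + self.dg10[m10])

    def ln_keq_table(self) -> pd.DataFrame:
        """ln K_eq of every combination, −35 labels as rows, −10 as columns."""
        rows = sorted(self.dg35)
        cols = sorted(self.dg10)
        data = [[self.ln_keq(r, c) for c in cols] for r in rows]
        return pd.DataFrame(data, index=rows, columns=cols)

    def params_for(self, m35: str, m10: str) -> ThermoParams:
        regs = tuple(
            replace(r, binding_weight=self.reg_weights[r.name])
            for r in self.regulators
        )
        return ThermoParams(
            site_energies=SiteEnergies(
                dG_minus10=self.dg10[m10], dG_minus35=self.dg35[m35]
            ),
            alpha=self.alpha,
            background=self.background,
            omega=self.omega,
            regulators=regs,
        )

    def energy_table(self) -> pd.DataFrame:
        rows = [
            {"family": "minus35", "label": k, "dG": v}
            for k, v in sorted(self.dg35.items())
        ] + [
            {"family": "minus10", "label": k, "dG": v}
            for k, v in sorted(self.dg10.items())
        ]
        return pd.DataFrame(rows, columns=["family", "label", "dG"])

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "dg35": dict(sorted(self.dg35.items())),
            "dg10": dict(sorted(self.dg10.items())),
            "alpha": self.alpha,
            "background": self.background,
            "omega": self.omega,
            "reg_weights": dict(sorted(self.reg_weights.items())),
            "loss": self.loss,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def observations_from_plate(per_well_rpu: pd.DataFrame) -> pd.DataFrame:
    """Convert replicate-level RPU wells into an observation table.

    Input is the output of :func:`promtune.plate_assay.rpu_per_well`;
    reference wells are dropped and variant ids are parsed into their
    −35/−10 labels.
    """
    from .plate_assay import REFERENCE_ID
    from .promoter_library import parse_variant_id

    rows = []
    for r in per_well_rpu.itertuples():
        if r.promoter == REFERENCE_ID:
            continue
        _, m35, m10 = parse_variant_id(str(r.promoter))
        rows.append(
            {
                "variant": r.promoter, "minus35": m35, "minus10": m10,
                "condition": r.condition, "replicate": r.replicate,
                "rate_rpu": r.rpu,
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def validate_observations(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(OBSERVATION_COLUMNS) - set(table.columns)
    if missing:
        raise FitError(f"observation table missing columns: {sorted(missing)}")
    return table


def floor_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Floor non-positive rates at half the smallest positive rate so logs
    are defined (plate noise can push near-background wells below zero)."""
    table = validate_observations(table).copy()
    rates = table["rate_rpu"].to_numpy(dtype=float)
    positive = rates[rates > 0]
    if positive.size == 0:
        raise FitError("observation table has no positive rates")
    table["rate_rpu"] = np.maximum(rates, positive.min() / 2.0)
    return table


def log_rate_loss(
    params_by_variant: Mapping[str, ThermoParams],
    table: pd.DataFrame,
    conditions: Mapping[str, InducerCondition],
) -> float:
    """Σ over rows of (ln r_obs − ln r_pred)²."""
    table = validate_observations(table)
    total = 0.0
    for row in table.itertuples():
        r_obs = float(row.rate_rpu)
        if r_obs <= 0:
            raise FitError(
                f"non-positive observed rate for {row.variant!r}; floor the table "
                "with floor_rates() first"
            )
        params = params_by_variant[row.variant]
        r_pred = transcription_rate(params, conditions[row.condition])
        total += (math.log(r_obs) - math.log(r_pred)) ** 2
    return total


# ---------------------------------------------------------------------------
# Vectorised model evaluation for the optimiser
# ---------------------------------------------------------------------------

class _Problem:
    """Precomputed design: rows indexed into site labels and conditions."""

    def __init__(self, table: pd.DataFrame, config: FitConfig):
        table = validate_observations(table)
        if (table["rate_rpu"] <= 0).any():
            raise FitError("non-positive rates; apply floor_rates() first")
        self.config = config
        self.labels35 = sorted(table["minus35"].unique())
        self.labels10 = sorted(table["minus10"].unique())
        if config.fit_energies:
            if config.anchor35 not in self.labels35:
                raise FitError(f"anchor −35 label {config.anchor35!r} not in table")
            if config.anchor10 not in self.labels10:
                raise FitError(f"anchor −10 label {config.anchor10!r} not in table")
        unknown_cond = set(table["condition"].unique()) - set(config.conditions)
        if unknown_cond:
            raise FitError(f"conditions without ligand maps: {sorted(unknown_cond)}")

        self.cond_ids = sorted(table["condition"].unique())
        i35 = {l: i for i, l in enumerate(self.labels35)}
        i10 = {l: i for i, l in enumerate(self.labels10)}
        icond = {c: i for i, c in enumerate(self.cond_ids)}
        self.row35 = table["minus35"].map(i35).to_numpy()
        self.row10 = table["minus10"].map(i10).to_numpy()
        self.rowc = table["condition"].map(icond).to_numpy()
        self.log_obs = np.log(table["rate_rpu"].to_numpy(dtype=float))

        # condition-resolved active fractions (fixed during the fit)
        self.activator = next(
            (r for r in config.regulators if r.mode == ACTIVATOR), None
        )
        self.repressors = tuple(r for r in config.regulators if r.mode != ACTIVATOR)
        conds = [config.conditions[c] for c in self.cond_ids]
        self.a_act = (
            np.array([active_fraction(self.activator, c) for c in conds])
            if self.activator is not None
            else np.zeros(len(conds))
        )
        self.a_rep = np.array(
            [[active_fraction(r, c) for c in conds] for r in self.repressors]
        )  # shape (n_rep, n_cond)

        # free-parameter layout
        if config.fit_energies:
            self.free35 = [l for l in self.labels35 if l != config.anchor35]
            self.free10 = [l for l in self.labels10 if l != config.anchor10]
        else:
            self.free35 = []
            self.free10 = []
        self.fit_alpha = "alpha" in config.free_globals
        self.fit_background = "background" in config.free_globals
        self.fit_omega = "omega" in config.free_globals and self.activator is not None
        self.fit_K = "K" in config.free_globals
        self.n_free = (
            len(self.free35)
            + len(self.free10)
            + self.fit_alpha
            + self.fit_background
            + self.fit_omega
            + (len(config.regulators) if self.fit_K else 0)
        )

    def default_start(self) -> np.ndarray:
        """Data-driven initial point.

        α and background start at the observed rate extremes; site
        energies start from an additive decomposition of ln K_eq values
        implied by inverting the occupancy in the least-induced condition;
        ω starts at the largest observed induction ratio. Starting near
        the data scale keeps the local optimizer out of the no-induction
        (K_A → 0) local minimum.
        """
        cfg = self.config
        rates = np.exp(self.log_obs)
        bg0 = max(rates.min() * 0.5, 1e-12)
        alpha0 = max(rates.max() - bg0, 10 * bg0)

        e35 = {l: 0.0 for l in self.free35}
        e10 = {l: 0.0 for l in self.free10}
        if self.free35 or self.free10:
            # least-active condition: smallest activator activity
            c_off = int(np.argmin(self.a_act))
            mask = self.rowc == c_off
            p = np.clip((rates[mask] - bg0) / alpha0, 1e-6, 1.0 - 1e-6)
            s = -np.log(p / (1.0 - p))  # implied dG35 + dG10 per row
            # additive decomposition, anchors pinned at 0
            cols35 = {l: k for k, l in enumerate(self.free35)}
            cols10 = {l: k + len(cols35) for k, l in enumerate(self.free10)}
            design = np.zeros((mask.sum(), len(cols35) + len(cols10)))
            for r, (i35, i10) in enumerate(zip(self.row35[mask], self.row10[mask])):
                l35, l10 = self.labels35[i35], self.labels10[i10]
                if l35 in cols35:
                    design[r, cols35[l35]] = 1.0
                if l10 in cols10:
                    design[r, cols10[l10]] = 1.0
            coef, *_ = np.linalg.lstsq(design, s, rcond=None)
            for l, k in cols35.items():
                e35[l] = float(coef[k])
            for l, k in cols10.items():
                e10[l] = float(coef[k])

        x = [e35[l] for l in self.free35] + [e10[l] for l in self.free10]
        if self.fit_alpha:
            x.append(math.log(alpha0))
        if self.fit_background:
            x.append(math.log(bg0))
        if self.fit_omega:
            # largest mean induction ratio across conditions as ω guess
            c_off = int(np.argmin(self.a_act))
            c_on = int(np.argmax(self.a_act))
            r_off = rates[self.rowc == c_off]
            r_on = rates[self.rowc == c_on]
            omega0 = float(np.clip(r_on.max() / max(r_off.min(), 1e-12), 1.0, 1e6))
            x.append(math.log(omega0))
        if self.fit_K:
            x.extend(math.log(max(r.binding_weight, 1e-6)) for r in cfg.regulators)
        return np.asarray(x, dtype=float)

    @staticmethod
    def _exp(v: float) -> float:
        # positivity transform, clipped so optimizer trial steps cannot overflow
        return math.exp(min(float(v), 60.0))

    def unpack(self, x: np.ndarray) -> dict:
        cfg = self.config
        n35, n10 = len(self.free35), len(self.free10)
        if cfg.fit_energies:
            dg35 = dict(zip(self.free35, (float(v) for v in x[:n35])))
            dg35[cfg.anchor35] = 0.0
            dg10 = dict(zip(self.free10, (float(v) for v in x[n35 : n35 + n10])))
            dg10[cfg.anchor10] = 0.0
        else:
            dg35 = {l: cfg.fixed_dg35.get(l, 0.0) for l in self.labels35}
            dg10 = {l: cfg.fixed_dg10.get(l, 0.0) for l in self.labels10}
        i = n35 + n10
        alpha = self._exp(x[i]) if self.fit_alpha else cfg.alpha0
        i += self.fit_alpha
        background = self._exp(x[i]) if self.fit_background else cfg.background0
        i += self.fit_background
        omega = self._exp(x[i]) if self.fit_omega else cfg.omega0
        i += self.fit_omega
        if self.fit_K:
            weights = {
                r.name: self._exp(x[i + j]) for j, r in enumerate(cfg.regulators)
            }
        else:
            weights = {r.name: r.binding_weight for r in cfg.regulators}
        return {
            "dg35": dg35, "dg10": dg10, "alpha": alpha,
            "background": background, "omega": omega, "weights": weights,
        }

    def predict_log_rates(self, x: np.ndarray) -> np.ndarray:
        p = self.unpack(x)
        e35 = np.array([p["dg35"][l] for l in self.labels35])
        e10 = np.array([p["dg10"][l] for l in self.labels10])
        ln_keq = -(e35[self.row35] + e10[self.row10])  # per row
        keq = np.exp(np.clip(ln_keq, -60.0, 60.0))  # occupancy saturates anyway
        if self.activator is not None:
            q_a = p["weights"][self.activator.name] * self.a_act[self.rowc]
        else:
            q_a = np.zeros(len(self.rowc))
        free = 1.0 + q_a
        for j, r in enumerate(self.repressors):
            free = free * (1.0 + p["weights"][r.name] * self.a_rep[j, self.rowc])
        sigma_w = keq * (1.0 + q_a * p["omega"])
        rate = p["alpha"] * sigma_w / (free + sigma_w) + p["background"]
        return np.log(rate)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.predict_log_rates(x) - self.log_obs


def fit_model(table: pd.DataFrame, config: FitConfig) -> FitResult:
    """Fit site energies and globals by multistart least squares on log rates.

    Deterministic for a given config seed. Requires at least two −35 and
    two −10 labels so both energy families are identifiable. On total
    non-convergence the best point found is returned with
    ``converged=False`` rather than raising.
    """
    table = validate_observations(table)
    if table["minus35"].nunique() < 2 or table["minus10"].nunique() < 2:
        raise FitError(
            "need >= 2 distinct −35 and −10 sites for identifiability"
        )
    prob = _Problem(table, config)
    rng = np.random.default_rng(config.seed)
    base = prob.default_start()

    best_x: np.ndarray | None = None
    best_cost = math.inf
    any_converged = False
    for start_idx in range(config.multistart):
        x0 = base.copy()
        if start_idx > 0:  # wide seeded perturbation around the default start
            x0 = x0 + rng.normal(scale=2.0, size=x0.shape)
        sol = least_squares(
            prob.residuals, x0, method="lm" if prob.n_free <= prob.log_obs.size
            else "trf", xtol=config.xtol, max_nfev=config.max_nfev,
        )
        cost = 2.0 * sol.cost  # least_squares cost is half the SSE
        if cost < best_cost:
            best_cost, best_x = cost, sol.x
        any_converged = any_converged or bool(sol.success)

    assert best_x is not None
    p = prob.unpack(best_x)
    return FitResult(
        dg35=p["dg35"],
        dg10=p["dg10"],
        alpha=p["alpha"],
        background=p["background"],
        omega=p["omega"],
        reg_weights=p["weights"],
        regulators=config.regulators,
        loss=float(best_cost),
        converged=any_converged,
        n_starts=config.multistart,
        anchor35=config.anchor35,
        anchor10=config.anchor10,
    )


def apply_gauge(result: FitResult, config: FitConfig | None = None) -> FitResult:
    """Re-impose the anchor convention by the one-parameter gauge shift.

    The additive degeneracy is one-dimensional (ΔG−35 → ΔG−35 + δ,
    ΔG−10 → ΔG−10 − δ), so the shift is chosen to zero the −35 anchor;
    the −10 anchor then returns to zero for any result produced by
    :func:`fit_model` that was subsequently shifted. Every ln K_eq is
    unchanged. Idempotent.
    """
    anchor35 = config.anchor35 if config is not None else result.anchor35
    anchor10 = config.anchor10 if config is not None else result.anchor10
    if anchor35 not in result.dg35:
        raise FitError(f"anchor −35 label {anchor35!r} absent from result")
    if anchor10 not in result.dg10:
        raise FitError(f"anchor −10 label {anchor10!r} absent from result")
    delta = result.dg35[anchor35]
    return replace(
        result,
        dg35={k: v - delta for k, v in result.dg35.items()},
        dg10={k: v + delta for k, v in result.dg10.items()},
        anchor35=anchor35,
        anchor10=anchor10,
    )


def predict_heatmaps(
    result: FitResult, conditions: Sequence[tuple[str, InducerCondition]]
) -> dict[str, pd.DataFrame]:
    """Predicted rate matrix per condition plus a fold-change matrix.

    Matrices are indexed (−35 label rows, −10 label columns) in the same
    alphabetical order as library assembly. The fold-change matrix divides
    the last condition (ON) by the first (OFF).
    """
    if not conditions:
        raise FitError("need at least one condition")
    rows = sorted(result.dg35)
    cols = sorted(result.dg10)
    out: dict[str, pd.DataFrame] = {}
    for cond_id, cond in conditions:
        data = [
            [transcription_rate(result.params_for(r, c), cond) for c in cols]
            for r in rows
        ]
        out[cond_id] = pd.DataFrame(data, index=rows, columns=cols)
    first = conditions[0][0]
    last = conditions[-1][0]
    out["fold_change"] = out[last] / out[first]
    return out
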