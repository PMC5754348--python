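"""Statistical-mechanics (occupancy) model of σ70 transcription initiation.

The promoter is treated as a set of binding sites in thermodynamic
equilibrium. σ70 (carrying RNA polymerase) binds the −10/−35 hexamers with
relative equilibrium constant

    K_eq = exp(−(ΔG−10 + ΔG−35)),   energies in k_BT, natural logs,

so stronger (more consensus-like) hexamers mean lower ΔG and higher K_eq.
A ligand-inducible activator bound at its proximal operator recruits σ70
through a cooperativity factor ω ≥ 1; a repressor bound in the spacer (or
at +1) sterically excludes σ70. Ligands set the active fraction of each
regulator through a Hill function. The transcription rate is proportional
to the equilibrium probability that σ70 is bound:

    rate = α · P(σ bound) + b,

with α the maximal rate (in relative promoter units, RPU) and b an additive
background (autofluorescence plus reporter leak). The background makes the
fold change approach 1 in both K_eq limits: very weak promoters never rise
above background, saturated promoters are already maximal without inducer —
only intermediate K_eq gives a large dynamic range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ACTIVATOR = "activator"
REPRESSOR = "repressor"


class ModelError(ValueError):
    """Invalid model parameters or unsupported regulatory architecture."""


@dataclass(frozen=True)
class SiteEnergies:
    """Free energies of σ70 binding to the two hexamers, in k_BT."""

    dG_minus10: float
    dG_minus35: float

    @property
    def ln_keq(self) -> float:
        return -(self.dG_minus10 + self.dG_minus35)

    @property
    def keq(self) -> float:
        return math.exp(self.ln_keq)


@dataclass(frozen=True)
class RegulatorSpec:
    """A ligand-responsive transcription factor acting on the promoter.

    ``binding_weight`` is the dimensionless Boltzmann weight of the fully
    active regulator on its operator (K_A for activators, K_R for
    repressors). ``half_conc`` is the ligand concentration at half-maximal
    response (EC50 for activators; for repressors the ligand *deactivates*
    the protein, so it is the concentration of half-derepression).
    """

    name: str
    mode: str  # ACTIVATOR | REPRESSOR
    binding_weight: float
    half_conc: float
    ligand: str
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in (ACTIVATOR, REPRESSOR):
            raise ModelError(f"regulator {self.name!r}: unknown mode {self.mode!r}")
        if self.binding_weight < 0:
            raise ModelError(f"regulator {self.name!r}: binding_weight must be >= 0")
        if self.hill_n <= 0 or self.half_conc <= 0:
            raise ModelError(
                f"regulator {self.name!r}: hill_n and half_conc must be > 0"
            )


@dataclass(frozen=True)
class ThermoParams:
    """All parameters of the occupancy model for one promoter."""

    site_energies: SiteEnergies
    alpha: float = 1e5  # maximal rate scale, RPU
    background: float = 10.0  # basal signal b, RPU
    omega: float = 100.0  # activator–σ70 cooperativity, dimensionless
    regulators: tuple[RegulatorSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ModelError("alpha must be > 0")
        if self.background < 0:
            raise ModelError("background must be >= 0")
        if self.omega < 0:
            raise ModelError("omega must be >= 0")
        object.__setattr__(self, "regulators", tuple(self.regulators))
        n_act = sum(r.mode == ACTIVATOR for r in self.regulators)
        if n_act > 1:
            raise ModelError(
                "at most one activator is supported (proximal-operator model)"
            )

    @property
    def activator(self) -> RegulatorSpec | None:
        for r in self.regulators:
            if r.mode == ACTIVATOR:
                return r
        return None

    @property
    def repressors(self) -> tuple[RegulatorSpec, ...]:
        return tuple(r for r in self.regulators if r.mode == REPRESSOR)

    def with_ln_keq(self, ln_keq: float) -> "ThermoParams":
        """Copy with the combined site energy set to the given ln K_eq
        (split arbitrarily onto the −10 site; only the sum matters)."""
        return replace(self, site_energies=SiteEnergies(-ln_keq, 0.0))


@dataclass(frozen=True)
class InducerCondition:
    """Ligand concentrations defining one induction state.

    Absent ligands are at concentration 0. Units must match each
    regulator's ``half_conc``.
    """

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = dict(self.concentrations)
        for ligand, c in conc.items():
            if c < 0:
                raise ModelError(f"negative concentration for {ligand!r}")
        object.__setattr__(self, "concentrations", conc)

    def __getitem__(self, ligand: str) -> float:
        return self.concentrations.get(ligand, 0.0)

    def with_ligand(self, ligand: str, conc: float) -> "InducerCondition":
        merged = dict(self.concentrations)
        merged[ligand] = conc
        return InducerCondition(merged)


@dataclass(frozen=True)
class BindingState:
    """One microstate: which species occupy the promoter, and its
    Boltzmann weight relative to the empty state (weight 1)."""

    occupants: frozenset[str]
    weight: float


def active_fraction(reg: RegulatorSpec, condition: InducerCondition) -> float:
    """Fraction of the regulator in its DNA-binding form at this condition.

    Activators are activated by ligand, a(c) = c^n / (c^n + h^n); repressors
    are deactivated by ligand, ρ(c) = h^n / (c^n + h^n).
    """
    c = condition[reg.ligand]
    if c < 0:
        raise ModelError(f"negative concentration for {reg.ligand!r}")
    cn = c**reg.hill_n
    hn = reg.half_conc**reg.hill_n
    a = cn / (cn + hn)
    return a if reg.mode == ACTIVATOR else 1.0 - a


def _occupancy_weights(
    params: ThermoParams, condition: InducerCondition
) -> tuple[float, float, list[float]]:
    """(K_eq, q_A, [q_R...]) — condition-resolved Boltzmann weights."""
    keq = params.site_energies.keq
    act = params.activator
    q_a = act.binding_weight * active_fraction(act, condition) if act else 0.0
    q_rs = [
        r.binding_weight * active_fraction(r, condition) for r in params.repressors
    ]
    return keq, q_a, q_rs


def enumerate_states(
    params: ThermoParams, condition: InducerCondition
) -> list[BindingState]:
    """Every allowed microstate of {σ, activator, repressors}.

    All subsets are allowed except those containing σ together with any
    repressor (steric exclusion). Weights: empty = 1; activator contributes
    q_A = a·K_A; repressor j contributes q_Rj = ρj·K_Rj; σ contributes
    K_eq, multiplied by ω when co-occupying with the activator.
    """
    keq, q_a, q_rs = _occupancy_weights(params, condition)
    act = params.activator
    species: list[tuple[str, float]] = []
    if act is not None:
        species.append((act.name, q_a))
    species.extend((r.name, q) for r, q in zip(params.repressors, q_rs))
    rep_names = {r.name for r in params.repressors}

    states: list[BindingState] = []
    for sigma_in in (False, True):
        for k in range(len(species) + 1):
            for combo in itertools.combinations(species, k):
                names = {name for name, _ in combo}
                if sigma_in and names & rep_names:
                    continue  # σ excluded by spacer-bound repressor
                w = 1.0
                for _, q in combo:
                    w *= q
                occ = set(names)
                if sigma_in:
                    w *= keq
                    if act is not None and act.name in names:
                        w *= params.omega
                    occ.add("sigma")
                states.append(BindingState(frozenset(occ), w))
    return states


def p_sigma_bound(params: ThermoParams, condition: InducerCondition) -> float:
    """Equilibrium probability that σ70 occupies the promoter (closed form).

    P = K_eq (1 + q_A ω) / Z,
    Z = (1 + q_A) ∏_j (1 + q_Rj) + K_eq (1 + q_A ω).
    """
    keq, q_a, q_rs = _occupancy_weights(params, condition)
    sigma_weight = keq * (1.0 + q_a * params.omega)
    free = 1.0 + q_a
    for q in q_rs:
        free *= 1.0 + q
    return sigma_weight / (free + sigma_weight)


def transcription_rate(params: ThermoParams, condition: InducerCondition) -> float:
    """rate = α · P(σ bound) + b, in RPU."""
    return params.alpha * p_sigma_bound(params, condition) + params.background


def fold_change(
    params: ThermoParams, off: InducerCondition, on: InducerCondition
) -> float:
    """Induction ratio r(on)/r(off)."""
    r_off = transcription_rate(params, off)
    if r_off == 0.0:
        raise ModelError(
            "fold change undefined: uninduced rate is 0 (set background > 0)"
        )
    return transcription_rate(params, on) / r_off


def dynamic_range(
    params: ThermoParams, off: InducerCondition, on: InducerCondition
) -> float:
    """Absolute ON − OFF rate difference, in RPU."""
    return transcription_rate(params, on) - transcription_rate(params, off)


def dose_response_curve(
    params: ThermoParams,
    ligand: str,
    concentrations: Sequence[float],
    base_condition: InducerCondition | None = None,
) -> list[tuple[float, float]]:
    """Rate as a function of one ligand's concentration (others fixed at
    the base condition, default all-zero)."""
    known = {r.ligand for r in params.regulators}
    if ligand not in known:
        raise ModelError(f"ligand {ligand!r} unknown to any regulator ({sorted(known)})")
    base = base_condition or InducerCondition()
    return [
        (c, transcription_rate(params, base.with_ligand(ligand, c)))
        for c in concentrations
    ]


def sweep_keq(
    params_template: ThermoParams,
    ln_keq_grid: Sequence[float],
    off: InducerCondition,
    on: InducerCondition,
) -> pd.DataFrame:
    """Evaluate OFF/ON rates across a grid of ln K_eq values.

    Reproduces the three-regime picture: low K_eq → low leak, poor
    induction; high K_eq → high leak, saturated; intermediate K_eq →
    maximal dynamic range.
    """
    rows = []
    for ln_keq in ln_keq_grid:
        p = params_template.with_ln_keq(float(ln_keq))
        r_off = transcription_rate(p, off)
        r_on = transcription_rate(p, on)
        rows.append(
            {
                "ln_keq": float(ln_keq),
                "r_off": r_off,
                "r_on": r_on,
                "fold_change": r_on / r_off if r_off > 0 else math.inf,
                "dynamic_range": r_on - r_off,
            }
        )
    return pd.DataFrame(rows, columns=["ln_keq", "r_off", "r_on", "fold_change",
                                       "dynamic_range"])


# Convenience regulator constructors with field-typical defaults ------------

def make_activator(
    name: str = "AraC",
    ligand: str = "arabinose",
    binding_weight: float = 50.0,
    half_conc: float = 0.5,
    hill_n: float = 2.0,
) -> RegulatorSpec:
    return RegulatorSpec(name, ACTIVATOR, binding_weight, half_conc, ligand, hill_n)


def make_repressor(
    name: str = "LacI",
    ligand: str = "IPTG",
    binding_weight: float = 200.0,
    half_conc: float = 0.1,
    hill_n: float = 2.0,
) -> RegulatorSpec:
    return RegulatorSpec(name, REPRESSOR, binding_weight, half_conc, ligand, hill_n)
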