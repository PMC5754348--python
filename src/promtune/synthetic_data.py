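"""Seeded synthetic plate-reader datasets with ground truth.

Emulates the study designs the model is meant to analyse: a combinatorial
−35 × −10 library under one activator (± inducer), the same library with a
spacer repressor (4 conditions), dose–response titrations, and two-/three-
input gate truth-table panels. Each dataset is a list of raw plate wells
(biological triplicates by default, one plate per condition, reference
wells on every plate) plus a :class:`GroundTruth` record of the true
parameters and rates used to generate it.

True rates come from the same :mod:`promtune.thermo_model` code path that
analysis uses, so generator and model cannot drift apart. Measurement
noise is multiplicative lognormal with a configurable coefficient of
variation (plate fluorescence errors scale with signal); the lognormal is
mean-1 so noisy replicates average to the true rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .plate_assay import REFERENCE_ID, PlateMeasurement
from .thermo_model import (
    InducerCondition,
    RegulatorSpec,
    SiteEnergies,
    ThermoParams,
    make_activator,
    make_repressor,
    transcription_rate,
)

#: True site energies of the packaged fixture library, in k_BT. Chosen so
#: the 48 ln K_eq values tile the whole dynamic-range curve (from saturated
#: consensus-like promoters down to near-background ones).
DEFAULT_MINUS35_DG: Mapping[str, float] = {
    "a": 0.0, "b": 0.7, "c": 1.5, "d": 2.3, "e": 3.2, "f": 4.5,
}
DEFAULT_MINUS10_DG: Mapping[str, float] = {
    "A": 0.0, "B": 0.5, "C": 1.0, "D": 1.8, "E": 2.6, "F": 3.5, "G": 4.6, "H": 6.0,
}


class SyntheticError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to simulate one experiment.

    Rates are in RPU; the reference promoter is a constitutive mid-strength
    well simulated at ``reference_rate`` with the same noise model.
    """

    minus35_dg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MINUS35_DG)
    )
    minus10_dg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MINUS10_DG)
    )
    regulators: tuple[RegulatorSpec, ...] = field(
        default_factory=lambda: (make_activator(),)
    )
    alpha: float = 1e5
    background: float = 10.0
    omega: float = 100.0
    conditions: Mapping[str, InducerCondition] = field(
        default_factory=lambda: {
            "uninduced": InducerCondition({}),
            "induced": InducerCondition({"arabinose": 5.0}),
        }
    )
    replicates: int = 3
    noise_cv: float = 0.10
    reference_rate: float = 1.0e4
    activator_prefix: str = "ara"
    od600: float = 0.5
    fluor_2h: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise SyntheticError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise SyntheticError("noise_cv must be >= 0")
        object.__setattr__(self, "minus35_dg", dict(self.minus35_dg))
        object.__setattr__(self, "minus10_dg", dict(self.minus10_dg))
        object.__setattr__(self, "regulators", tuple(self.regulators))
        object.__setattr__(self, "conditions", dict(self.conditions))

    def params_for(self, m35: str, m10: str) -> ThermoParams:
        """True model parameters of variant (m35, m10)."""
        return ThermoParams(
            site_energies=SiteEnergies(
                dG_minus10=self.minus10_dg[m10], dG_minus35=self.minus35_dg[m35]
            ),
            alpha=self.alpha,
            background=self.background,
            omega=self.omega,
            regulators=self.regulators,
        )

    def variant_id(self, m35: str, m10: str) -> str:
        return f"{self.activator_prefix}-{m35}{m10}"


@dataclass(frozen=True)
class GroundTruth:
    """True quantities behind a synthetic dataset."""

    ln_keq: Mapping[str, float]  # variant id -> ln K_eq
    rates: Mapping[tuple[str, str], float]  # (variant id, condition id) -> RPU
    config: SyntheticConfig

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "ln_keq": dict(self.ln_keq),
            "rates": {f"{v}|{c}": r for (v, c), r in self.rates.items()},
            "alpha": self.config.alpha,
            "background": self.config.background,
            "omega": self.config.omega,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _well_name(i: int) -> str:
    return f"{'ABCDEFGH'[(i // 12) % 8]}{i % 12 + 1:02d}"


def _simulate_plate(
    config: SyntheticConfig,
    rng: np.random.Generator,
    plate: str,
    condition_id: str,
    true_rates: Sequence[tuple[str, float]],
) -> list[PlateMeasurement]:
    """One plate: every (variant, replicate) well plus reference wells."""
    rows: list[tuple[str, int, float]] = []
    for variant_id, rate in true_rates:
        for rep in range(1, config.replicates + 1):
            rows.append((variant_id, rep, rate))
    for rep in range(1, config.replicates + 1):
        rows.append((REFERENCE_ID, rep, config.reference_rate))

    noise = _lognormal_factors(rng, config.noise_cv, len(rows))
    wells = []
    for i, ((variant_id, rep, rate), eps) in enumerate(zip(rows, noise)):
        fluo = rate * eps  # implied per-OD gain
        wells.append(
            PlateMeasurement(
                well=_well_name(i),
                promoter=variant_id,
                condition=condition_id,
                replicate=rep,
                od600_4h=config.od600,
                fluor_2h=config.fluor_2h,
                fluor_4h=config.fluor_2h + fluo * config.od600,
                plate=plate,
            )
        )
    return wells


def generate_library_dataset(
    config: SyntheticConfig,
) -> tuple[list[PlateMeasurement], GroundTruth]:
    """Combinatorial library panel: every variant × condition × replicate.

    One plate per condition; deterministic for a given config seed.
    """
    rng = np.random.default_rng(config.seed)
    ln_keq: dict[str, float] = {}
    rates: dict[tuple[str, str], float] = {}
    per_condition: dict[str, list[tuple[str, float]]] = {
        c: [] for c in config.conditions
    }
    for m35 in sorted(config.minus35_dg):
        for m10 in sorted(config.minus10_dg):
            vid = config.variant_id(m35, m10)
            params = config.params_for(m35, m10)
            ln_keq[vid] = params.site_energies.ln_keq
            for cond_id, cond in config.conditions.items():
                r = transcription_rate(params, cond)
                rates[(vid, cond_id)] = r
                per_condition[cond_id].append((vid, r))

    measurements: list[PlateMeasurement] = []
    for k, (cond_id, true_rates) in enumerate(per_condition.items(), start=1):
        measurements.extend(
            _simulate_plate(config, rng, f"plate{k}", cond_id, true_rates)
        )
    return measurements, GroundTruth(ln_keq=ln_keq, rates=rates, config=config)


#: Default titration variants: low, mid and high ln K_eq exemplars.
DOSE_RESPONSE_VARIANTS: tuple[tuple[str, str], ...] = (("b", "D"), ("d", "E"), ("e", "G"))


def generate_dose_response(
    config: SyntheticConfig,
    ligand: str,
    concentrations: Sequence[float],
    variants: Sequence[tuple[str, str]] = DOSE_RESPONSE_VARIANTS,
) -> tuple[list[PlateMeasurement], GroundTruth]:
    """Titration series for selected variants; one plate per concentration.

    Condition ids are ``c=<concentration>``; all other ligands are at 0.
    """
    known = {r.ligand for r in config.regulators}
    if ligand not in known:
        raise SyntheticError(f"ligand {ligand!r} unknown to any regulator")
    for m35, m10 in variants:
        if m35 not in config.minus35_dg or m10 not in config.minus10_dg:
            raise SyntheticError(f"variant ({m35}, {m10}) not in configured library")

    conditions = {
        f"c={float(c):g}": InducerCondition({ligand: float(c)})
        for c in concentrations
    }
    sub = replace(
        config,
        minus35_dg={m: config.minus35_dg[m] for m, _ in variants},
        minus10_dg={m: config.minus10_dg[m] for _, m in variants},
        conditions=conditions,
    )
    # restrict to exactly the requested pairs, not their product
    rng = np.random.default_rng(config.seed)
    ln_keq: dict[str, float] = {}
    rates: dict[tuple[str, str], float] = {}
    per_condition: dict[str, list[tuple[str, float]]] = {c: [] for c in conditions}
    for m35, m10 in variants:
        vid = config.variant_id(m35, m10)
        params = config.params_for(m35, m10)
        ln_keq[vid] = params.site_energies.ln_keq
        for cond_id, cond in conditions.items():
            r = transcription_rate(params, cond)
            rates[(vid, cond_id)] = r
            per_condition[cond_id].append((vid, r))

    measurements: list[PlateMeasurement] = []
    for k, (cond_id, true_rates) in enumerate(per_condition.items(), start=1):
        measurements.extend(
            _simulate_plate(config, rng, f"plate{k}", cond_id, true_rates)
        )
    return measurements, GroundTruth(ln_keq=ln_keq, rates=rates, config=sub)


def gate_config(
    n_inputs: int,
    minus35: str = "d",
    minus10: str = "E",
    seed: int = 0,
    noise_cv: float = 0.10,
) -> SyntheticConfig:
    """Fixture parameters for a 2- or 3-input AND-gate promoter (one
    activator plus 1–2 repressors on a single −35/−10 combination)."""
    if n_inputs == 2:
        regulators = (make_activator(), make_repressor())
    elif n_inputs == 3:
        regulators = (
            make_activator(),
            make_repressor(),
            make_repressor(name="TetR", ligand="aTc", binding_weight=500.0,
                           half_conc=10.0),
        )
    else:
        raise SyntheticError("n_inputs must be 2 or 3")
    return SyntheticConfig(
        minus35_dg={minus35: DEFAULT_MINUS35_DG[minus35]},
        minus10_dg={minus10: DEFAULT_MINUS10_DG[minus10]},
        regulators=regulators,
        conditions={},  # filled by generate_gate_dataset
        seed=seed,
        noise_cv=noise_cv,
    )


def generate_gate_dataset(
    config: SyntheticConfig, n_inputs: int
) -> tuple[list[PlateMeasurement], GroundTruth]:
    """Truth-table-complete panel: all 2^n inducer on/off combinations.

    The config must carry exactly one activator and n_inputs − 1
    repressors; working (ON) concentrations are taken from
    :data:`promtune.gate_analysis.WORKING_CONCENTRATIONS`.
    """
    from .gate_analysis import WORKING_CONCENTRATIONS, enumerate_conditions

    if n_inputs not in (2, 3):
        raise SyntheticError("n_inputs must be 2 or 3")
    activators = [r for r in config.regulators if r.mode == "activator"]
    repressors = [r for r in config.regulators if r.mode == "repressor"]
    if len(activators) != 1 or len(repressors) != n_inputs - 1:
        raise SyntheticError(
            f"{n_inputs}-input gate needs 1 activator + {n_inputs - 1} repressor(s); "
            f"config has {len(activators)} + {len(repressors)}"
        )
    ligands = [activators[0].ligand] + [r.ligand for r in repressors]
    conditions = enumerate_conditions(ligands, WORKING_CONCENTRATIONS)
    cond_map = {
        "".join(str(int(cond[l] > 0)) for l in ligands): cond for cond in conditions
    }
    full = replace(config, conditions=cond_map)
    return generate_library_dataset(full)
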