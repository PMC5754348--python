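import numpy as np
import pytest

import promtune as pt


@pytest.fixture
def activator() -> pt.RegulatorSpec:
    return pt.make_activator()  # AraC-like: K_A=50, EC50=0.5 mM, n=2


@pytest.fixture
def repressor() -> pt.RegulatorSpec:
    return pt.make_repressor()  # LacI-like: K_R=200, half-derepression 0.1 mM


@pytest.fixture
def induced() -> pt.InducerCondition:
    return pt.InducerCondition({"arabinose": 5.0})


@pytest.fixture
def uninduced() -> pt.InducerCondition:
    return pt.InducerCondition({})


@pytest.fixture
def activated_params(activator) -> pt.ThermoParams:
    """Mid-strength activator-only promoter (dE-like energies)."""
    return pt.ThermoParams(
        site_energies=pt.SiteEnergies(dG_minus10=2.6, dG_minus35=2.3),
        regulators=(activator,),
    )


@pytest.fixture
def hybrid_params(activator, repressor) -> pt.ThermoParams:
    """Activator + spacer repressor (the 4-condition hybrid layout)."""
    return pt.ThermoParams(
        site_energies=pt.SiteEnergies(dG_minus10=2.6, dG_minus35=2.3),
        regulators=(activator, repressor),
    )


def random_params(rng: np.random.Generator, n_repressors: int | None = None
                  ) -> tuple[pt.ThermoParams, pt.InducerCondition]:
    """Random but valid model parameters and condition, for oracle checks."""
    if n_repressors is None:
        n_repressors = int(rng.integers(0, 3))
    regs = [
        pt.RegulatorSpec(
            name="Act", mode="activator",
            binding_weight=float(rng.uniform(0, 100)),
            half_conc=float(rng.uniform(0.05, 5.0)),
            ligand="act_ligand", hill_n=float(rng.uniform(0.5, 4.0)),
        )
    ]
    for j in range(n_repressors):
        regs.append(
            pt.RegulatorSpec(
                name=f"Rep{j}", mode="repressor",
                binding_weight=float(rng.uniform(0, 500)),
                half_conc=float(rng.uniform(0.05, 5.0)),
                ligand=f"rep_ligand{j}", hill_n=float(rng.uniform(0.5, 4.0)),
            )
        )
    params = pt.ThermoParams(
        site_energies=pt.SiteEnergies(
            dG_minus10=float(rng.uniform(-5, 8)),
            dG_minus35=float(rng.uniform(-5, 8)),
        ),
        alpha=float(rng.uniform(1e3, 2e5)),
        background=float(rng.uniform(0, 50)),
        omega=float(rng.uniform(1, 500)),
        regulators=tuple(regs),
    )
    conc = {"act_ligand": float(rng.uniform(0, 10))}
    for j in range(n_repressors):
        conc[f"rep_ligand{j}"] = float(rng.uniform(0, 10))
    return params, pt.InducerCondition(conc)


def brute_force_p_sigma(params: pt.ThermoParams,
                        condition: pt.InducerCondition) -> float:
    """Independent oracle: σ-bound probability by explicit state summation."""
    states = pt.enumerate_states(params, condition)
    total = sum(s.weight for s in states)
    sigma = sum(s.weight for s in states if "sigma" in s.occupants)
    return sigma / total
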