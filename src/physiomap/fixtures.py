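"""Generated example models and the numeric oracle that validates tracing.

Three generators emulate the worked examples and provide randomized test
material:

* a toy glycolysis chain (six metabolites, five irreversible mass-action
  reactions, an activating and an inhibiting enzyme modifier) — the
  qualitative topology of the classic pathway, not any published
  parameterization;
* a lumped-parameter cardiovascular ring of elastic compartments, where
  each inter-compartment blood flow is driven by the pressure difference
  over a resistance and each pressure follows volume over compliance;
* seeded random mass-action reaction networks, optionally constrained so
  the derived signed influence graph (depletion off) is acyclic.

Every generator declares its expected counts at generation time, so
readers and inference can be cross-validated against the construction
rather than against hard-coded numbers.

The module also holds a fixed-step 4th-order Runge-Kutta integrator and a
finite-difference sign oracle: perturb one variable's initial value,
integrate, and report the sign of the response of every variable — the
independent ground truth the qualitative tracer is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import expr as ex
from .ingest import (
    Equation,
    IngestedModel,
    ModelVariable,
    ReactionRecord,
    read_equation_model,
    synthesize_mass_balance_odes,
)
from .ontology import BearerLink, CompositeAnnotation

__all__ = [
    "FixtureSpec",
    "Trajectory",
    "make_glycolysis_toy",
    "make_cv_circuit",
    "make_random_network",
    "simulate_ode",
    "numeric_sign_oracle",
]


@dataclass
class FixtureSpec:
    name: str
    parameters: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    time: np.ndarray
    values: dict[str, np.ndarray]

    def at(self, t: float) -> dict[str, float]:
        idx = int(np.argmin(np.abs(self.time - t)))
        return {name: float(series[idx]) for name, series in self.values.items()}


# ---------------------------------------------------------------------------
# glycolysis toy

_GLYCOLYSIS_CHAIN = [
    ("glucose", "chebix:Glucose"),
    ("g6p", "chebix:Glucose6Phosphate"),
    ("f6p", "chebix:Fructose6Phosphate"),
    ("f16bp", "chebix:Fructose16Bisphosphate"),
    ("pep", "chebix:Phosphoenolpyruvate"),
    ("pyruvate", "chebix:Pyruvate"),
]

_GLYCOLYSIS_REACTIONS = [
    # (id, substrate, product, rate constant, law template)
    ("r_hk", "glucose", "g6p", 1.0, "k_hk * glucose"),
    ("r_pgi", "g6p", "f6p", 0.8, "k_pgi * g6p"),
    ("r_pfk", "f6p", "f16bp", 1.2, "k_pfk * f6p * amp"),
    ("r_ald", "f16bp", "pep", 0.9, "k_ald * f16bp"),
    ("r_pk", "pep", "pyruvate", 1.1, "k_pk * pep / (1 + atp)"),
]


def _species_annotation(term: str, compartment: str | None) -> CompositeAnnotation:
    bearer = [BearerLink(term, "none")]
    if compartment:
        bearer.append(BearerLink(compartment, "contained-in"))
    return CompositeAnnotation("opbx:ChemicalAmount", tuple(bearer))


def make_glycolysis_toy() -> tuple[IngestedModel, FixtureSpec]:
    """A six-metabolite glycolysis chain with two enzyme-level modifiers.

    AMP stimulates the phosphofructokinase step (it multiplies the rate
    law, SBO-tagged as a stimulator) and ATP inhibits the pyruvate-kinase
    step (it divides the rate law, tagged as an inhibitor); both are
    clamped boundary pools.  All kinetic laws are mass-action in the
    substrate, so the dependency-network inference path applies alongside
    the explicit reaction tags.
    """
    model = IngestedModel(source_format="sbml", source_uri="fixture:glycolysis-toy")
    model.variables["cytosol"] = ModelVariable(name="cytosol")
    model.nominal_values["cytosol"] = 1.0
    for name, term in _GLYCOLYSIS_CHAIN:
        model.variables[name] = ModelVariable(
            name=name, annotation=_species_annotation(term, "fmax:Cytosol")
        )
    model.nominal_values["glucose"] = 2.0
    for name, _ in _GLYCOLYSIS_CHAIN[1:]:
        model.nominal_values[name] = 1.0
    for name, term, value in (("amp", "chebix:AMP", 0.5), ("atp", "chebix:ATP", 1.5)):
        model.variables[name] = ModelVariable(
            name=name,
            annotation=_species_annotation(term, "fmax:Cytosol"),
            boundary=True,
        )
        model.nominal_values[name] = value

    for rid, substrate, product, k, law in _GLYCOLYSIS_REACTIONS:
        kname = law.split("*")[0].strip()
        model.variables[kname] = ModelVariable(name=kname)
        model.nominal_values[kname] = k
        eq = Equation(
            id=f"eq_{rid}", target=rid, is_derivative=False, rhs=ex.parse_infix(law)
        )
        model.equations.append(eq)
        model.variables[rid] = ModelVariable(
            name=rid,
            annotation=CompositeAnnotation("opbx:ChemicalFlowRate", (), free_label=rid),
            equation_id=eq.id,
        )
        record = ReactionRecord(
            id=rid,
            reactants=[(substrate, 1.0)],
            products=[(product, 1.0)],
            rate_variable=rid,
            reversible=False,
        )
        if rid == "r_pfk":
            record.modifiers.append(("amp", +1))
        if rid == "r_pk":
            record.modifiers.append(("atp", -1))
        model.reactions.append(record)

    synthesize_mass_balance_odes(model)
    model.check_integrity()
    spec = FixtureSpec(
        name="glycolysis-toy",
        expected={
            "species": len(_GLYCOLYSIS_CHAIN) + 2,
            "metabolites": len(_GLYCOLYSIS_CHAIN),
            "reactions": len(_GLYCOLYSIS_REACTIONS),
            "modifiers": 2,
            "flow_processes": len(_GLYCOLYSIS_REACTIONS),
            "modulation_processes": 2,
            "participants": 2 * len(_GLYCOLYSIS_REACTIONS),
            "chain": [name for name, _ in _GLYCOLYSIS_CHAIN],
            "reaction_ids": [r[0] for r in _GLYCOLYSIS_REACTIONS],
        },
    )
    return model, spec


# ---------------------------------------------------------------------------
# cardiovascular ring


def _cv_compartments(n: int) -> list[tuple[str, str]]:
    names = [("LV", "fmax:LeftVentricle"), ("aorta", "fmax:Aorta")]
    for i in range(3, n + 1):
        names.append((f"comp{i}", f"fmax:Compartment{i}"))
    return names[:n]


def make_cv_circuit(n: int = 4) -> tuple[IngestedModel, FixtureSpec]:
    """A closed ring of n elastic compartments exchanging blood.

    Per compartment i: ``V_i' = F_in - F_out``, ``P_i = V_i / C_i``,
    ``F_i_next = (P_i - P_next) / R_i``.  Volumes are annotated as the
    fluid amount of the portion of blood in the compartment, pressures as
    its fluid force, flows as fluid flow rates — so the dependency path
    can recover each flow's source and sink blood pools.  The first two
    compartments are the left ventricle and the aorta, giving the flow
    variable ``F_LV_aorta``.
    """
    if n < 2:
        raise ValueError("the ring needs at least 2 compartments")
    comps = _cv_compartments(n)
    volumes = [100.0, 80.0, 60.0, 40.0] + [50.0] * max(0, n - 4)
    compliances = [1.0, 2.0, 1.5, 3.0] + [2.5] * max(0, n - 4)
    lines = ["# lumped-parameter cardiovascular ring"]
    for i, (name, term) in enumerate(comps):
        bearer = f"fmax:PortionOfBlood contained-in {term}"
        lines.append(f"var V_{name} {{property: opbx:FluidVolume, entity: {bearer}}}")
        lines.append(f"var P_{name} {{property: opbx:FluidPressure, entity: {bearer}}}")
    flow_names = []
    for i, (name, _) in enumerate(comps):
        nxt = comps[(i + 1) % n][0]
        flow_names.append(f"F_{name}_{nxt}")
        lines.append(f"var F_{name}_{nxt} {{property: opbx:FluidFlowRate}}")
    for i, (name, _) in enumerate(comps):
        prev = comps[(i - 1) % n][0]
        nxt = comps[(i + 1) % n][0]
        lines.append(f"eq V_{name}' = F_{prev}_{name} - F_{name}_{nxt}")
        lines.append(f"eq P_{name} = V_{name} / C_{name}")
        lines.append(f"eq F_{name}_{nxt} = (P_{name} - P_{nxt}) / R_{name}")
        lines.append(f"init V_{name} = {volumes[i]!r}")
        lines.append(f"init C_{name} = {compliances[i]!r}")
        lines.append(f"init R_{name} = 1.0")
    text = "\n".join(lines) + "\n"

    import os
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".eqn", delete=False, encoding="utf-8"
    ) as fh:
        fh.write(text)
        tmp = fh.name
    try:
        model = read_equation_model(tmp)
    finally:
        os.unlink(tmp)
    model.source_uri = f"fixture:cv-circuit-{n}"
    model.eqn_text = text  # type: ignore[attr-defined]

    expected_flows = {
        f"F_{comps[i][0]}_{comps[(i + 1) % n][0]}": {
            "source": ("fmax:PortionOfBlood", comps[i][1]),
            "sink": ("fmax:PortionOfBlood", comps[(i + 1) % n][1]),
        }
        for i in range(n)
    }
    spec = FixtureSpec(
        name="cv-circuit",
        parameters={"n": n},
        expected={
            "flows": n,
            "pressures": n,
            "volumes": n,
            "entities": n,
            "dependency_edges_per_flow": 3,
            "flow_roles": expected_flows,
        },
    )
    return model, spec


# ---------------------------------------------------------------------------
# random mass-action networks


def make_random_network(
    n_species: int,
    n_reactions: int,
    p_modifier: float = 0.0,
    seed: int = 0,
    acyclic: bool = False,
) -> tuple[IngestedModel, FixtureSpec]:
    """A seeded random mass-action reaction network.

    With ``acyclic=True`` the construction guarantees the derived signed
    influence graph (depletion off) is acyclic AND that qualitative
    reachability coincides with the ODE influence pattern: reactions are
    single-reactant/single-product along a fixed species order, and a
    modulated reaction draws its substrate from a dedicated clamped
    boundary pool (so modulating the rate never depletes a dynamic pool
    the map does not show).  With ``acyclic=False`` reactions may take 1-2
    reactants/products with stoichiometries in {1,2} and cycles can arise.

    Modifiers always appear multiplicatively (stimulator) or as ``1/(1+M)``
    (inhibitor) in the rate law, and carry the matching polarity tag, so
    the explicit-tag and dependency-inference paths see the same physics.
    """
    if n_species < 2 or n_reactions < 1:
        raise ValueError("need n_species >= 2 and n_reactions >= 1")
    if not 0.0 <= p_modifier <= 1.0:
        raise ValueError("p_modifier must be in [0, 1]")
    rng = np.random.default_rng(seed)
    model = IngestedModel(
        source_format="sbml",
        source_uri=f"fixture:random-{n_species}-{n_reactions}-{seed}",
    )
    species = [f"s{i}" for i in range(n_species)]
    for name in species:
        model.variables[name] = ModelVariable(
            name=name,
            annotation=_species_annotation(f"chebix:Species_{name}", None),
        )
        model.nominal_values[name] = float(np.round(rng.uniform(0.5, 2.0), 3))

    n_boundary = 0
    n_modifiers = 0
    for j in range(n_reactions):
        rid = f"r{j}"
        k = float(np.round(rng.uniform(0.5, 2.0), 3))
        kname = f"k_{rid}"
        model.variables[kname] = ModelVariable(name=kname)
        model.nominal_values[kname] = k
        modulated = rng.random() < p_modifier
        if acyclic:
            if modulated:
                pool = f"b{n_boundary}"
                n_boundary += 1
                model.variables[pool] = ModelVariable(
                    name=pool,
                    annotation=_species_annotation(f"chebix:Species_{pool}", None),
                    boundary=True,
                )
                model.nominal_values[pool] = float(
                    np.round(rng.uniform(0.5, 2.0), 3)
                )
                mod_idx = int(rng.integers(0, n_species - 1))
                product_idx = int(rng.integers(mod_idx + 1, n_species))
                modifier = species[mod_idx]
                polarity = int(rng.choice([-1, 1]))
                if polarity == +1:
                    law = f"{kname} * {pool} * {modifier}"
                else:
                    law = f"{kname} * {pool} / (1 + {modifier})"
                reactants = [(pool, 1.0)]
                products = [(species[product_idx], 1.0)]
                modifiers = [(modifier, polarity)]
                n_modifiers += 1
            else:
                r_idx = int(rng.integers(0, n_species - 1))
                p_idx = int(rng.integers(r_idx + 1, n_species))
                law = f"{kname} * {species[r_idx]}"
                reactants = [(species[r_idx], 1.0)]
                products = [(species[p_idx], 1.0)]
                modifiers = []
        else:
            picks = list(rng.permutation(n_species))
            n_r = int(rng.integers(1, 3))
            n_p = int(rng.integers(1, 3))
            r_names = [species[i] for i in picks[:n_r]]
            p_names = [species[i] for i in picks[n_r : n_r + n_p]]
            reactants = [(nm, float(rng.integers(1, 3))) for nm in r_names]
            products = [(nm, float(rng.integers(1, 3))) for nm in p_names]
            law = " * ".join([kname] + r_names)
            modifiers = []
            rest = [species[i] for i in picks[n_r + n_p :]]
            if modulated and rest:
                modifier = rest[0]
                polarity = int(rng.choice([-1, 1]))
                if polarity == +1:
                    law = f"{law} * {modifier}"
                else:
                    law = f"({law}) / (1 + {modifier})"
                modifiers = [(modifier, polarity)]
                n_modifiers += 1
        eq = Equation(
            id=f"eq_{rid}", target=rid, is_derivative=False, rhs=ex.parse_infix(law)
        )
        model.equations.append(eq)
        model.variables[rid] = ModelVariable(
            name=rid,
            annotation=CompositeAnnotation("opbx:ChemicalFlowRate", (), free_label=rid),
            equation_id=eq.id,
        )
        model.reactions.append(
            ReactionRecord(
                id=rid,
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                rate_variable=rid,
                reversible=False,
            )
        )
    synthesize_mass_balance_odes(model)
    model.check_integrity()
    spec = FixtureSpec(
        name="random-network",
        parameters={
            "n_species": n_species,
            "n_reactions": n_reactions,
            "p_modifier": p_modifier,
            "seed": seed,
            "acyclic": acyclic,
        },
        expected={
            "species": n_species + n_boundary,
            "boundary_pools": n_boundary,
            "reactions": n_reactions,
            "modifiers": n_modifiers,
            "flow_processes": n_reactions,
            "modulation_processes": n_modifiers,
        },
    )
    return model, spec


# ---------------------------------------------------------------------------
# ODE simulation and the numeric sign oracle


class SimulationError(RuntimeError):
    pass


def _algebraic_order(model: IngestedModel) -> list[Equation]:
    """Assignment equations sorted so dependencies are evaluated first."""
    algebraic = [eq for eq in model.equations if not eq.is_derivative]
    targets = {eq.target for eq in algebraic}
    order: list[Equation] = []
    placed: set[str] = set()
    pending = list(algebraic)
    while pending:
        progressed = False
        for eq in list(pending):
            if all(d not in targets or d in placed for d in eq.rhs_dependencies):
                order.append(eq)
                placed.add(eq.target)
                pending.remove(eq)
                progressed = True
        if not progressed:
            raise SimulationError("cyclic algebraic equations cannot be ordered")
    return order


def simulate_ode(
    model: IngestedModel, t_end: float, dt: float | None = None
) -> Trajectory:
    """Fixed-step classical Runge-Kutta integration of the model ODEs.

    The default step keeps ``k_max * dt <= 0.01`` for the largest nominal
    parameter magnitude, which is deterministic and comfortably stable for
    the non-stiff mass-action and lumped-parameter fixtures this package
    generates.  Non-finite values abort with the offending time and
    variable named.
    """
    states = sorted(n for n, v in model.variables.items() if v.is_state)
    if not states:
        raise SimulationError("model has no state variables")
    derivs = {}
    for name in states:
        eq = model.equation_defining(name)
        if eq is None or not eq.is_derivative:
            raise SimulationError(f"state variable {name} has no derivative equation")
        derivs[name] = eq
    algebraic = _algebraic_order(model)
    constants = {
        n: model.nominal_values.get(n, 1.0)
        for n, v in model.variables.items()
        if not v.is_state and v.equation_id is None
    }
    if dt is None:
        k_max = max([abs(v) for v in constants.values()] + [1.0])
        dt = min(0.01 / k_max, t_end / 100.0)
    n_steps = max(1, int(round(t_end / dt)))
    dt = t_end / n_steps

    def _compile(eq: Equation):
        return compile(ex.to_infix(eq.rhs).replace("^", "**"), f"<{eq.id}>", "eval")

    algebraic_code = [(eq.target, _compile(eq)) for eq in algebraic]
    deriv_code = [_compile(derivs[n]) for n in states]
    no_builtins = {"__builtins__": {}}

    def rhs(y: np.ndarray) -> tuple[np.ndarray, dict]:
        env = dict(constants)
        env.update(zip(states, y.tolist()))  # plain floats: inf, not numpy warnings
        try:
            for target, code in algebraic_code:
                env[target] = eval(code, no_builtins, env)
            dy = np.array([eval(code, no_builtins, env) for code in deriv_code])
        except ZeroDivisionError as exc:
            raise SimulationError(f"division by zero during integration: {exc}") from None
        return dy, env

    y = np.array([model.nominal_values.get(n, 1.0) for n in states], dtype=float)
    times = np.linspace(0.0, t_end, n_steps + 1)
    recorded_names = states + [eq.target for eq in algebraic] + sorted(constants)
    series: dict[str, list[float]] = {n: [] for n in recorded_names}

    def record(y_now: np.ndarray, t: float) -> None:
        _, env = rhs(y_now)
        for n in recorded_names:
            value = env[n]
            if not np.isfinite(value):
                raise SimulationError(f"non-finite value for {n} at t={t:g}")
            series[n].append(value)

    record(y, 0.0)
    for step in range(n_steps):
        t = times[step]
        k1, _ = rhs(y)
        k2, _ = rhs(y + 0.5 * dt * k1)
        k3, _ = rhs(y + 0.5 * dt * k2)
        k4, _ = rhs(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            bad = states[int(np.argmax(~np.isfinite(y)))]
            raise SimulationError(f"non-finite value for {bad} at t={times[step+1]:g}")
        record(y, times[step + 1])
    return Trajectory(
        time=times, values={n: np.array(v) for n, v in series.items()}
    )


DEAD_BAND = 1e-9


def numeric_sign_oracle(
    model: IngestedModel,
    perturb_var: str,
    epsilon: float = 1e-3,
    t_probe: float = 1.0,
    dt: float | None = None,
) -> dict[str, int]:
    """Sign of each variable's response to a small bump of one variable.

    Runs a baseline and a perturbed trajectory (the perturbed variable's
    initial/nominal value scaled by ``1 + epsilon``) and reports
    ``sign(perturbed - baseline)`` at ``t_probe`` per variable, with a
    dead band of 1e-9 mapping tiny responses to 0.
    """
    if perturb_var not in model.variables:
        raise KeyError(f"unknown variable {perturb_var!r}")
    baseline = simulate_ode(model, t_probe, dt=dt)
    import copy

    perturbed_model = copy.deepcopy(model)
    base_value = perturbed_model.nominal_values.get(perturb_var, 1.0)
    perturbed_model.nominal_values[perturb_var] = base_value * (1.0 + epsilon)
    perturbed = simulate_ode(perturbed_model, t_probe, dt=dt)
    base_at = baseline.at(t_probe)
    pert_at = perturbed.at(t_probe)
    out: dict[str, int] = {}
    for name in base_at:
        delta = pert_at[name] - base_at[name]
        if abs(delta) < DEAD_BAND:
            out[name] = 0
        else:
            out[name] = 1 if delta > 0 else -1
    return out
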