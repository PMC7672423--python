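"""Mass-action kinetics of the two-hairpin cascade and dCas9 endpoint.

The cascade is modelled as a small network of irreversible uni/bimolecular
mass-action reactions (each displacement step consumes a long toehold and
leaves no reverse toehold, so the forward direction dominates):

    R1  T + H1            -> T:H1               k = rate(|d1|, mismatches)
    R2  T:H1 + H2         -> T:H1:H2            k = rate(|d2|)
    R3  T:H1:H2 + RepF:RepQ -> T:H1:H2:RepF + RepQ   k = rate(|d3|)
    R4  T:H1:H2 + SI-gRNA -> Active             k = rate(|d3|)
    R5  H1 + H2           -> H1:H2 (leak)       k = k_leak   (default 0)

The activator stays tethered to the opened T:H1:H2 assembly, so reporter
displacement and SI-gRNA activation compete for assemblies when both are
present.  Rate constants follow the standard exponential toehold-length
dependence of strand displacement, saturating at ``n_sat`` nt; the source
study reports no fitted constants, so all endpoint checks are qualitative
(gating, ordering, conservation), never fitted-rate values.

dCas9 binding is an equilibrium endpoint (the gel shift is a 10-min
endpoint assay), not integrated kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .design import CircuitSpec
from .sequences import validate_sequence

NM = 1e-9  # molar per nanomolar
UM = 1e-6


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class RateModel:
    """Strand-displacement rate law and dCas9 binding constant.

    ``k_base`` is the bimolecular rate at a 1-nt toehold (M^-1 s^-1); each
    extra toehold nt multiplies by ``per_nt_factor`` until ``n_sat`` nt,
    capped at ``k_max``.  Mismatches between invader and toehold/migration
    domains each multiply by ``mismatch_factor``.  ``kd_rnp`` is the
    effective dissociation constant of the activated-gRNA.dCas9.DNA
    ternary assembly.
    """

    k_max: float = 3e6
    k_base: float = 1e2
    per_nt_factor: float = 10 ** 0.7
    n_sat: int = 7
    k_leak: float = 0.0
    mismatch_factor: float = 1e-2
    kd_rnp: float = 10 * NM


def toehold_rate(n: int, m: int = 0, model: RateModel = RateModel()) -> float:
    """Displacement rate constant for an n-nt toehold with m mismatches."""
    if n < 0 or m < 0:
        raise ValueError("toehold length and mismatch count must be >= 0")
    if n == 0:
        return model.k_leak
    base = min(model.k_max,
               model.k_base * model.per_nt_factor ** (min(n, model.n_sat) - 1))
    return base * model.mismatch_factor ** m


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction: reactants -> products at rate constant k."""

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValueError("only uni- and bimolecular reactions are supported")
        if self.k < 0:
            raise ValueError("rate constant must be >= 0")


@dataclass
class ReactionNetwork:
    """Species (with initial molar concentrations and per-strand composition)
    plus mass-action reactions."""

    species: dict[str, float]
    composition: dict[str, dict[str, int]]
    reactions: list[Reaction]
    fluorescent_species: str | None = None
    active_species: str | None = None

    def validate(self) -> None:
        for r in self.reactions:
            for s in r.reactants + r.products:
                if s not in self.species:
                    raise ValueError(f"reaction {r.name}: undeclared species {s!r}")
            lhs = _strand_count(self.composition, r.reactants)
            rhs = _strand_count(self.composition, r.products)
            if lhs != rhs:
                raise ValueError(
                    f"reaction {r.name} does not conserve strands: {lhs} != {rhs}"
                )

    def strand_totals(self, conc: dict[str, float]) -> dict[str, float]:
        """Per-strand total concentration, summed over all complexes."""
        totals: dict[str, float] = {}
        for sp, c in conc.items():
            for strand, count in self.composition.get(sp, {}).items():
                totals[strand] = totals.get(strand, 0.0) + count * c
        return totals


def _strand_count(comp: dict[str, dict[str, int]], side: tuple[str, ...]
                  ) -> dict[str, int]:
    out: dict[str, int] = {}
    for sp in side:
        for strand, n in comp.get(sp, {}).items():
            out[strand] = out.get(strand, 0) + n
    return out


@dataclass(frozen=True)
class Condition:
    """Initial concentrations (molar) keyed by input species name, a duration,
    and an informational temperature tag."""

    concentrations: dict[str, float]
    t_end: float
    n_samples: int = 201
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")

    def get(self, name: str) -> float:
        return self.concentrations.get(name, 0.0)


#: Fluorescence assay condition (20-min endpoint at 37 C).
FLUORESCENCE_CONDITION = Condition(
    {"T": 60 * NM, "H1": 60 * NM, "H2": 60 * NM, "RepFQ": 30 * NM},
    t_end=20 * 60.0,
)

#: Gel-shift activation condition (1-h pre-incubation at 37 C before dCas9).
GEL_SHIFT_CONDITION = Condition(
    {"T": 2 * UM, "H1": 2 * UM, "H2": 2 * UM, "SIgRNA": 1 * UM},
    t_end=3600.0,
)
GEL_SHIFT_DCAS9 = 1 * UM
GEL_SHIFT_DNA = 100 * NM


@dataclass
class TimeCourse:
    """Sampled concentrations plus derived observables."""

    times: np.ndarray
    concentrations: pd.DataFrame  # one column per species, molar
    fluorescence: np.ndarray      # displaced-reporter proxy, molar
    network: ReactionNetwork

    def endpoint_fluorescence(self) -> float:
        return float(self.fluorescence[-1])

    def final(self, species: str) -> float:
        return float(self.concentrations[species].iloc[-1])

    def conservation_residual(self) -> float:
        """Worst relative per-strand mass-balance error over all samples."""
        t0 = self.network.strand_totals(
            {s: self.network.species[s] for s in self.network.species})
        worst = 0.0
        for k in range(len(self.times)):
            row = self.concentrations.iloc[k].to_dict()
            tot = self.network.strand_totals(row)
            for strand, ref in t0.items():
                if ref <= 0:
                    continue
                worst = max(worst, abs(tot.get(strand, 0.0) - ref) / ref)
        return worst

    def to_frame(self) -> pd.DataFrame:
        df = self.concentrations.copy()
        df.insert(0, "time_s", self.times)
        df["fluorescence_M"] = self.fluorescence
        return df


def enumerate_network(circuit: CircuitSpec, condition: Condition,
                      model: RateModel = RateModel(),
                      trigger_mismatches: tuple[int, int] = (0, 0),
                      ) -> ReactionNetwork:
    """Emit the canonical cascade network for the given initial condition.

    Species whose reactions can never fire (a reactant neither present
    initially nor producible) are pruned.  ``trigger_mismatches`` carries
    the Hamming distances of the supplied trigger to the designed (d1, d2)
    and penalizes the T + H1 step, the only reaction the trigger takes
    part in.
    """
    n1 = len(circuit.domain("d1"))
    n2 = len(circuit.domain("d2"))
    n3 = len(circuit.domain("d3"))
    m1, m2 = trigger_mismatches

    species = {
        "T": condition.get("T"),
        "H1": condition.get("H1"),
        "H2": condition.get("H2"),
        "RepFQ": condition.get("RepFQ"),
        "SIgRNA": condition.get("SIgRNA"),
        "T:H1": 0.0,
        "T:H1:H2": 0.0,
        "T:H1:H2:RepF": 0.0,
        "RepQ": 0.0,
        "Active": 0.0,
        "H1:H2": 0.0,
    }
    composition = {
        "T": {"T": 1},
        "H1": {"H1": 1},
        "H2": {"H2": 1},
        "RepFQ": {"RepF": 1, "RepQ": 1},
        "SIgRNA": {"SIgRNA": 1},
        "T:H1": {"T": 1, "H1": 1},
        "T:H1:H2": {"T": 1, "H1": 1, "H2": 1},
        "T:H1:H2:RepF": {"T": 1, "H1": 1, "H2": 1, "RepF": 1},
        "RepQ": {"RepQ": 1},
        "Active": {"T": 1, "H1": 1, "H2": 1, "SIgRNA": 1},
        "H1:H2": {"H1": 1, "H2": 1},
    }
    candidates = [
        Reaction("R1", ("T", "H1"), ("T:H1",), toehold_rate(n1, m1 + m2, model)),
        Reaction("R2", ("T:H1", "H2"), ("T:H1:H2",), toehold_rate(n2, 0, model)),
        Reaction("R3", ("T:H1:H2", "RepFQ"), ("T:H1:H2:RepF", "RepQ"),
                 toehold_rate(n3, 0, model)),
        Reaction("R4", ("T:H1:H2", "SIgRNA"), ("Active",),
                 toehold_rate(n3, 0, model)),
    ]
    if model.k_leak > 0:
        candidates.append(Reaction("R5", ("H1", "H2"), ("H1:H2",), model.k_leak))

    # reachability pruning: keep reactions whose reactants are all producible
    producible = {s for s, c in species.items() if c > 0}
    changed = True
    kept: list[Reaction] = []
    while changed:
        changed = False
        for r in candidates:
            if r in kept:
                continue
            if all(s in producible for s in r.reactants):
                kept.append(r)
                for p in r.products:
                    if p not in producible:
                        producible.add(p)
                        changed = True
    kept.sort(key=lambda r: r.name)
    net = ReactionNetwork(
        species=species,
        composition=composition,
        reactions=kept,
        fluorescent_species="T:H1:H2:RepF",
        active_species="Active",
    )
    net.validate()
    return net


def simulate(network: ReactionNetwork, condition: Condition | None = None,
             t_end: float | None = None, n_samples: int | None = None,
             rtol: float = 1e-9, atol: float = 1e-13) -> TimeCourse:
    """Integrate the network deterministically (stiff-capable LSODA).

    ``condition`` may override initial concentrations for species already
    in the network; otherwise the network's own initials are used.
    """
    species = list(network.species)
    y0 = np.array([network.species[s] for s in species], dtype=float)
    if condition is not None:
        for name, c in condition.concentrations.items():
            if name in network.species:
                y0[species.index(name)] = c
        t_end = t_end if t_end is not None else condition.t_end
        n_samples = n_samples if n_samples is not None else condition.n_samples
    if t_end is None:
        raise ValueError("t_end must come from condition or argument")
    n_samples = n_samples or 201
    index = {s: k for k, s in enumerate(species)}
    rxn = [
        (r.k, tuple(index[s] for s in r.reactants),
         tuple(index[s] for s in r.products))
        for r in network.reactions
    ]

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for k, reac, prod in rxn:
            flux = k
            for i in reac:
                flux *= max(y[i], 0.0)
            for i in reac:
                dy[i] -= flux
            for i in prod:
                dy[i] += flux
        return dy

    times = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=times,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}",
                              last_state=sol.y[:, -1] if sol.y.size else y0)
    conc = pd.DataFrame(np.clip(sol.y.T, 0.0, None), columns=species)
    fl = (conc[network.fluorescent_species].to_numpy()
          if network.fluorescent_species else np.zeros(len(times)))
    net0 = ReactionNetwork(
        species={s: float(y0[index[s]]) for s in species},
        composition=network.composition,
        reactions=network.reactions,
        fluorescent_species=network.fluorescent_species,
        active_species=network.active_species,
    )
    return TimeCourse(times=times, concentrations=conc, fluorescence=fl,
                      network=net0)


def truth_table(circuit: CircuitSpec, base_condition: Condition | None = None,
                model: RateModel = RateModel()) -> pd.DataFrame:
    """Endpoint fluorescence for all 2^3 presence/absence combinations of
    trigger, H1 and H2 (the AND-gate pattern of the reporter assay)."""
    base = base_condition or FLUORESCENCE_CONDITION
    rows = []
    for bits in range(8):
        present = {"T": bool(bits & 4), "H1": bool(bits & 2), "H2": bool(bits & 1)}
        conc = dict(base.concentrations)
        for name, keep in present.items():
            if not keep:
                conc[name] = 0.0
        cond = replace(base, concentrations=conc)
        net = enumerate_network(circuit, cond, model)
        tc = simulate(net, cond)
        rows.append({**present, "endpoint_M": tc.endpoint_fluorescence()})
    return pd.DataFrame(rows)


def dose_response(circuit: CircuitSpec, trigger_concs: list[float],
                  base_condition: Condition | None = None,
                  model: RateModel = RateModel()) -> pd.DataFrame:
    """Endpoint signal and time-to-90%-of-endpoint per trigger concentration."""
    base = base_condition or FLUORESCENCE_CONDITION
    rows = []
    for c in trigger_concs:
        if c < 0:
            raise ValueError("trigger concentration must be >= 0")
        conc = dict(base.concentrations)
        conc["T"] = c
        cond = replace(base, concentrations=conc)
        net = enumerate_network(circuit, cond, model)
        tc = simulate(net, cond)
        end = tc.endpoint_fluorescence()
        if end > 0:
            t90 = float(tc.times[np.argmax(tc.fluorescence >= 0.9 * end)])
        else:
            t90 = float("nan")
        rows.append({"trigger_M": c, "endpoint_M": end, "t90_s": t90})
    return pd.DataFrame(rows)


def _domain_mismatches(circuit: CircuitSpec, wrong_trigger: str
                       ) -> tuple[int, int]:
    designed = circuit.trigger.sequence
    wrong = validate_sequence(wrong_trigger, circuit.material)
    if len(wrong) != len(designed):
        raise ValueError(
            f"mismatched trigger must match the designed length "
            f"({len(designed)} nt), got {len(wrong)}; no implicit alignment"
        )
    n1 = circuit.params.n1
    m1 = sum(a != b for a, b in zip(designed[:n1], wrong[:n1]))
    m2 = sum(a != b for a, b in zip(designed[n1:], wrong[n1:]))
    return m1, m2


def mismatch_discrimination(circuit: CircuitSpec, wrong_trigger: str,
                            condition: Condition | None = None,
                            horizon_s: float = 24 * 3600.0,
                            model: RateModel = RateModel()) -> float:
    """Ratio of endpoint signal, correct vs mismatched trigger, at the horizon.

    Mismatch counts are per-domain Hamming distances and feed the rate of
    the trigger:H1 step.  The specificity assay used a 24-h incubation.
    """
    base = condition or FLUORESCENCE_CONDITION
    cond = replace(base, t_end=horizon_s)
    correct = simulate(enumerate_network(circuit, cond, model), cond)
    mm = _domain_mismatches(circuit, wrong_trigger)
    wrong = simulate(
        enumerate_network(circuit, cond, model, trigger_mismatches=mm), cond)
    num = correct.endpoint_fluorescence()
    den = wrong.endpoint_fluorescence()
    if den == 0.0:
        return float("inf") if num > 0 else 1.0
    return num / den


def dcas9_endpoint(active_grna: float, dcas9: float, dna: float,
                   model: RateModel = RateModel()) -> float:
    """Equilibrium bound-DNA fraction for the gel-shift endpoint.

    With dCas9 in excess of DNA, ribonucleoprotein RNP ~ min(active gRNA,
    dCas9); the bound fraction follows a single-site binding isotherm with
    ``kd_rnp``, and bound DNA can never exceed total DNA.  Monotone
    non-decreasing in the activated-gRNA concentration.
    """
    if min(active_grna, dcas9, dna) < 0:
        raise ValueError("concentrations must be >= 0")
    rnp = min(active_grna, dcas9)
    if rnp == 0.0 or dna == 0.0:
        return 0.0
    frac = rnp / (model.kd_rnp + rnp)
    bound = min(frac * dna, dna)
    return bound / dna


def dcas9_gate_series(circuit: CircuitSpec, trigger_concs: list[float],
                      base_condition: Condition | None = None,
                      dcas9: float = GEL_SHIFT_DCAS9,
                      dna: float = GEL_SHIFT_DNA,
                      model: RateModel = RateModel()) -> pd.DataFrame:
    """Activate the SI-gRNA at each trigger concentration, then take the
    equilibrium dCas9 binding endpoint (the concentration-series gel)."""
    base = base_condition or GEL_SHIFT_CONDITION
    rows = []
    for c in trigger_concs:
        conc = dict(base.concentrations)
        conc["T"] = c
        conc.setdefault("RepFQ", 0.0)
        cond = replace(base, concentrations=conc)
        net = enumerate_network(circuit, cond, model)
        tc = simulate(net, cond)
        active = tc.final("Active") if "Active" in tc.concentrations else 0.0
        rows.append({
            "trigger_M": c,
            "active_grna_M": active,
            "bound_dna_fraction": dcas9_endpoint(active, dcas9, dna, model),
        })
    return pd.DataFrame(rows)
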