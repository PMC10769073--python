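"""Synthetic device exports with known ground truth, for every experiment type.

The generator writes text files in the same dialect the parser reads
(comment lines, ``Date Time`` / ``Elapsed`` header, one column per condition)
and returns the generating truth so downstream estimates can be checked
against it.

Growth model: the control grows as ``c0 * exp(K(t))`` with cumulative rate
``K(t) = k0*t + slope*t^2/2`` (constant or linear-in-time rate).  Each
chemical agent carries a true dose-inhibition curve
``I(d) = emax * u / (1 + u)``, ``u = (d/ic50)**hill``; a genetic perturbagen
carries a fixed inhibition fraction.  Two effect models:

* ``rate`` (default for time courses): a condition's rate is
  ``k(t) * (1 - sum_i I_i)``.  Per-agent survival on the read-out is then
  ``S_i(t) = exp(-K(t) * I_i)`` and combination survival is the product of
  the single-agent survivals, so Bliss independence holds exactly at every
  time point and growth-rate ground truth is well defined.
* ``direct`` (endpoint-style): survival ``1 - I_i`` multiplies the control
  read-out directly, so margin inhibitions are exactly the 4PL curves.

Synergy is injected by multiplying a chosen combination cell's read-out by
``(1 - epsilon)`` from the onset time onward (excess killing beyond Bliss);
the resulting BI score is ``epsilon * (1 - H)`` with ``H`` the Bliss
expectation at that cell.  Noise is multiplicative Gaussian on the read-out,
floored at 0.  Seeded generation is bit-reproducible.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .screen_io import ChemicalDose, ConditionDescriptor, RawScreen, write_export

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class AgentSpec:
    """A chemical agent with its tested doses and true inhibition curve."""

    name: str
    doses: tuple[float, ...]
    ic50: float
    hill: float = 1.5
    emax: float = 0.9
    unit: str = "nM"

    def inhibition(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        u = (dose / self.ic50) ** self.hill
        return self.emax * u / (1.0 + u)


@dataclass(frozen=True)
class GeneticSpec:
    """A genetic perturbagen (knockdown/overexpression) with a fixed rate inhibition."""

    label: str
    inhibition: float = 0.3


@dataclass(frozen=True)
class SynergySpec:
    """Bliss-excess synergy injected at chosen grid cells from an onset time."""

    epsilon: float = 0.2
    onset: float = 20.0
    combination: int = 0  # index into SimSpec.combinations
    cells: tuple[tuple[int, ...], ...] = ((0, 0),)  # dose indices per member


@dataclass(frozen=True)
class SimSpec:
    """Complete description of one simulated screen."""

    experiment_type: str = "drug"
    agents: tuple[AgentSpec, ...] = ()
    genetic: tuple[GeneticSpec, ...] = ()
    #: tuples of perturbagen names (agents and/or genetic labels) to cross;
    #: a member may also be ``(name, k)`` to use only the first k doses
    combinations: tuple[tuple, ...] = ()
    cell_line: str = "CELL-A"
    seeding: str = "10k"
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 74, 2))
    growth_rate: float = LN2 / 24.0  # per hour; doubling every 24 h
    rate_slope: float = 0.0  # linear-in-time rate term
    effect_model: str = "rate"  # "rate" | "direct"
    synergy: SynergySpec | None = None
    noise_sd: float = 0.05
    replicates: int = 1
    seed: int = 0
    initial_confluency: float = 5.0
    vehicle: tuple[str, float, str] = ("DMSO", 0.1, "%")
    genetic_control: str = "untreated"


@dataclass
class GroundTruth:
    """What the generator actually put into a simulated screen."""

    spec: SimSpec
    descriptors: list[ConditionDescriptor]
    #: per condition, the individual true inhibition fractions of its perturbagens
    inhibitions: list[tuple[float, ...]]
    #: condition indices that received injected synergy
    synergy_conditions: list[int]
    times: np.ndarray

    def cumulative_rate(self, t: np.ndarray) -> np.ndarray:
        s = self.spec
        return s.growth_rate * t + 0.5 * s.rate_slope * t**2

    def expected_bliss(self, condition: int, t: np.ndarray) -> np.ndarray:
        """True Bliss expectation H at a combination condition over time."""
        surv = np.ones_like(np.asarray(t, dtype=float))
        for inh in self.inhibitions[condition]:
            surv = surv * self._survival(inh, t)
        return 1.0 - surv

    def _survival(self, inhibition: float, t: np.ndarray) -> np.ndarray:
        if self.spec.effect_model == "direct":
            return np.full_like(np.asarray(t, dtype=float), 1.0 - inhibition)
        return np.exp(-self.cumulative_rate(np.asarray(t, dtype=float)) * inhibition)


def _agent_by_name(spec: SimSpec, name: str) -> AgentSpec | None:
    for a in spec.agents:
        if a.name == name:
            return a
    return None


def _genetic_by_label(spec: SimSpec, label: str) -> GeneticSpec | None:
    for g in spec.genetic:
        if g.label == label:
            return g
    return None


def build_conditions(spec: SimSpec) -> tuple[list[ConditionDescriptor], list[tuple[float, ...]], list[int]]:
    """Enumerate condition columns: controls, singles, genetic, then combinations.

    Returns descriptors, the per-condition tuple of true inhibitions, and the
    indices of conditions carrying injected synergy.
    """
    descriptors: list[ConditionDescriptor] = []
    inhibitions: list[tuple[float, ...]] = []

    def add(agents=(), genetic=(), inh=()):
        descriptors.append(
            ConditionDescriptor(
                agents=tuple(agents),
                genetic=tuple(genetic),
                cell_line=spec.cell_line,
                seeding=spec.seeding,
            )
        )
        inhibitions.append(tuple(inh))

    # control column
    if spec.agents:
        name, conc, unit = spec.vehicle
        add(agents=[ChemicalDose(name, conc, unit)], inh=[0.0])
    else:
        add(genetic=[spec.genetic_control], inh=[0.0])

    for a in spec.agents:
        for d in a.doses:
            add(agents=[ChemicalDose(a.name, d, a.unit)], inh=[a.inhibition(d)])
    for g in spec.genetic:
        add(genetic=[g.label], inh=[g.inhibition])

    synergy_conditions: list[int] = []
    for ci, members in enumerate(spec.combinations):
        axes: list[list[tuple]] = []  # per member: list of (ChemicalDose|label, I)
        for member in members:
            name, limit = (member, None) if isinstance(member, str) else member
            a = _agent_by_name(spec, name)
            if a is not None:
                doses = a.doses if limit is None else a.doses[:limit]
                axes.append(
                    [(ChemicalDose(a.name, d, a.unit), a.inhibition(d)) for d in doses]
                )
                continue
            g = _genetic_by_label(spec, name)
            if g is None:
                raise ValidationError(f"combination member {name!r} is not defined")
            axes.append([(g.label, g.inhibition)])
        syn_cells = set()
        if spec.synergy is not None and spec.synergy.combination == ci:
            for cell in spec.synergy.cells:
                if len(cell) != len(axes) or any(
                    not (0 <= k < len(ax)) for k, ax in zip(cell, axes)
                ):
                    raise ValidationError(
                        f"synergy cell {cell} outside the {members} dose grid"
                    )
                syn_cells.add(tuple(cell))
        for coords in itertools.product(*(range(len(ax)) for ax in axes)):
            agents, genetic, inh = [], [], []
            for ax, k in zip(axes, coords):
                item, i_val = ax[k]
                (agents if isinstance(item, ChemicalDose) else genetic).append(item)
                inh.append(i_val)
            add(agents=agents, genetic=genetic, inh=inh)
            if coords in syn_cells:
                synergy_conditions.append(len(descriptors) - 1)
    return descriptors, inhibitions, synergy_conditions


def simulate_screen(
    spec: SimSpec, path: str | os.PathLike | None = None
) -> tuple[RawScreen, GroundTruth, str | None]:
    """Simulate a screen; optionally write it as a device-format text export.

    Returns ``(screen, ground_truth, path)``.  With ``replicates > 1`` the
    export holds one column per replicate (duplicate condition headers), as a
    real multi-replicate export would.
    """
    if spec.effect_model not in ("rate", "direct"):
        raise ValidationError(f"unknown effect model {spec.effect_model!r}")
    rng = np.random.default_rng(spec.seed)
    descriptors, inhibitions, syn_conditions = build_conditions(spec)
    times = np.asarray(spec.times, dtype=float)
    K = spec.growth_rate * times + 0.5 * spec.rate_slope * times**2
    control_traj = spec.initial_confluency * np.exp(K)

    clean = np.empty((times.size, len(descriptors)))
    syn_set = set(syn_conditions)
    for j, inh in enumerate(inhibitions):
        if spec.effect_model == "rate":
            factor = 1.0 - sum(inh)
            traj = spec.initial_confluency * np.exp(K * factor)
        else:
            traj = control_traj * float(np.prod([1.0 - i for i in inh]))
        if j in syn_set and spec.synergy is not None:
            traj = traj * np.where(times >= spec.synergy.onset, 1.0 - spec.synergy.epsilon, 1.0)
        clean[:, j] = traj

    rep_desc: list[ConditionDescriptor] = []
    rep_cols: list[np.ndarray] = []
    for j, d in enumerate(descriptors):
        for _ in range(spec.replicates):
            noisy = clean[:, j] * (1.0 + spec.noise_sd * rng.standard_normal(times.size))
            rep_desc.append(d)
            rep_cols.append(np.clip(noisy, 0.0, None))
    measurements = np.column_stack(rep_cols)
    datetimes = [f"2026-01-01 {int(t) // 24:02d}d{t % 24:05.2f}h" for t in times]
    screen = RawScreen(
        elapsed=times,
        measurements=measurements,
        descriptors=rep_desc,
        datetimes=datetimes,
    )
    truth = GroundTruth(
        spec=spec,
        descriptors=descriptors,
        inhibitions=inhibitions,
        synergy_conditions=syn_conditions,
        times=times,
    )
    out = None
    if path is not None:
        out = str(path)
        tmp = out + ".tmp"
        write_export(screen, tmp)
        with open(tmp, "r", encoding="utf-8") as fh:
            body = fh.read()
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(f"# simulated {spec.experiment_type} screen (seed {spec.seed})\n")
            fh.write("# generated by perturbscreen.synthgen\n")
            fh.write(body)
        os.remove(tmp)
    return screen, truth, out


# ---------------------------------------------------------------------------
# canonical screens and randomized layouts


def _dose_range(top: float, n: int, step: float = 3.0) -> tuple[float, ...]:
    return tuple(round(top / step**i, 4) for i in reversed(range(n)))


def worked_fixtures(out_dir: str | os.PathLike, seed: int = 0) -> dict[str, tuple[str, SimSpec]]:
    """Generate the canonical screens used throughout the tests and docs.

    * ``endpoint_drug`` — one agent, 8 doses, single time point;
    * ``combination`` — 3 agents x 7 doses, two full 7x7 grids and one 4x4
      grid: 136 conditions x 37 time points (5032 measurements);
    * ``genetic`` — two overexpression conditions vs. an untreated control;
    * ``genetic_chemical`` — overexpression crossed with a 7-dose drug range.
    """
    os.makedirs(out_dir, exist_ok=True)
    a = AgentSpec("WEE1i", _dose_range(3000.0, 7), ic50=400.0, hill=1.6, emax=0.85)
    b = AgentSpec("CHK1i", _dose_range(100.0, 7), ic50=9.0, hill=1.2, emax=0.55)
    c = AgentSpec("ATRi", _dose_range(1000.0, 7), ic50=120.0, hill=1.4, emax=0.7)
    specs = {
        "endpoint_drug": SimSpec(
            experiment_type="drug",
            agents=(AgentSpec("DRUG1", _dose_range(10000.0, 8), ic50=300.0),),
            times=(72.0,),
            effect_model="direct",
            noise_sd=0.02,
            seed=seed + 1,
        ),
        "combination": SimSpec(
            experiment_type="drug_combination",
            agents=(a, b, c),
            combinations=(
                ("WEE1i", "CHK1i"),
                ("WEE1i", "ATRi"),
                (("CHK1i", 4), ("ATRi", 4)),
            ),
            noise_sd=0.03,
            seed=seed + 2,
        ),
        "genetic": SimSpec(
            experiment_type="genetic",
            genetic=(GeneticSpec("GENE1 OE", 0.35), GeneticSpec("GENE2 KD", 0.15)),
            times=tuple(float(t) for t in range(0, 74, 6)),
            noise_sd=0.03,
            seed=seed + 3,
        ),
        "genetic_chemical": SimSpec(
            experiment_type="genetic_chemical",
            agents=(AgentSpec("MYBi", _dose_range(2000.0, 7), ic50=500.0, emax=0.8),),
            genetic=(GeneticSpec("TF1 OE", 0.3),),
            combinations=(("TF1 OE", "MYBi"),),
            noise_sd=0.03,
            seed=seed + 4,
        ),
    }
    # combination screen: 1 control + 21 singles + 49 + 49 + 16 = 136 conditions
    out: dict[str, tuple[str, SimSpec]] = {}
    for name, spec in specs.items():
        path = os.path.join(str(out_dir), f"{name}.txt")
        simulate_screen(spec, path)
        out[name] = (path, spec)
    return out


def random_layout(rng: np.random.Generator, experiment_type: str | None = None):
    """Random descriptor set of a known experiment type (for categorization tests).

    Returns ``(descriptors, expected_type)``; descriptors include a control.
    """
    if experiment_type is None:
        experiment_type = rng.choice(
            ["drug", "drug_combination", "genetic", "genetic_chemical"]
        )
    n_agents = int(rng.integers(1, 4))
    n_doses = int(rng.integers(2, 8))
    agents = tuple(
        AgentSpec(
            f"AG{i}-{rng.integers(1000)}",
            _dose_range(float(rng.uniform(100, 5000)), n_doses),
            ic50=float(rng.uniform(10, 1000)),
        )
        for i in range(n_agents)
    )
    genetic = tuple(
        GeneticSpec(f"G{i}-{rng.integers(1000)} OE", float(rng.uniform(0.1, 0.5)))
        for i in range(int(rng.integers(1, 3)))
    )
    if experiment_type == "drug":
        spec = SimSpec(experiment_type="drug", agents=agents)
    elif experiment_type == "drug_combination":
        if n_agents < 2:
            agents = agents + (
                AgentSpec("AGX", _dose_range(500.0, n_doses), ic50=100.0),
            )
        combo = tuple(a.name for a in agents[:2])
        spec = SimSpec(
            experiment_type="drug_combination", agents=agents, combinations=(combo,)
        )
    elif experiment_type == "genetic":
        spec = SimSpec(experiment_type="genetic", genetic=genetic)
    else:
        combo = (genetic[0].label, agents[0].name)
        spec = SimSpec(
            experiment_type="genetic_chemical",
            agents=agents[:1],
            genetic=genetic,
            combinations=(combo,),
        )
    descriptors, _, _ = build_conditions(spec)
    perm = rng.permutation(len(descriptors))
    return [descriptors[i] for i in perm], experiment_type
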