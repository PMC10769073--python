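"""Branch grouping, control identification and experiment categorization.

Conditions sharing cell line, seeding density and genetic condition form a
*branch*; the experiment is then categorized as a drug, drug-combination,
genetic or genetic-chemical perturbagen screen from the branch composition
(number of agents per condition, presence of genetic labels, doses per
agent).  Controls are vehicle/solvent conditions (DMSO and friends) or
conditions with zero dose of every agent; the proposed control set is meant
to be confirmed by the user before analysis (``--yes`` on the CLI).
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CategorizationError, ControlError
from .screen_io import ConditionDescriptor

#: vehicle/solvent tokens proposed as controls (case-insensitive)
DEFAULT_VEHICLES = frozenset({"dmso", "pbs", "h2o", "untreated", "control"})

EXPERIMENT_TYPES = ("drug", "drug_combination", "genetic", "genetic_chemical")


@dataclass
class Branch:
    """Conditions sharing (cell line, seeding, genetic condition)."""

    cell_line: str
    seeding: str
    genetic: tuple[str, ...]
    members: list[int]  # condition indices into the screen
    descriptors: list[ConditionDescriptor]

    @classmethod
    def from_members(
        cls,
        descriptors: Sequence[ConditionDescriptor],
        members: Sequence[int],
        cell_line: str | None = None,
        seeding: str | None = None,
    ) -> "Branch":
        d0 = descriptors[0]
        return cls(
            cell_line=cell_line if cell_line is not None else d0.cell_line,
            seeding=seeding if seeding is not None else d0.seeding,
            genetic=d0.genetic,
            members=list(members),
            descriptors=list(descriptors),
        )

    @property
    def agents(self) -> tuple[str, ...]:
        """Chemical agent names in this branch, sorted."""
        names = {a.name for d in self.descriptors for a in d.agents}
        return tuple(sorted(names))

    def doses(self, agent: str) -> np.ndarray:
        """Sorted unique doses of one agent across the branch."""
        ds = sorted(
            {a.concentration for d in self.descriptors for a in d.agents if a.name == agent}
        )
        return np.asarray(ds, dtype=float)

    @property
    def has_combination(self) -> bool:
        return any(d.is_combination for d in self.descriptors)

    @property
    def monotherapy_members(self) -> list[int]:
        return [i for i, d in zip(self.members, self.descriptors) if not d.is_combination]

    @property
    def combination_members(self) -> list[int]:
        return [i for i, d in zip(self.members, self.descriptors) if d.is_combination]


@dataclass
class Layout:
    """Branches + confirmed controls + inferred experiment type for a screen."""

    branches: list[Branch]
    control_indices: list[int]
    descriptors: list[ConditionDescriptor]
    experiment_type: str
    confirmed: bool = False

    @property
    def controls(self) -> list[ConditionDescriptor]:
        return [self.descriptors[i] for i in self.control_indices]


def _branch_key(d: ConditionDescriptor):
    return (d.cell_line, d.seeding, d.genetic)


def group_branches(descriptors: Sequence[ConditionDescriptor]) -> list[Branch]:
    """Partition non-control descriptors by (cell line, seeding, genetic condition)."""
    order: list[tuple] = []
    groups: dict[tuple, tuple[list[ConditionDescriptor], list[int]]] = {}
    for i, d in enumerate(descriptors):
        if d.is_control:
            continue
        key = _branch_key(d)
        if key not in groups:
            order.append(key)
            groups[key] = ([], [])
        groups[key][0].append(d)
        groups[key][1].append(i)
    return [Branch.from_members(groups[k][0], groups[k][1]) for k in order]


def identify_controls(
    descriptors: Sequence[ConditionDescriptor],
    vehicles: Iterable[str] = DEFAULT_VEHICLES,
    extra_names: Iterable[str] = (),
) -> list[int]:
    """Propose control conditions: vehicle-only columns or zero dose of every agent.

    Returns condition indices.  Raises :class:`ControlError` when no candidate
    exists (the caller is expected to write a categorization-error file).
    """
    vocab = {v.lower() for v in vehicles} | {v.lower() for v in extra_names}
    controls: list[int] = []
    for i, d in enumerate(descriptors):
        vehicle_only = (
            len(d.agents) >= 1
            and not d.genetic
            and all(a.name.lower() in vocab for a in d.agents)
        )
        genetic_vehicle = (
            not d.agents and d.genetic and all(g.lower() in vocab for g in d.genetic)
        )
        zero_dose = (
            len(d.agents) >= 1
            and not d.genetic
            and all(a.concentration == 0 for a in d.agents)
        )
        if vehicle_only or genetic_vehicle or zero_dose:
            controls.append(i)
    if not controls:
        raise ControlError(
            "no control condition found: expected a vehicle column "
            f"({', '.join(sorted(vocab))}) or a zero-dose condition"
        )
    return controls


def write_categorization_error(
    path: str | os.PathLike,
    descriptors: Sequence[ConditionDescriptor],
    reason: str,
) -> str:
    """Emit the error file produced when categorization/control detection fails."""
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("categorization error\n")
        fh.write(f"reason: {reason}\n")
        fh.write("possible missing information: control column (vehicle or zero dose)\n")
        fh.write("data headers:\n")
        for d in descriptors:
            fh.write(f"  {d.raw_label or d}\n")
    return path


def categorize(branches: Sequence[Branch], control_indices: Sequence[int]) -> str:
    """Infer the experiment type from branch composition and controls.

    Rules (genetic-chemical wins over drug when both patterns occur):

    * any condition combines genetic label(s) with chemical agent(s), or a
      branch carries a genetic condition while chemical agents are tested
      anywhere -> ``genetic_chemical``;
    * genetic labels only, no chemical agent anywhere -> ``genetic``;
    * >=2 chemical agents co-applied in at least one condition -> ``drug_combination``;
    * exactly one chemical agent per condition, >=1 dose -> ``drug``.
    """
    if not branches:
        raise CategorizationError("no non-control conditions to categorize")
    if not control_indices:
        raise CategorizationError("no confirmed controls")
    has_genetic = any(br.genetic or any(d.genetic for d in br.descriptors) for br in branches)
    has_chemical = any(len(d.agents) > 0 for br in branches for d in br.descriptors)
    if has_genetic and has_chemical:
        return "genetic_chemical"
    if has_genetic:
        return "genetic"
    if any(len(d.agents) >= 2 for br in branches for d in br.descriptors):
        return "drug_combination"
    if all(len(d.agents) == 1 for br in branches for d in br.descriptors):
        return "drug"
    raise CategorizationError(
        "inconsistent branch composition: conditions with no perturbagen"
    )


def build_layout(
    descriptors: Sequence[ConditionDescriptor],
    vehicles: Iterable[str] = DEFAULT_VEHICLES,
    extra_control_names: Iterable[str] = (),
    confirmed: bool = False,
) -> Layout:
    """Identify controls, group branches and categorize in one step.

    Control flags are set on the returned layout's descriptors (the input
    sequence is not mutated).
    """
    control_idx = identify_controls(descriptors, vehicles, extra_control_names)
    flagged = [
        d.with_control(i in set(control_idx)) for i, d in enumerate(descriptors)
    ]
    branches = group_branches(flagged)
    experiment_type = categorize(branches, control_idx)
    return Layout(
        branches=branches,
        control_indices=list(control_idx),
        descriptors=flagged,
        experiment_type=experiment_type,
        confirmed=confirmed,
    )


# ---------------------------------------------------------------------------
# combination grids


@dataclass
class CombinationGrid:
    """N-dimensional dose grid of a combination branch.

    Axes are the perturbagens appearing in combination conditions: each
    chemical agent contributes its sorted unique combination doses; a genetic
    perturbagen contributes a single-level presence axis.  ``cells`` maps grid
    coordinates to the combination condition index; ``margins[axis]`` maps a
    dose level to the matching single-perturbagen condition index.
    """

    axis_names: tuple[str, ...]
    axis_is_genetic: tuple[bool, ...]
    axis_doses: tuple[np.ndarray, ...]  # genetic axes hold a single level [1.0]
    cells: dict[tuple[int, ...], int]
    margins: tuple[dict[int, int], ...]
    incomplete: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.axis_doses)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def chemical_shape(self) -> tuple[int, ...]:
        return tuple(
            len(d) for d, g in zip(self.axis_doses, self.axis_is_genetic) if not g
        )

    @property
    def heatmap_2d_only(self) -> bool:
        """True when any chemical axis tests a single concentration (m = 1)."""
        chem = self.chemical_shape
        return len(chem) < 2 or min(chem) == 1

    def margin_indices(self, coords: tuple[int, ...]) -> list[int | None]:
        return [m.get(c) for m, c in zip(self.margins, coords)]


def combination_grids(
    branch: Branch, companion_branches: Sequence[Branch] = ()
) -> list[CombinationGrid]:
    """One grid per distinct combination (perturbagen set) in a branch.

    A branch may test several combinations side by side (e.g. two different
    drug pairs); each distinct set of co-applied perturbagens becomes its own
    N-dimensional grid.
    """
    sets: dict[frozenset, None] = {}
    for d in branch.descriptors:
        if d.is_combination:
            sets.setdefault(frozenset(d.perturbagens), None)
    return [
        combination_grid(branch, companion_branches, perturbagens=s) for s in sets
    ]


def combination_grid(
    branch: Branch,
    companion_branches: Sequence[Branch] = (),
    perturbagens: frozenset | None = None,
) -> CombinationGrid:
    """Index a combination branch's conditions on the N-dimensional dose grid.

    Monotherapy margins are looked up in the branch itself and, for
    genetic-chemical screens, in ``companion_branches`` (e.g. the parental
    branch holding drug-alone conditions, or the genetic-alone branch).
    ``perturbagens`` restricts the grid to one combination when a branch
    tests several.  Grid cells with neither a measured condition nor usable
    margins are flagged incomplete; analysis proceeds on the present cells.
    """
    combos = [
        (i, d)
        for i, d in zip(branch.members, branch.descriptors)
        if d.is_combination
        and (perturbagens is None or frozenset(d.perturbagens) == perturbagens)
    ]
    if not combos:
        raise CategorizationError(
            "branch has no combination conditions (need >=2 co-applied perturbagens)"
        )
    chem_names = sorted({a.name for _, d in combos for a in d.agents})
    gen_names = sorted({g for _, d in combos for g in d.genetic})
    axis_names = tuple(chem_names + gen_names)
    axis_is_genetic = tuple([False] * len(chem_names) + [True] * len(gen_names))
    if len(axis_names) < 2:
        raise CategorizationError("combination grid needs >=2 distinct perturbagens")

    axis_doses: list[np.ndarray] = []
    for name, is_gen in zip(axis_names, axis_is_genetic):
        if is_gen:
            axis_doses.append(np.asarray([1.0]))
        else:
            ds = sorted(
                {
                    a.concentration
                    for _, d in combos
                    for a in d.agents
                    if a.name == name
                }
            )
            axis_doses.append(np.asarray(ds, dtype=float))

    cells: dict[tuple[int, ...], int] = {}
    for idx, d in combos:
        coords = []
        ok = True
        for name, is_gen, doses in zip(axis_names, axis_is_genetic, axis_doses):
            if is_gen:
                if name not in d.genetic:
                    ok = False
                    break
                coords.append(0)
            else:
                try:
                    dose = d.dose_of(name)
                except KeyError:
                    ok = False
                    break
                coords.append(int(np.searchsorted(doses, dose)))
        if ok:
            cells[tuple(coords)] = idx

    # margin lookup: single-perturbagen conditions matching each axis level
    pool = list(zip(branch.members, branch.descriptors))
    for cb in companion_branches:
        pool.extend(zip(cb.members, cb.descriptors))
    margins: list[dict[int, int]] = []
    for name, is_gen, doses in zip(axis_names, axis_is_genetic, axis_doses):
        lookup: dict[int, int] = {}
        for idx, d in pool:
            if d.is_combination:
                continue
            if is_gen:
                if d.genetic == (name,) and not d.agents:
                    lookup[0] = idx
            else:
                if len(d.agents) == 1 and not d.genetic and d.agents[0].name == name:
                    pos = np.searchsorted(doses, d.agents[0].concentration)
                    if pos < len(doses) and doses[pos] == d.agents[0].concentration:
                        lookup[int(pos)] = idx
        margins.append(lookup)

    incomplete = [
        coords
        for coords in itertools.product(*(range(len(d)) for d in axis_doses))
        if coords not in cells
        or any(m.get(c) is None for m, c in zip(margins, coords))
    ]
    return CombinationGrid(
        axis_names=axis_names,
        axis_is_genetic=axis_is_genetic,
        axis_doses=tuple(axis_doses),
        cells=cells,
        margins=tuple(margins),
        incomplete=incomplete,
    )
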