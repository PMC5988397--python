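"""Relative-energy arithmetic within elementary steps.

An elementary step is a reactant→TS→product triple sharing one cluster
model and level of theory. Relative energies are differences of absolute
electronic energies (hartree) converted to kcal/mol with the step's
reactant pinned at exactly zero — the convention of every published
cluster-model table this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import hartree_to_kcalmol
from .energy_io import SpeciesEnergy, canonical_label

__all__ = [
    "ElementaryStep",
    "SizeComparison",
    "relative_energies",
    "steps_from_records",
    "step_barrier",
    "step_reaction_energy",
    "size_dependence_report",
]


@dataclass
class ElementaryStep:
    """One elementary step with per-species relative energies.

    ``relative_kcal`` maps species label → energy in kcal/mol relative to
    the step's reactant (which maps to exactly 0.0). Exactly one TS is
    present and all species share (model, method).
    """

    name: str
    reactant: SpeciesEnergy
    ts: SpeciesEnergy
    product: SpeciesEnergy
    relative_kcal: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        species = (self.reactant, self.ts, self.product)
        methods = {(s.model, s.method) for s in species}
        if len(methods) != 1:
            raise ValueError(
                f"step {self.name!r}: species mix models/methods: {sorted(methods)}"
            )
        if self.relative_kcal.get(self.reactant.label) != 0.0:
            raise ValueError(
                f"step {self.name!r}: reactant {self.reactant.label} must sit at "
                f"exactly 0, got {self.relative_kcal.get(self.reactant.label)!r}"
            )

    @property
    def species(self) -> tuple[SpeciesEnergy, SpeciesEnergy, SpeciesEnergy]:
        return (self.reactant, self.ts, self.product)


def _is_ts_label(label: str) -> bool:
    return label.upper().startswith("TS")


def relative_energies(
    species: Iterable[SpeciesEnergy],
    reference_label: str,
    name: str | None = None,
) -> ElementaryStep:
    """Build an :class:`ElementaryStep` from absolute energies.

    Each species gets ``hartree_to_kcalmol(E(s) - E(reference))``; the
    reference maps to exactly 0.0 (assigned, not computed, so it cannot
    pick up rounding noise).

    Parameters
    ----------
    species : iterable of SpeciesEnergy
        The three stationary points of one step, any order. All must share
        (model, method).
    reference_label : str
        Label of the step's initial state (synonyms accepted).
    name : str, optional
        Step name; defaults to the species' common ``step`` field.

    Raises
    ------
    KeyError
        If the reference label is absent.
    ValueError
        If species mix cluster models or methods.
    """
    pool = list(species)
    if not pool:
        raise KeyError("no species supplied")
    methods = {(s.model, s.method) for s in pool}
    if len(methods) != 1:
        raise ValueError(f"species mix models/methods: {sorted(methods)}")
    reference_label = canonical_label(reference_label)
    by_label = {s.label: s for s in pool}
    if reference_label not in by_label:
        raise KeyError(
            f"reference species {reference_label!r} not among {sorted(by_label)}"
        )
    ref = by_label[reference_label]
    rel = {
        s.label: (
            0.0
            if s.label == reference_label
            else hartree_to_kcalmol(s.energy_au - ref.energy_au)
        )
        for s in pool
    }
    if len(pool) == 1:
        # degenerate single-species "step": reference plays all three roles
        return ElementaryStep(
            name=name or ref.step, reactant=ref, ts=ref, product=ref,
            relative_kcal=rel,
        )

    ts_candidates = [s for s in pool if _is_ts_label(s.label)]
    if len(ts_candidates) != 1:
        raise ValueError(
            f"expected exactly one TS among {sorted(by_label)}, "
            f"found {len(ts_candidates)}"
        )
    ts = ts_candidates[0]
    others = [s for s in pool if s.label not in (reference_label, ts.label)]
    if len(others) != 1:
        raise ValueError(
            f"expected reactant/TS/product triple, got labels {sorted(by_label)}"
        )
    return ElementaryStep(
        name=name or ref.step,
        reactant=ref,
        ts=ts,
        product=others[0],
        relative_kcal=rel,
    )


def steps_from_records(
    records: Iterable[SpeciesEnergy],
) -> dict[tuple[str, tuple[str, str, str], str], ElementaryStep]:
    """Group a species table into elementary steps.

    Records are grouped by (model, method, step); within each group the
    first row is taken as the step's initial state — species tables list
    stationary points in mechanistic order.
    """
    groups: dict[tuple, list[SpeciesEnergy]] = {}
    for r in records:
        groups.setdefault((r.model, r.method, r.step), []).append(r)
    return {
        key: relative_energies(species, species[0].label, name=key[2])
        for key, species in groups.items()
    }


def step_barrier(step: ElementaryStep) -> float:
    """Electronic-energy barrier: TS relative to the step's initial state."""
    return step.relative_kcal[step.ts.label]


def step_reaction_energy(step: ElementaryStep) -> float:
    """Step reaction energy: product relative to the step's initial state."""
    return step.relative_kcal[step.product.label]


@dataclass
class SizeComparison:
    """Relative energies on a (species × cluster model) grid, per method.

    ``grid`` is a DataFrame indexed by species label with one column per
    cluster model. Cells absent from the input stay NaN — they are never
    imputed. Each model column's reference species sits at exactly 0.
    """

    grid: pd.DataFrame
    references: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return self.grid.copy()


def size_dependence_report(
    steps_per_model: Mapping[str, Sequence[ElementaryStep]],
) -> SizeComparison:
    """Compare relative energies across cluster-model sizes.

    Parameters
    ----------
    steps_per_model : mapping of model name → elementary steps
        At least two models sharing part of the species vocabulary.

    Returns
    -------
    SizeComparison
        Species × model grid of relative energies (kcal/mol), with each
        step's reference at 0 within its model column.

    Raises
    ------
    ValueError
        If fewer than two models are supplied or no species overlaps.
    """
    if len(steps_per_model) < 2:
        raise ValueError(
            f"size comparison needs >=2 cluster models, got {len(steps_per_model)}"
        )
    columns: dict[str, dict[str, float]] = {}
    references: dict[str, str] = {}
    order: list[str] = []
    for model, steps in steps_per_model.items():
        col: dict[str, float] = {}
        for st in steps:
            for lab, val in st.relative_kcal.items():
                col[lab] = val
                if lab not in order:
                    order.append(lab)
            references.setdefault(model, st.reactant.label)
        columns[model] = col
    shared = set.intersection(*(set(c) for c in columns.values()))
    if not shared:
        raise ValueError("no species label shared across the supplied models")
    grid = pd.DataFrame(
        {m: [columns[m].get(lab) for lab in order] for m in columns},
        index=pd.Index(order, name="species"),
        dtype=float,
    )
    return SizeComparison(grid=grid, references=references)
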