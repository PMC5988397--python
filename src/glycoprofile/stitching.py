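"""Join half-reactions of differing chemical composition into one profile.

The catalytic cycle of a retaining glycosidase/fructosyltransferase has a
common first half — glycosylation, RC→TS1→IM1, forming the covalent
glycosyl-enzyme intermediate with glucose as leaving group — after which
the path forks: water attacks (hydrolysis, IM2→TS2→PC2) or a sugar
acceptor attacks (transglycosylation, IM3→TS3→PC3). The second-half
species do not share a chemical composition with the first, so their
absolute energies cannot simply be subtracted from RC's. Two stitching
procedures are provided:

* **dissociation-junction stitching** (`stitch_bras`) — the second half's
  reference state is placed at an offset relative to RC, conventionally
  decomposed as ΔE(IM1 rel RC) + ΔG_diss of the departing leaving group
  between a protein-like and a water-like dielectric continuum;
* **composition-balanced ledger stitching** (`stitch_balanced`) — each
  state is augmented with auxiliary free molecules (waters, free sugars)
  until every compared state has the same atomic composition, after which
  plain energy differences are meaningful.

Derived quantities — overall activation/reaction energies relative to
RC = 0, step-level selectivity ΔΔE, and the rate-limiting step — live here
too.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .constants import hartree_to_kcalmol
from .energy_io import SpeciesEnergy, canonical_label
from .profile_core import ElementaryStep

__all__ = [
    "JunctionSpec",
    "ProfilePoint",
    "WholeProfile",
    "BalancedLedger",
    "stitch_bras",
    "stitch_balanced",
    "merge_branches",
    "calibrate_junction_offset",
    "overall_barrier",
    "overall_reaction_energy",
    "selectivity_dd",
    "rate_limiting_step",
]

COMMON_BRANCH = "common"


@dataclass(frozen=True)
class JunctionSpec:
    """Placement of a second half-reaction's reference state relative to RC.

    Either give ``offset_kcal`` directly, or give ``components`` as a
    mapping (conventionally ``{"dE_im1_rel_rc": ..., "dG_diss": ...}``)
    whose values sum to the offset. When both are given they must agree
    exactly.
    """

    donor_species: str
    acceptor_reference: str
    offset_kcal: float | None = None
    components: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.offset_kcal is None and self.components is None:
            raise ValueError("JunctionSpec needs offset_kcal or components")
        if self.components is not None:
            total = sum(self.components.values())
            if self.offset_kcal is None:
                object.__setattr__(self, "offset_kcal", total)
            elif self.offset_kcal != total:
                raise ValueError(
                    f"offset_kcal={self.offset_kcal} != sum(components)={total}"
                )
        object.__setattr__(self, "donor_species", canonical_label(self.donor_species))
        object.__setattr__(
            self, "acceptor_reference", canonical_label(self.acceptor_reference)
        )


@dataclass(frozen=True)
class ProfilePoint:
    label: str
    branch: str
    energy_kcal: float
    is_ts: bool = False


@dataclass
class WholeProfile:
    """A stitched catalytic-cycle profile relative to RC = 0.

    ``points`` are in mechanistic order within each branch; branch tags are
    ``common`` for the shared glycosylation segment and the branch names
    (e.g. ``hydrolysis``, ``transfructosylation``) after the fork.
    """

    points: list[ProfilePoint]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        rc = [p for p in self.points if p.branch == COMMON_BRANCH]
        if rc and rc[0].energy_kcal != 0.0:
            raise ValueError(
                f"profile origin {rc[0].label} must sit at exactly 0, "
                f"got {rc[0].energy_kcal}"
            )

    @property
    def branches(self) -> list[str]:
        seen: list[str] = []
        for p in self.points:
            if p.branch != COMMON_BRANCH and p.branch not in seen:
                seen.append(p.branch)
        return seen

    def branch_points(self, branch: str) -> list[ProfilePoint]:
        if branch not in self.branches and branch != COMMON_BRANCH:
            raise KeyError(f"no branch {branch!r}; have {self.branches}")
        return [p for p in self.points if p.branch == branch]

    def common_points(self) -> list[ProfilePoint]:
        return [p for p in self.points if p.branch == COMMON_BRANCH]

    def energy(self, label: str, branch: str | None = None) -> float:
        label = canonical_label(label)
        for p in self.points:
            if p.label == label and (branch is None or p.branch == branch):
                return p.energy_kcal
        raise KeyError(f"no point {label!r} (branch={branch!r}) in profile")


def stitch_bras(
    first_half: ElementaryStep,
    second_half: ElementaryStep,
    junction: JunctionSpec,
    branch: str | None = None,
    provenance: Mapping | None = None,
) -> WholeProfile:
    """Stitch one second-half branch onto the common first half.

    The common segment carries ``first_half``'s relative energies (RC at
    exactly 0). Every second-half species ``s`` is placed at
    ``junction.offset_kcal + rel(s vs junction.acceptor_reference)``.

    Raises
    ------
    KeyError
        If the junction references a species absent from either half.
    """
    if junction.donor_species not in first_half.relative_kcal:
        raise KeyError(
            f"junction donor {junction.donor_species!r} not in first half "
            f"{sorted(first_half.relative_kcal)}"
        )
    if junction.acceptor_reference not in second_half.relative_kcal:
        raise KeyError(
            f"junction acceptor reference {junction.acceptor_reference!r} not in "
            f"second half {sorted(second_half.relative_kcal)}"
        )
    acc_ref = second_half.relative_kcal[junction.acceptor_reference]
    branch = branch or second_half.name
    points = [
        ProfilePoint(s.label, COMMON_BRANCH, first_half.relative_kcal[s.label],
                     is_ts=(s is first_half.ts))
        for s in first_half.species
    ]
    points += [
        ProfilePoint(
            s.label,
            branch,
            junction.offset_kcal + (second_half.relative_kcal[s.label] - acc_ref),
            is_ts=(s is second_half.ts),
        )
        for s in second_half.species
    ]
    prov = dict(provenance or {})
    prov.setdefault("procedure", "dissociation-junction")
    prov.setdefault("model", first_half.reactant.model)
    prov.setdefault("method", "/".join(first_half.reactant.method))
    return WholeProfile(points=points, provenance=prov)


def merge_branches(*profiles: WholeProfile) -> WholeProfile:
    """Merge stitched profiles that share an identical common segment."""
    if not profiles:
        raise ValueError("nothing to merge")
    base = profiles[0]
    common = [(p.label, p.energy_kcal) for p in base.common_points()]
    points = list(base.points)
    for other in profiles[1:]:
        if [(p.label, p.energy_kcal) for p in other.common_points()] != common:
            raise ValueError("profiles disagree on the common segment")
        points += [p for p in other.points if p.branch != COMMON_BRANCH]
    return WholeProfile(points=points, provenance=dict(base.provenance))


def calibrate_junction_offset(
    target_overall_barrier: float, step_barrier: float
) -> float:
    """Offset that places a branch TS at a known overall barrier.

    Inverts the stitching identity: offset = overall − step barrier. Useful
    for reconstructing profiles from published overall/step barrier pairs
    when the junction components were not printed.
    """
    return target_overall_barrier - step_barrier


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse a simple Hill-style molecular formula (no parentheses)."""
    counts: Counter = Counter()
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        consumed += len(m.group(0))
        counts[m.group(1)] += int(m.group(2) or 1)
    if consumed != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class BalancedLedger:
    """Auxiliary molecules added per state to equalise atomic composition.

    ``auxiliaries`` maps a state label to a list of
    ``(aux_label, energy_au, count)`` entries. ``formulas`` optionally maps
    every state label and auxiliary label to a molecular formula; when
    given, the net composition of each balanced state is checked against
    the reference and a mismatch is an error listing the deficit.
    """

    auxiliaries: Mapping[str, Sequence[tuple[str, float, int]]]
    formulas: Mapping[str, str] | None = None

    def aux_energy(self, state_label: str) -> float:
        """Total auxiliary energy (hartree) attached to a state."""
        return sum(
            e * n for (_, e, n) in self.auxiliaries.get(state_label, ())
        )

    def net_composition(self, state_label: str) -> Counter | None:
        if self.formulas is None:
            return None
        if state_label not in self.formulas:
            raise KeyError(f"no formula declared for state {state_label!r}")
        total = Counter(parse_formula(self.formulas[state_label]))
        for aux_label, _, count in self.auxiliaries.get(state_label, ()):
            aux = parse_formula(self.formulas[aux_label])
            for el, n in aux.items():
                total[el] += n * count
        return total


def stitch_balanced(
    states: Iterable[SpeciesEnergy],
    ledger: BalancedLedger,
    reference_state: str,
    branch_of: Mapping[str, str] | None = None,
    provenance: Mapping | None = None,
) -> WholeProfile:
    """Composition-balanced stitching: one energy axis via auxiliary species.

    Each state's energy is ``E(state) + Σ aux(state)`` and the profile is
    the difference to the balanced reference, converted to kcal/mol:

        energy(s) = 627.5095 · ([E(s)+Σaux(s)] − [E(ref)+Σaux(ref)])

    When the ledger declares formulas, every balanced state's net atomic
    composition must equal the reference's; a mismatch raises with the
    per-element deficit.

    Parameters
    ----------
    states : iterable of SpeciesEnergy
        All stationary points of the cycle, mechanistic order preserved.
    ledger : BalancedLedger
        Auxiliary species and (optionally) formulas.
    reference_state : str
        Label pinned at 0 (normally RC).
    branch_of : mapping, optional
        Label → branch tag; defaults to ``common`` for every state.
    """
    pool = list(states)
    reference_state = canonical_label(reference_state)
    by_label = {s.label: s for s in pool}
    if reference_state not in by_label:
        raise KeyError(f"reference state {reference_state!r} not among supplied states")
    ref = by_label[reference_state]
    ref_total = ref.energy_au + ledger.aux_energy(ref.label)

    ref_comp = ledger.net_composition(ref.label)
    if ref_comp is not None:
        for s in pool:
            comp = ledger.net_composition(s.label)
            if comp != ref_comp:
                deficit = {
                    el: comp.get(el, 0) - ref_comp.get(el, 0)
                    for el in set(comp) | set(ref_comp)
                    if comp.get(el, 0) != ref_comp.get(el, 0)
                }
                raise ValueError(
                    f"state {s.label!r} composition differs from reference after "
                    f"balancing; deficit (state - reference): {deficit}"
                )

    branch_of = dict(branch_of or {})
    points = []
    for s in pool:
        if s.label == reference_state:
            e = 0.0
        else:
            e = hartree_to_kcalmol(
                (s.energy_au + ledger.aux_energy(s.label)) - ref_total
            )
        points.append(
            ProfilePoint(
                s.label,
                branch_of.get(s.label, COMMON_BRANCH),
                e,
                is_ts=s.label.upper().startswith("TS"),
            )
        )
    prov = dict(provenance or {})
    prov.setdefault("procedure", "composition-balanced")
    return WholeProfile(points=points, provenance=prov)


def _branch_ts(profile: WholeProfile, branch: str) -> ProfilePoint:
    candidates = [p for p in profile.branch_points(branch) if p.is_ts]
    if not candidates:
        raise ValueError(f"branch {branch!r} has no transition state")
    if len(candidates) > 1:
        raise ValueError(f"branch {branch!r} has {len(candidates)} TSs; expected one")
    return candidates[0]


def overall_barrier(
    profile: WholeProfile, branch: str, mode: str = "branch_ts"
) -> float:
    """Overall activation energy of a branch relative to RC = 0.

    ``mode="branch_ts"`` (default) returns the branch's own TS height —
    the convention of published overall-barrier tables. ``mode="span"``
    returns the energetic-span variant: the highest TS along the path
    (common segment + branch) minus the lowest preceding point.
    """
    if mode == "branch_ts":
        return _branch_ts(profile, branch).energy_kcal
    if mode == "span":
        path = profile.common_points() + profile.branch_points(branch)
        best = None
        for i, p in enumerate(path):
            if not p.is_ts:
                continue
            floor = min(q.energy_kcal for q in path[: i + 1] if not q.is_ts)
            span = p.energy_kcal - floor
            best = span if best is None else max(best, span)
        if best is None:
            raise ValueError(f"no TS found on path to branch {branch!r}")
        return best
    raise ValueError(f"unknown mode {mode!r}")


def overall_reaction_energy(profile: WholeProfile, branch: str) -> float:
    """Branch product-complex energy relative to RC = 0."""
    non_ts = [p for p in profile.branch_points(branch) if not p.is_ts]
    products = [p for p in non_ts if p.label.upper().startswith("PC")]
    if not products:
        if not non_ts:
            raise ValueError(f"branch {branch!r} has no product state")
        products = [non_ts[-1]]
    return products[-1].energy_kcal


def selectivity_dd(
    barrier_hydrolysis: float, barrier_transfructosylation: float
) -> float:
    """Step-level selectivity ΔΔE = ΔE₃ − ΔE₂.

    Positive means transglycosylation is harder than hydrolysis at the
    deglycosylation step.
    """
    return barrier_transfructosylation - barrier_hydrolysis


def rate_limiting_step(
    profile: WholeProfile, branch: str, tie_tol: float = 0.0
) -> tuple[list[str], float]:
    """Highest-TS step along a branch's path from RC.

    Returns ``(ts_labels, height)``: the TS label(s) sitting highest
    relative to RC on the common-segment-plus-branch path, and that
    height. Ties (within ``tie_tol``) are reported as a multi-element
    list, not broken silently.
    """
    path = profile.common_points() + profile.branch_points(branch)
    ts_points = [p for p in path if p.is_ts]
    if len(ts_points) < 2:
        raise ValueError(
            f"rate-limiting comparison needs >=2 TSs on the path, got {len(ts_points)}"
        )
    top = max(p.energy_kcal for p in ts_points)
    winners = [p.label for p in ts_points if top - p.energy_kcal <= tie_tol]
    return winners, top
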