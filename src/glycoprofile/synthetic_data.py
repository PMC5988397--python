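"""Ground-truth generators and packaged reference fixtures.

Everything the test suite consumes is either generated here with known
content — species-energy sets with prescribed barriers and offsets,
Gaussian-dialect logs with known frequency content — or shipped as a small
text fixture transcribing a published reference table.

The cycle generator writes absolute energies near the magnitudes of real
cluster-model calculations (≈ −6000 hartree) on purpose: differences of
~20 kcal/mol between such numbers sit at catastrophic-cancellation scale,
which is exactly the arithmetic regime the relative-energy pipeline must
survive.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import HARTREE_TO_KCALMOL
from .energy_io import QCRecord, SpeciesEnergy

__all__ = [
    "CycleBlueprint",
    "make_cycle_energies",
    "write_qc_log",
    "packaged_fixtures",
]


@dataclass(frozen=True)
class CycleBlueprint:
    """Prescription for a synthetic two-branch catalytic cycle.

    All energies in kcal/mol. ``de1/de2/de3`` are the step barriers
    (TS rel step reactant), ``rxn2/rxn3`` the step reaction energies
    (PC rel step reactant), ``de_im1`` the covalent-intermediate energy
    relative to RC, and ``dg_diss`` the leaving-group dissociation
    correction. Base absolute energies (hartree) differ per composition so
    the three steps cannot be compared without stitching. ``noise_kcal``
    is the standard deviation of independent Gaussian perturbations on
    each absolute energy.
    """

    de1: float = 17.5
    de2: float = 17.6
    de3: float = 23.0
    de_im1: float = 0.1
    dg_diss: float = 3.1
    rxn2: float = -13.0
    rxn3: float = 8.3
    base_fruct_au: float = -6018.936815
    base_hyd_au: float = -5943.226656
    base_trans_au: float = -6094.608459
    noise_kcal: float = 0.0
    seed: int = 0
    functional: str = "B3LYP"
    basis: str = "6-311+G(2d,2p)"
    solvent: str = "CPCM(eps=80)"
    model: str = "QM2"

    def __post_init__(self):
        if self.noise_kcal < 0:
            raise ValueError(f"noise_kcal must be >= 0, got {self.noise_kcal}")

    def junction_offset(self) -> float:
        """Offset of IM2/IM3 relative to RC implied by the prescription."""
        return self.de_im1 + self.dg_diss


def make_cycle_energies(blueprint: CycleBlueprint) -> list[SpeciesEnergy]:
    """Generate absolute species energies realising a blueprint.

    The nine stationary points of the two-branch cycle are constructed so
    that each step's internal differences equal the prescribed values
    (plus Gaussian noise when ``noise_kcal > 0``). The three steps use
    distinct base energies — different chemical compositions — so only
    stitching can put them on one axis. Deterministic for a fixed
    (blueprint, seed).
    """
    b = blueprint
    k = HARTREE_TO_KCALMOL
    layout = [
        ("RC", "fructosylation", b.base_fruct_au, 0.0),
        ("TS1", "fructosylation", b.base_fruct_au, b.de1),
        ("IM1", "fructosylation", b.base_fruct_au, b.de_im1),
        ("IM2", "hydrolysis", b.base_hyd_au, 0.0),
        ("TS2", "hydrolysis", b.base_hyd_au, b.de2),
        ("PC2", "hydrolysis", b.base_hyd_au, b.rxn2),
        ("IM3", "transfructosylation", b.base_trans_au, 0.0),
        ("TS3", "transfructosylation", b.base_trans_au, b.de3),
        ("PC3", "transfructosylation", b.base_trans_au, b.rxn3),
    ]
    rng = np.random.default_rng(b.seed)
    noise_au = rng.normal(0.0, b.noise_kcal / k, size=len(layout)) if b.noise_kcal else np.zeros(len(layout))
    return [
        SpeciesEnergy(
            label=label,
            step=step,
            model=b.model,
            functional=b.functional,
            basis=b.basis,
            solvent=b.solvent,
            energy_au=base + rel / k + float(eps),
            charge=-2,
        )
        for (label, step, base, rel), eps in zip(layout, noise_au)
    ]


def write_qc_log(record: QCRecord, destination=None) -> str:
    """Emit a Gaussian-dialect text log for a :class:`QCRecord`.

    The output re-parses bit-compatibly on all populated fields (the
    round-trip contract with ``parse_qc_log``). Absent fields produce no
    section; imaginary modes are written as negative wavenumbers.
    """
    lines: list[str] = []
    if record.atom_count is not None:
        lines.append(f" NAtoms=  {record.atom_count:d}")
    lines.append(f" Charge =  0 Multiplicity = {record.multiplicity}")
    if record.dielectric is not None:
        lines.append(f" Eps=  {record.dielectric:.4f}")
    if record.final_energy_au is not None:
        lines.append(
            f" SCF Done:  E(RB3LYP) =  {record.final_energy_au:.9f}     A.U. after   11 cycles"
        )
    freqs = record.frequencies_cm1
    for i in range(0, len(freqs), 3):
        chunk = freqs[i : i + 3]
        lines.append(
            " Frequencies --  " + "  ".join(f"{f:10.4f}" for f in chunk)
        )
    if record.rotational_constants_ghz is not None:
        a, bb, c = record.rotational_constants_ghz
        lines.append(f" Rotational constants (GHZ):  {a:.7f}  {bb:.7f}  {c:.7f}")
    if record.mass_amu is not None:
        lines.append(f" Molecular mass:   {record.mass_amu:.5f} amu.")
    lines.append(f" Rotational symmetry number  {record.symmetry_number}.")
    tc = record.thermal_corrections
    if "zpe" in tc:
        lines.append(f" Zero-point correction=    {tc['zpe']:.6f}")
    if "enthalpy" in tc:
        lines.append(f" Thermal correction to Enthalpy=    {tc['enthalpy']:.6f}")
    if "gibbs" in tc:
        lines.append(
            f" Thermal correction to Gibbs Free Energy=    {tc['gibbs']:.6f}"
        )
    lines.append(" Normal termination of Gaussian 09")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text, encoding="utf-8")
    return text


def packaged_fixtures() -> dict[str, Path]:
    """Paths of the packaged reference-table fixtures.

    Keys: ``table2_qm3_absolute`` (absolute electronic energies, hartree,
    QM3 model), ``table2_relative_all_models`` (relative energies per
    cluster model, CPCM and gas columns), ``table3_barriers`` (per-
    functional step barriers and ΔΔE), ``table5_bras`` (per-functional
    ΔG_diss and overall activation/reaction energies from dissociation-
    junction stitching).
    """
    root = importlib.resources.files("glycoprofile") / "data"
    names = (
        "table2_qm3_absolute",
        "table2_relative_all_models",
        "table3_barriers",
        "table5_bras",
    )
    return {name: Path(str(root / f"{name}.tsv")) for name in names}
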