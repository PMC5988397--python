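"""Readers and writers for the package's external representations.

Three formats live here:

* **species-energy tables** — delimiter-separated text with a fixed header
  (``label, step, model, functional, basis, solvent, energy_au, charge``),
  one stationary point per row, energies in hartree;
* **quantum-chemistry text logs** — the Gaussian textual dialect
  (``SCF Done:`` energy lines, ``Frequencies --`` triplet blocks, thermal
  correction lines). Other programs' dialects are out of scope; users
  convert those to the species table instead;
* **profile documents** — YAML with an explicit schema version, carrying a
  stitched whole profile so it can be exchanged and re-plotted.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import yaml

PROFILE_SCHEMA_VERSION = 1

#: Published tables use "ES" and "RC" interchangeably for the reactant
#: complex of the glycosylation step; one canonical label is used internally.
LABEL_SYNONYMS: Mapping[str, str] = {"ES": "RC"}

REQUIRED_COLUMNS = (
    "label",
    "step",
    "model",
    "functional",
    "basis",
    "solvent",
    "energy_au",
)


class TableSchemaError(ValueError):
    """A species-energy table is missing a required column."""


class DuplicateSpeciesError(ValueError):
    """Two rows share (label, step, model, method)."""


class RowParseError(ValueError):
    """A table row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class LogParseError(ValueError):
    """A quantum-chemistry log could not be parsed."""


def canonical_label(label: str) -> str:
    """Map species-label synonyms (ES ≡ RC) onto one canonical name."""
    return LABEL_SYNONYMS.get(label, label)


@dataclass(frozen=True)
class SpeciesEnergy:
    """One stationary point's absolute electronic energy plus metadata.

    Parameters
    ----------
    label : str
        Species identifier (RC/ES, TS1, IM1, IM2, TS2, PC2, IM3, TS3, PC3
        for the fructosyltransferase cycle; synonyms are canonicalised).
    step : str
        Elementary-step identifier, e.g. ``fructosylation``, ``hydrolysis``
        or ``transfructosylation``.
    model : str
        Cluster-model identifier (QM1/QM2/QM3).
    functional, basis, solvent : str
        Level of theory; together they form the method key.
    energy_au : float
        Absolute electronic energy in hartree. Must be finite.
    charge : int or None
        Total charge of the cluster model, if declared.
    """

    label: str
    step: str
    model: str
    functional: str
    basis: str
    solvent: str
    energy_au: float
    charge: int | None = None

    def __post_init__(self):
        if not math.isfinite(self.energy_au):
            raise ValueError(
                f"energy_au must be finite for {self.label}, got {self.energy_au!r}"
            )
        object.__setattr__(self, "label", canonical_label(self.label))

    @property
    def method(self) -> tuple[str, str, str]:
        """(functional, basis, solvent) triple identifying the level of theory."""
        return (self.functional, self.basis, self.solvent)

    @property
    def key(self) -> tuple:
        return (self.label, self.step, self.model, self.method)


@dataclass
class QCRecord:
    """Parsed content of one quantum-chemistry log.

    ``final_energy_au`` is the last SCF energy in the file (the final SCF
    of an optimisation or single point is authoritative). Imaginary modes
    are encoded as negative wavenumbers. ``thermal_corrections`` holds the
    printed ZPE/enthalpy/Gibbs corrections in hartree when present.
    """

    final_energy_au: float | None = None
    frequencies_cm1: list[float] = field(default_factory=list)
    thermal_corrections: dict[str, float] = field(default_factory=dict)
    dielectric: float | None = None
    mass_amu: float | None = None
    rotational_constants_ghz: tuple[float, float, float] | None = None
    symmetry_number: int = 1
    multiplicity: int = 1
    atom_count: int | None = None

    def __post_init__(self):
        if self.dielectric is not None and self.dielectric <= 1.0:
            raise ValueError(
                f"a declared continuum dielectric must exceed 1, got {self.dielectric}"
            )
        if self.atom_count is not None:
            nmax = max(3 * self.atom_count - 5, 0)
            if len(self.frequencies_cm1) > nmax:
                raise ValueError(
                    f"{len(self.frequencies_cm1)} frequencies exceeds 3N-5={nmax} "
                    f"for {self.atom_count} atoms"
                )


def _open_text(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_species_table(source) -> list[SpeciesEnergy]:
    """Load a species-energy table from a TSV/CSV path or text stream.

    The header must declare at least the columns
    ``label step model functional basis solvent energy_au``; a ``charge``
    column is optional. Cell whitespace is stripped, so re-serialising with
    different column spacing loads identically. Row order is preserved.

    Raises
    ------
    TableSchemaError
        If a required column is absent.
    DuplicateSpeciesError
        If two rows share (label, step, model, method).
    RowParseError
        If an energy (or charge) cell does not parse, with its line number.
    """
    stream, should_close = _open_text(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()

    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise TableSchemaError("empty table: no header line found")

    header_no, header_line = content[0]
    delim = _sniff_delimiter(header_line)
    columns = [c.strip() for c in header_line.split(delim)]
    for required in REQUIRED_COLUMNS:
        if required not in columns:
            raise TableSchemaError(f"missing required column: {required!r}")
    idx = {c: i for i, c in enumerate(columns)}

    records: list[SpeciesEnergy] = []
    seen: set[tuple] = set()
    for line_no, line in content[1:]:
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) < len(REQUIRED_COLUMNS):
            raise RowParseError(
                f"expected at least {len(REQUIRED_COLUMNS)} cells, got {len(cells)}",
                line_no,
            )

        def cell(name: str) -> str:
            return cells[idx[name]] if idx[name] < len(cells) else ""

        try:
            energy = float(cell("energy_au"))
        except ValueError:
            raise RowParseError(
                f"unparseable energy_au: {cell('energy_au')!r}", line_no
            ) from None
        charge: int | None = None
        if "charge" in idx and cell("charge") not in ("", "NA", "None"):
            try:
                charge = int(cell("charge"))
            except ValueError:
                raise RowParseError(
                    f"unparseable charge: {cell('charge')!r}", line_no
                ) from None
        rec = SpeciesEnergy(
            label=cell("label"),
            step=cell("step"),
            model=cell("model"),
            functional=cell("functional"),
            basis=cell("basis"),
            solvent=cell("solvent"),
            energy_au=energy,
            charge=charge,
        )
        if rec.key in seen:
            raise DuplicateSpeciesError(
                f"duplicate species entry {rec.label}/{rec.step}/{rec.model}/"
                f"{'-'.join(rec.method)} at line {line_no}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def write_species_table(records: Iterable[SpeciesEnergy], destination) -> None:
    """Write records as a TSV with the canonical header (inverse of load)."""
    stream, should_close = (
        (destination, False)
        if hasattr(destination, "write")
        else (open(destination, "w", encoding="utf-8"), True)
    )
    try:
        stream.write("\t".join(REQUIRED_COLUMNS + ("charge",)) + "\n")
        for r in records:
            charge = "" if r.charge is None else str(r.charge)
            stream.write(
                f"{r.label}\t{r.step}\t{r.model}\t{r.functional}\t{r.basis}\t"
                f"{r.solvent}\t{r.energy_au:.6f}\t{charge}\n"
            )
    finally:
        if should_close:
            stream.close()


_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_FREQ_RE = re.compile(r"^\s*Frequencies\s*--\s*(.*)$")
_ZPE_RE = re.compile(r"Zero-point correction=\s*(-?\d+\.\d+)")
_H_RE = re.compile(r"Thermal correction to Enthalpy=\s*(-?\d+\.\d+)")
_G_RE = re.compile(r"Thermal correction to Gibbs Free Energy=\s*(-?\d+\.\d+)")
_EPS_RE = re.compile(r"Eps=\s*(\d+\.?\d*)")
_MASS_RE = re.compile(r"Molecular mass:\s*(-?\d+\.\d+)\s*amu")
_ROT_RE = re.compile(r"Rotational constants \(GHZ\):\s*(\S+)\s+(\S+)\s+(\S+)")
_SYM_RE = re.compile(r"Rotational symmetry number\s+(\d+)")
_MULT_RE = re.compile(r"Multiplicity\s*=\s*(\d+)")
_NATOMS_RE = re.compile(r"NAtoms=\s*(\d+)")


def parse_qc_log(source) -> QCRecord:
    """Parse a Gaussian-dialect text log into a :class:`QCRecord`.

    The last ``SCF Done:`` energy wins. Frequency triplets are concatenated
    in file order; absent sections yield empty/absent fields rather than
    errors. A log with no energy line at all is a :class:`LogParseError`,
    as is a malformed frequency line (reported with its line number).
    """
    stream, should_close = _open_text(source)
    try:
        text_lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()

    energy: float | None = None
    freqs: list[float] = []
    thermo: dict[str, float] = {}
    eps = mass = None
    rot = None
    sym = 1
    mult = 1
    natoms = None

    for line_no, line in enumerate(text_lines, start=1):
        m = _SCF_RE.search(line)
        if m:
            energy = float(m.group(1))
            continue
        m = _FREQ_RE.match(line)
        if m:
            try:
                freqs.extend(float(tok) for tok in m.group(1).split())
            except ValueError:
                raise LogParseError(
                    f"line {line_no}: malformed frequency line: {line.strip()!r}"
                ) from None
            continue
        for key, rx in (("zpe", _ZPE_RE), ("enthalpy", _H_RE), ("gibbs", _G_RE)):
            m = rx.search(line)
            if m:
                thermo[key] = float(m.group(1))
                break
        else:
            for setter, rx in (
                ("eps", _EPS_RE),
                ("mass", _MASS_RE),
                ("rot", _ROT_RE),
                ("sym", _SYM_RE),
                ("mult", _MULT_RE),
                ("natoms", _NATOMS_RE),
            ):
                m = rx.search(line)
                if not m:
                    continue
                if setter == "eps":
                    eps = float(m.group(1))
                elif setter == "mass":
                    mass = float(m.group(1))
                elif setter == "rot":
                    rot = tuple(float(g) for g in m.groups())
                elif setter == "sym":
                    sym = int(m.group(1))
                elif setter == "mult":
                    mult = int(m.group(1))
                elif setter == "natoms":
                    natoms = int(m.group(1))
                break

    if energy is None:
        raise LogParseError("no 'SCF Done:' energy line found in log")

    return QCRecord(
        final_energy_au=energy,
        frequencies_cm1=freqs,
        thermal_corrections=thermo,
        dielectric=eps,
        mass_amu=mass,
        rotational_constants_ghz=rot,
        symmetry_number=sym,
        multiplicity=mult,
        atom_count=natoms,
    )


def write_profile_document(profile, destination) -> str:
    """Serialise a stitched whole profile to schema-versioned YAML.

    Returns the YAML text; also writes it to ``destination`` (path or
    stream) when given. ``read_profile_document`` inverts it field-for-field.
    """
    doc = {
        "schema_version": PROFILE_SCHEMA_VERSION,
        "provenance": dict(profile.provenance),
        "points": [
            {
                "label": p.label,
                "branch": p.branch,
                "energy_kcal": float(p.energy_kcal),
                "is_ts": bool(p.is_ts),
            }
            for p in profile.points
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text, encoding="utf-8")
    return text


def read_profile_document(source):
    """Read a YAML profile document back into a ``WholeProfile``."""
    from .stitching import ProfilePoint, WholeProfile

    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    doc = yaml.safe_load(text)
    version = doc.get("schema_version")
    if version != PROFILE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported profile schema version {version!r} "
            f"(expected {PROFILE_SCHEMA_VERSION})"
        )
    points = [
        ProfilePoint(
            label=pt["label"],
            branch=pt["branch"],
            energy_kcal=float(pt["energy_kcal"]),
            is_ts=bool(pt.get("is_ts", False)),
        )
        for pt in doc["points"]
    ]
    return WholeProfile(points=points, provenance=dict(doc.get("provenance", {})))
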