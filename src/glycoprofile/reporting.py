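"""Comparison tables and stepped energy-profile diagrams.

Tables collect per-functional step barriers, selectivities and stitched
overall energetics into grids mirroring the shapes of published
functional-benchmark tables. Diagrams draw the conventional
reaction-profile idiom: horizontal level bars at each stationary point's
energy, joined by dashed diagonals, with both deglycosylation branches
forking from the shared glycosylation segment and RC pinned at 0.

Rounding happens only at render time (half away from zero, one decimal);
every cell remains traceable to its full-precision operation output via
the table's ``provenance`` frame. Rendering is deterministic: no
timestamps, fixed ordering, colors assigned by functional-name hash.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "glycoprofile"  # reproducible SVG ids
matplotlib.rcParams["svg.fonttype"] = "none"  # keep labels as readable text
import matplotlib.pyplot as plt
import pandas as pd

from .constants import round_half_away
from .profile_core import ElementaryStep, step_barrier, step_reaction_energy
from .stitching import (
    COMMON_BRANCH,
    WholeProfile,
    overall_barrier,
    overall_reaction_energy,
    selectivity_dd,
)

__all__ = [
    "ComparisonTable",
    "functional_comparison",
    "export_table",
    "render_profile_diagram",
]


@dataclass
class ComparisonTable:
    """A functional (or species) × quantity grid in kcal/mol.

    ``provenance`` holds the full-precision values; ``rounded()`` applies
    the single display-rounding step. Rows with missing cells are kept and
    flagged in ``incomplete``, never dropped silently.
    """

    provenance: pd.DataFrame
    title: str = ""
    ndigits: int = 1
    incomplete: list[str] = field(default_factory=list)

    def rounded(self) -> pd.DataFrame:
        return self.provenance.map(
            lambda v: round_half_away(v, self.ndigits) if pd.notna(v) else v
        )


def functional_comparison(
    steps: Mapping[str, Mapping[str, ElementaryStep]],
    profiles: Mapping[str, WholeProfile] | None = None,
    dg_diss: Mapping[str, float] | None = None,
) -> tuple[ComparisonTable, ComparisonTable | None]:
    """Build step-barrier and stitched-profile comparison grids.

    Parameters
    ----------
    steps : mapping functional → {step name → ElementaryStep}
        Step names ``fructosylation``, ``hydrolysis``,
        ``transfructosylation``. Missing steps flag the row as incomplete.
    profiles : mapping functional → stitched WholeProfile, optional
        When given, a second grid with ΔG_diss and per-branch overall
        activation/reaction energies is produced.
    dg_diss : mapping functional → ΔG_diss (kcal/mol), optional

    Returns
    -------
    (barriers_table, overall_table)
        ``barriers_table`` has columns ΔE1, ΔE2, ΔE3, ΔΔE;
        ``overall_table`` (or None) has ΔG_diss plus activation/reaction
        energies for each branch.
    """
    if not steps:
        raise ValueError("need at least one functional")
    rows = {}
    incomplete = []
    for functional, per_step in steps.items():
        row = {}
        for col, key in (
            ("dE1", "fructosylation"),
            ("dE2", "hydrolysis"),
            ("dE3", "transfructosylation"),
        ):
            row[col] = (
                step_barrier(per_step[key]) if key in per_step else float("nan")
            )
        if pd.notna(row["dE2"]) and pd.notna(row["dE3"]):
            row["ddE"] = selectivity_dd(row["dE2"], row["dE3"])
        else:
            row["ddE"] = float("nan")
        if any(pd.isna(v) for v in row.values()):
            incomplete.append(functional)
        rows[functional] = row
    barriers = ComparisonTable(
        provenance=pd.DataFrame.from_dict(rows, orient="index")[
            ["dE1", "dE2", "dE3", "ddE"]
        ],
        title="Step barriers and selectivity (kcal/mol)",
        incomplete=incomplete,
    )

    overall = None
    if profiles:
        orow = {}
        oincomplete = []
        for functional, profile in profiles.items():
            r = {"dG_diss": (dg_diss or {}).get(functional, float("nan"))}
            for branch in ("hydrolysis", "transfructosylation"):
                try:
                    r[f"act_{branch}"] = overall_barrier(profile, branch)
                    r[f"rxn_{branch}"] = overall_reaction_energy(profile, branch)
                except (KeyError, ValueError):
                    r[f"act_{branch}"] = float("nan")
                    r[f"rxn_{branch}"] = float("nan")
            if any(pd.isna(v) for v in r.values()):
                oincomplete.append(functional)
            orow[functional] = r
        overall = ComparisonTable(
            provenance=pd.DataFrame.from_dict(orow, orient="index"),
            title="Overall energetics relative to RC (kcal/mol)",
            incomplete=oincomplete,
        )
    return barriers, overall


def export_table(table: ComparisonTable, fmt: str = "csv") -> str:
    """Serialise a comparison table to ``csv``, ``tsv`` or ``markdown``.

    Delimiter-separated exports carry the rounded display values;
    re-parsing reproduces the provenance cells within display rounding.
    """
    df = table.rounded()
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        buf = io.StringIO()
        df.to_csv(buf, sep=sep, index_label="row")
        return buf.getvalue()
    if fmt == "markdown":
        cols = list(df.columns)
        lines = ["| row | " + " | ".join(cols) + " |",
                 "|" + "---|" * (len(cols) + 1)]
        for label, row in df.iterrows():
            cells = [
                "" if pd.isna(v) else f"{v:.{table.ndigits}f}" for v in row
            ]
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}; use csv, tsv or markdown")


def _series_color(name: str) -> str:
    digest = hashlib.sha256(name.encode()).digest()
    return "#{:02x}{:02x}{:02x}".format(
        64 + digest[0] % 128, 64 + digest[1] % 128, 64 + digest[2] % 128
    )


_LEVEL_HALFWIDTH = 0.3


def _profile_layout(profile: WholeProfile) -> dict[tuple[str, str], int]:
    """x-slot per (label, branch): common segment first, branches fork after."""
    slots: dict[tuple[str, str], int] = {}
    x = 0
    for p in profile.common_points():
        slots[(p.label, p.branch)] = x
        x += 1
    fork = x
    for branch in profile.branches:
        x = fork
        for p in profile.branch_points(branch):
            slots[(p.label, p.branch)] = x
            x += 1
    return slots


def render_profile_diagram(
    profiles: Sequence[WholeProfile] | WholeProfile,
    destination=None,
    labels: Sequence[str] | None = None,
) -> str:
    """Render stepped level diagrams for one or more whole profiles.

    Returns the SVG text (and writes it to ``destination`` when given).
    Output is deterministic for fixed input: fixed ordering, hashed series
    colors, no embedded timestamps.
    """
    if isinstance(profiles, WholeProfile):
        profiles = [profiles]
    if not profiles or any(not p.points for p in profiles):
        raise ValueError("cannot render an empty profile")
    if labels is None:
        labels = [
            str(p.provenance.get("method", f"profile {i+1}"))
            for i, p in enumerate(profiles)
        ]

    fig, ax = plt.subplots(figsize=(8, 5))
    branch_style = {COMMON_BRANCH: "-"}
    for i, (profile, series) in enumerate(zip(profiles, labels)):
        color = _series_color(series)
        slots = _profile_layout(profile)
        for (label, branch), x in sorted(slots.items(), key=lambda kv: kv[1]):
            e = profile.energy(label, branch)
            ax.hlines(e, x - _LEVEL_HALFWIDTH, x + _LEVEL_HALFWIDTH,
                      color=color, lw=2)
            ax.annotate(
                f"{label} {round_half_away(e, 1):.1f}",
                (x, e), textcoords="offset points", xytext=(0, 5),
                ha="center", fontsize=7, color=color,
            )
        # dashed connectors along each branch path
        for branch in profile.branches:
            path = profile.common_points() + profile.branch_points(branch)
            for a, b in zip(path, path[1:]):
                xa = slots[(a.label, a.branch)]
                xb = slots[(b.label, b.branch)]
                ax.plot(
                    [xa + _LEVEL_HALFWIDTH, xb - _LEVEL_HALFWIDTH],
                    [a.energy_kcal, b.energy_kcal],
                    linestyle="--", lw=0.8, color=color,
                )
        ax.plot([], [], color=color, label=series)

    ax.axhline(0.0, color="0.8", lw=0.5, zorder=0)
    ax.set_ylabel("energy relative to RC (kcal/mol)")
    ax.set_xticks([])
    if len(profiles) > 1:
        ax.legend(fontsize=8)
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(svg)
        else:
            Path(destination).write_text(svg, encoding="utf-8")
    return svg
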