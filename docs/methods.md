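# Methods

## Scope and model

The package post-processes single-point electronic energies of
stationary points from QM cluster models of a glycosidase /
fructosyltransferase active site. It never computes wavefunctions: the
inputs are absolute energies (hartree) tagged by species, elementary
step, cluster model and level of theory, plus (for the thermochemistry
path) Gaussian-dialect text logs carrying harmonic frequencies. The
outputs are relative-energy profiles, barriers, selectivities and
comparison reports in kcal/mol.

The catalytic cycle is the two-branch retaining mechanism: a common
glycosylation step RC → TS1 → IM1 forming the covalent glycosyl-enzyme
intermediate, then either hydrolysis IM2 → TS2 → PC2 or
transglycosylation IM3 → TS3 → PC3. The branch topology is declarative
(states, steps, branches, junction), so other two-branch cycles are
expressible; the labels RC/ES, TS*n*, IM*n*, PC*n* are a controlled
vocabulary with ES mapped to the canonical RC.

## Relative-energy arithmetic

Within one elementary step all species share a chemical composition, so
relative energies are plain differences:
ΔE(s) = 627.5095 · (E(s) − E(ref)) kcal/mol, the reference being the
step's initial state and *assigned* exactly 0 rather than computed, so
it cannot pick up cancellation noise. The conversion constant is the
7-digit literature value 627.5095 kcal·mol⁻¹/hartree; it reproduces all
six packaged reference relative energies at their printed precision.
Absolute energies near −6000 hartree differenced to ~20 kcal/mol sit at
catastrophic-cancellation scale by construction; double precision leaves
~10⁻⁹ kcal/mol of headroom, which the zero-noise recovery test pins.

Display rounding is half-away-from-zero to one decimal, applied only at
render time and acting on the shortest decimal repr (so a value printed
as 18.55 rounds to 18.6 despite its binary image sitting just under the
half). All internal arithmetic is full precision.

## Stitching across compositions

Between half-reactions the composition changes (glucose leaves; water or
an acceptor sugar arrives), so two procedures place everything on one
axis with RC = 0:

**Dissociation junction.** The second half's reference state (IM2 or
IM3) is placed at offset = ΔE(IM1 rel RC) + ΔG_diss, where ΔG_diss is
the leaving glucose's Gibbs-energy change between a protein-like (ε = 4)
and a water-like (ε = 80) continuum. ΔG_diss is oriented as
G(ε_low) − G(ε_high) and applied as an increment at the junction; its
sign is whatever the inputs give. A `JunctionSpec` accepts either the
raw offset or its two components (which must sum exactly). When the
published per-branch overall barriers are available but the junction
components are not, `calibrate_junction_offset` inverts the stitching
identity (offset = overall − step barrier) on one branch; the same
offset then predicts the other branch, which is the package's
consistency check across the five functionals (exact for two of them,
within the 0.1 kcal/mol rounding of the printed inputs for the rest).

**Composition-balanced ledger.** Each state is augmented with auxiliary
free molecules (label, energy, count) until every compared state has the
same net formula; energies of balanced states are then directly
comparable. When formulas are declared the balance is verified and a
mismatch reports the per-element deficit. Auxiliaries present
identically on all states cancel exactly (property-tested). The ledger
mechanism is validated on hand-computed toy systems; no reference
auxiliary energies are packaged, so no literature numbers are asserted
through this route.

**Derived quantities.** The overall activation energy of a branch is its
own TS height relative to RC — the convention of published overall-barrier
tables — not an energetic-span maximum; a `mode="span"` variant (highest
TS minus the lowest preceding minimum along the path) is available but
is not the default. The rate-limiting step is the highest TS along the
common-plus-branch path, with ties reported as ties rather than broken.
ΔΔE = ΔE₃ − ΔE₂ measures step-level selectivity; because both branches
share one junction offset, overall_barrier(trans) − overall_barrier(hyd)
equals ΔΔE identically, which is asserted in unrounded arithmetic.

## RRHO thermochemistry

Standard ideal-gas rigid-rotor/harmonic-oscillator sums: ZPE = Σ ½hcν̃;
vibrational thermal energy and entropy per mode from x = hcν̃/kT;
classical rotation (nonlinear top with symmetry number σ) and
Sackur–Tetrode translation; H_corr = ZPE + E_vib + E_rot + E_trans + RT
and G_corr = H_corr − T·S, so the consistency identity holds to 10⁻⁹
kcal/mol by construction. Defaults are T = 298.15 K, P = 1 atm, scale
factor 1.0. Raw RRHO only — no quasi-RRHO damping of low modes; an
optional hard low-frequency cutoff exists, default off. Imaginary modes
(negative wavenumbers) are excluded from the vibrational sums with a
warning in lenient mode — needed when processing transition-state
records — and are an error in strict mode; an exactly zero frequency is
always an error (the sums are undefined). Correctness is established
against an independently written per-term oracle on random synthetic
molecules (agreement ≤ 10⁻⁸ kcal/mol) and by the T → 0 limit
(G_corr → ZPE within 10⁻⁶ kcal/mol at T = 10⁻⁶ K).

## I/O formats

Species tables are TSV/CSV with header
`label step model functional basis solvent energy_au charge`, energies
in hartree at ≥6 decimals (the packaged tables store exactly the six
printed decimals). Loading enforces uniqueness of
(label, step, model, method) and reports unparseable cells with their
line number. QC logs are the Gaussian textual dialect (`SCF Done:`,
`Frequencies --` triplets, thermal-correction lines, plus mass,
rotational constants, symmetry number, multiplicity); the last SCF
energy wins, matching the convention that the final SCF of a job is
authoritative. The synthetic writer emits the same dialect
bit-compatibly for values representable at the printed precision, which
the round-trip property exercises. Profile documents are YAML with an
explicit `schema_version`; diagrams are SVG with text kept as text,
deterministic ids and no timestamps, so identical inputs give
byte-identical files.

## Synthetic data

`CycleBlueprint` prescribes step barriers, the IM1 offset, ΔG_diss and
step reaction energies; `make_cycle_energies` realises them as absolute
energies near −6000/−5943/−6095 hartree with deliberately distinct base
energies per step so only stitching can join them. Noise is independent
Gaussian perturbation of each absolute energy with a kcal/mol amplitude —
the simplest model that propagates realistically through differences.
The default blueprint mirrors the B3LYP reference energetics
(ΔE₁ = 17.5, ΔE₂ = 17.6, ΔE₃ = 23.0, ΔG_diss = 3.1, offset 3.2). What
the generator does **not** emulate: correlated errors between adjacent
stationary points, basis-set or functional dependence, or geometries —
passing tests demonstrate the bookkeeping, not the quality of any DFT
result. Problem sizes in the suite (9-species cycles, 50-molecule
thermochemistry sweeps, 100-seed noise studies) keep the whole run in a
few seconds while leaving the statistics meaningful.

## Known limitations and open choices

* The per-functional ΔG_diss values in the packaged overall-energetics
  table cannot be recomputed here (the underlying frequency calculation
  exists only at B3LYP); they are fixture inputs used as junction
  components.
* Whether ΔG_diss comprises only the Gibbs-correction difference or also
  the electronic/solvation difference is left to the caller:
  `dissociation_free_energy` takes full G values, so either composition
  is expressible.
* The balanced-ledger route ships without reference auxiliary energies,
  so it is mechanism-tested only.
* Smaller-cluster (QM1/QM2) relative energies exist only as transcribed
  values — no absolute energies are available — so the size-comparison
  grid treats them as data, and the shift-invariance property is checked
  on synthetically shifted copies instead.
* Gas-phase columns in the transcribed tables are stored but not
  asserted (no gas-phase absolute energies exist to recompute them).
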