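"""Ideal-gas RRHO thermochemistry and the two-dielectric dissociation cycle.

The rigid-rotor / harmonic-oscillator (RRHO) machinery converts harmonic
frequencies plus molecular metadata into zero-point, thermal-enthalpy,
entropy and Gibbs corrections — the same quantities an electronic-structure
program prints in its thermal analysis. The dissociation free energy of a
leaving group (here, glucose departing a glycosyl-enzyme complex) is then
estimated from its Gibbs energy in a protein-like continuum (ε≈4) versus a
water-like one (ε≈80); the difference, ΔG_diss, is the junction correction
used when stitching half-reactions of differing composition.

Conventions:

* raw RRHO only — no quasi-RRHO damping of low frequencies (an optional
  hard cutoff is available, default off);
* imaginary modes (negative wavenumbers) are dropped from the vibrational
  sums with a warning in lenient mode (needed for transition-state
  records) and are an error in strict mode;
* defaults T = 298.15 K, P = 1 atm, frequency scale factor 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants as _c

from .constants import KCALMOL_PER_WAVENUMBER, R_KCALMOL, hartree_to_kcalmol

__all__ = [
    "ThermoCorrections",
    "DissociationCorrection",
    "rrho_corrections",
    "gibbs_energy",
    "dissociation_free_energy",
]

_CAL = _c.calorie  # J per thermochemical calorie


@dataclass(frozen=True)
class ThermoCorrections:
    """RRHO corrections at one temperature/pressure.

    ``zpe``, ``thermal_enthalpy`` and ``gibbs_correction`` are in kcal/mol;
    ``entropy`` is in cal/(mol·K). ``thermal_enthalpy`` follows the common
    quantum-chemistry convention: ZPE + thermal internal energy + RT, so
    ``gibbs_correction = thermal_enthalpy − T·entropy`` holds exactly.
    """

    zpe: float
    thermal_enthalpy: float
    entropy: float
    gibbs_correction: float
    temperature: float
    pressure: float

    def __post_init__(self):
        if self.zpe < 0:
            raise ValueError(f"zpe must be >= 0, got {self.zpe}")
        residual = self.gibbs_correction - (
            self.thermal_enthalpy - self.temperature * self.entropy / 1000.0
        )
        if abs(residual) > 1e-9:
            raise ValueError(
                f"gibbs_correction inconsistent with H - T*S by {residual:g} kcal/mol"
            )


@dataclass(frozen=True)
class DissociationCorrection:
    """ΔG_diss between a low- and a high-dielectric continuum environment.

    ``delta_g_diss = g_low_eps − g_high_eps`` exactly; the sign is not
    forced positive. ``eps_low < eps_high`` by convention (protein-like
    versus water-like).
    """

    g_low_eps: float
    g_high_eps: float
    eps_low: float
    eps_high: float
    delta_g_diss: float

    def __post_init__(self):
        if self.eps_low >= self.eps_high:
            raise ValueError(
                f"eps_low must be < eps_high, got {self.eps_low} >= {self.eps_high}"
            )
        if self.delta_g_diss != self.g_low_eps - self.g_high_eps:
            raise ValueError("delta_g_diss must equal g_low_eps - g_high_eps exactly")


def _vibrational_terms(
    freqs_cm1: np.ndarray, temperature: float
) -> tuple[float, float, float]:
    """Return (ZPE, thermal vibrational energy, vibrational entropy).

    kcal/mol, kcal/mol, cal/(mol K). Frequencies must be positive.
    """
    zpe = 0.5 * KCALMOL_PER_WAVENUMBER * float(freqs_cm1.sum())
    # x = h c nu / k T, dimensionless
    x = KCALMOL_PER_WAVENUMBER * freqs_cm1 / (R_KCALMOL * temperature)
    # guard exp overflow: contributions vanish for large x
    small = x < 500.0
    xs = x[small]
    expm = np.expm1(xs)
    e_vib = R_KCALMOL * temperature * float((xs / expm).sum())
    s_vib = R_KCALMOL * 1000.0 * float(
        (xs / expm - np.log1p(-np.exp(-xs))).sum()
    )
    return zpe, e_vib, s_vib


def _rotational_entropy(
    rot_ghz: tuple[float, float, float], sigma: int, temperature: float
) -> float:
    """Nonlinear-top rotational entropy, cal/(mol K)."""
    thetas = [_c.h * b * 1e9 / _c.k for b in rot_ghz]  # K
    q_rot = (
        math.sqrt(math.pi)
        / sigma
        * math.sqrt(temperature**3 / (thetas[0] * thetas[1] * thetas[2]))
    )
    return R_KCALMOL * 1000.0 * (math.log(q_rot) + 1.5)


def _translational_entropy(
    mass_amu: float, temperature: float, pressure_atm: float
) -> float:
    """Sackur–Tetrode translational entropy, cal/(mol K)."""
    m = mass_amu * _c.atomic_mass
    p = pressure_atm * _c.atm
    q_trans = (2 * math.pi * m * _c.k * temperature / _c.h**2) ** 1.5 * (
        _c.k * temperature / p
    )
    return R_KCALMOL * 1000.0 * (math.log(q_trans) + 2.5)


def rrho_corrections(
    frequencies_cm1,
    mass_amu: float,
    rotational_constants_ghz,
    symmetry_number: int = 1,
    temperature: float = 298.15,
    pressure_atm: float = 1.0,
    scale_factor: float = 1.0,
    *,
    low_freq_cutoff: float | None = None,
    strict: bool = False,
) -> ThermoCorrections:
    """Compute ideal-gas RRHO corrections from harmonic frequencies.

    Parameters
    ----------
    frequencies_cm1 : sequence of float
        Harmonic wavenumbers in cm⁻¹; negative values encode imaginary
        modes. An empty list is the single-atom limit (no vibrations).
    mass_amu : float
        Molecular mass in amu.
    rotational_constants_ghz : (float, float, float) or None
        Rotational constants in GHz for a nonlinear top; ``None`` for an
        atom (no rotational contribution).
    symmetry_number : int
        External rotational symmetry number σ.
    temperature, pressure_atm : float
        Thermodynamic state; defaults 298.15 K, 1 atm.
    scale_factor : float
        Uniform harmonic-frequency scale factor applied before the sums.
    low_freq_cutoff : float, optional
        Drop real modes below this wavenumber (off by default; the raw
        RRHO sums are the reference behaviour).
    strict : bool
        If True, any imaginary mode is an error. If False (default),
        imaginary modes are excluded with a warning — the transition-state
        convention.

    Raises
    ------
    ValueError
        On non-positive temperature, a zero frequency (RRHO undefined), or
        imaginary modes in strict mode.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    freqs = np.asarray(list(frequencies_cm1), dtype=float) * scale_factor
    if np.any(freqs == 0.0):
        raise ValueError("zero frequencies make the RRHO sums undefined")
    imaginary = freqs[freqs < 0]
    if imaginary.size:
        if strict:
            raise ValueError(
                f"imaginary modes present: {sorted(imaginary.tolist())} cm^-1"
            )
        warnings.warn(
            f"excluding {imaginary.size} imaginary mode(s) from vibrational sums",
            stacklevel=2,
        )
    real = freqs[freqs > 0]
    if low_freq_cutoff is not None:
        real = real[real >= low_freq_cutoff]

    zpe, e_vib, s_vib = _vibrational_terms(real, temperature)

    rt = R_KCALMOL * temperature
    e_trans = 1.5 * rt
    s_trans = _translational_entropy(mass_amu, temperature, pressure_atm)
    if rotational_constants_ghz is not None:
        e_rot = 1.5 * rt
        s_rot = _rotational_entropy(
            tuple(rotational_constants_ghz), symmetry_number, temperature
        )
    else:
        e_rot = 0.0
        s_rot = 0.0

    entropy = s_vib + s_rot + s_trans  # cal/(mol K)
    thermal_enthalpy = zpe + e_vib + e_rot + e_trans + rt  # H = U + pV = U + RT
    gibbs = thermal_enthalpy - temperature * entropy / 1000.0
    return ThermoCorrections(
        zpe=zpe,
        thermal_enthalpy=thermal_enthalpy,
        entropy=entropy,
        gibbs_correction=gibbs,
        temperature=temperature,
        pressure=pressure_atm,
    )


def gibbs_energy(electronic_energy_au: float, corrections: ThermoCorrections) -> float:
    """Absolute-scale Gibbs energy in kcal/mol.

    ``G = 627.5095 · E_elec + gibbs_correction``; the absolute scale only
    matters through differences, e.g. across two dielectric environments.
    """
    return hartree_to_kcalmol(electronic_energy_au) + corrections.gibbs_correction


def dissociation_free_energy(
    g_low_eps: float,
    g_high_eps: float,
    eps_low: float = 4.0,
    eps_high: float = 80.0,
) -> DissociationCorrection:
    """ΔG_diss of a leaving group between two continuum environments.

    Parameters
    ----------
    g_low_eps, g_high_eps : float
        Absolute Gibbs energies (kcal/mol) of the molecule in the
        low-dielectric (protein-like) and high-dielectric (water-like)
        continuum. ΔG_diss = G(ε_low) − G(ε_high): the correction is
        applied as an increment at the profile junction, and the sign is
        whatever the inputs give.
    eps_low, eps_high : float
        Relative permittivities; must satisfy eps_low < eps_high.
    """
    return DissociationCorrection(
        g_low_eps=g_low_eps,
        g_high_eps=g_high_eps,
        eps_low=eps_low,
        eps_high=eps_high,
        delta_g_diss=g_low_eps - g_high_eps,
    )
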