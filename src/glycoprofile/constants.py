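"""Physical constants and unit conversions.

Fundamental constants come from :mod:`scipy.constants` (CODATA). The
hartree→kcal/mol factor is pinned to the 7-digit value conventional in the
quantum-chemistry literature rather than recomputed from CODATA, so that
relative energies round to the same printed decimals as published tables.
"""

from __future__ import annotations

import math

from scipy import constants as _c

#: kcal/mol per hartree. The literature-standard 7-digit value.
HARTREE_TO_KCALMOL: float = 627.5095

#: kcal/mol per cm^-1 of harmonic wavenumber (h*c*N_A / 4184).
KCALMOL_PER_WAVENUMBER: float = (
    _c.h * _c.c * 100.0 * _c.Avogadro / _c.calorie / 1000.0
)

#: Gas constant in kcal/(mol K).
R_KCALMOL: float = _c.R / _c.calorie / 1000.0


def hartree_to_kcalmol(delta_au: float) -> float:
    """Convert an energy difference from hartree to kcal/mol.

    Parameters
    ----------
    delta_au : float
        Energy difference in hartree. Must be finite.

    Returns
    -------
    float
        ``delta_au * 627.5095`` kcal/mol. Sign is preserved exactly.

    Raises
    ------
    ValueError
        If the input is NaN or infinite.
    """
    if not math.isfinite(delta_au):
        raise ValueError(f"energy difference must be finite, got {delta_au!r}")
    return delta_au * HARTREE_TO_KCALMOL


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for display values.

    Python's built-in ``round`` is banker's rounding; published energy
    tables round 0.05 up in magnitude, so display formatting goes through
    this helper. Rounding acts on the shortest decimal repr so that a
    value written as 18.55 rounds to 18.6 even though its binary image
    sits just below the half. Internal arithmetic is never rounded.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
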