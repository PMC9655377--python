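"""Osmotic-potential calibration for PEG-6000 and NaCl stress solutions.

Germination assays impose drought and saline stress of matched intensity
by soaking seeds in iso-osmotic solutions, conventionally at -0.20 MPa.
Two standard forward models give the osmotic potential (MPa, <= 0) of a
solution, and their inverses give the solute amount needed for a target
potential:

* PEG-6000: the empirical Michel-Kaufmann polynomial in concentration
  C (g/L) and temperature T (deg C),
  ``psi = [-(1.18e-2) C - (1.18e-4) C^2 + (2.67e-4) C T + (8.39e-7) C^2 T] / 10``,
  quadratic in C at fixed T and therefore invertible in closed form.
* NaCl (any fully dissociating salt): the van't Hoff relation
  ``psi = -R T_k C_m i`` with R = 0.008314 MPa L mol^-1 K^-1, absolute
  temperature T_k = 273.15 + T, molar concentration C_m (mol/L) and
  dissociation factor i (2 for NaCl: Na+ and Cl-).

Temperatures are accepted in deg C at every interface; the Kelvin
conversion is internal.
"""

from __future__ import annotations

import math

#: Gas constant in MPa L mol^-1 K^-1.
R_MPA = 0.008314

#: van't Hoff dissociation factor for NaCl (Na+ and Cl-).
I_NACL = 2.0

#: Molar mass of NaCl, g mol^-1.
NACL_MOLAR_MASS = 58.44

# Michel-Kaufmann coefficients (psi in MPa after the /10 rescale).
_A1 = -1.18e-2   # * C
_A2 = -1.18e-4   # * C^2
_A3 = 2.67e-4    # * C * T
_A4 = 8.39e-7    # * C^2 * T

#: Upper bound on physically meaningful PEG concentrations (g/L) when
#: selecting the closed-form root.
MAX_PEG_CONC = 1000.0


def psi_peg(concentration: float, temperature_c: float) -> float:
    """Osmotic potential (MPa) of a PEG-6000 solution.

    Parameters
    ----------
    concentration : float
        PEG-6000 concentration in g/L, >= 0.
    temperature_c : float
        Solution temperature in deg C.
    """
    c = float(concentration)
    t = float(temperature_c)
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return (_A1 * c + _A2 * c * c + _A3 * c * t + _A4 * c * c * t) / 10.0


def peg_concentration_for_psi(psi: float, temperature_c: float) -> float:
    """PEG-6000 concentration (g/L) giving a target osmotic potential.

    Solves the Michel-Kaufmann polynomial, quadratic in concentration at
    fixed temperature, in closed form.  When both roots are non-negative
    the smaller (the physically relevant branch continuous with C = 0) is
    returned.

    Raises
    ------
    ValueError
        If ``psi > 0``, or no root lies in [0, 1000] g/L.
    """
    psi = float(psi)
    t = float(temperature_c)
    if psi > 0:
        raise ValueError(f"osmotic potential must be <= 0 MPa, got {psi}")
    if psi == 0:
        return 0.0
    # (a C^2 + b C)/10 = psi  ->  a C^2 + b C - 10 psi = 0
    a = _A2 + _A4 * t
    b = _A1 + _A3 * t
    const = -10.0 * psi
    if a == 0.0:
        if b == 0.0:
            raise ValueError("degenerate polynomial: no concentration dependence")
        root = -const / b
        roots = [root]
    else:
        disc = b * b - 4.0 * a * const
        if disc < 0:
            raise ValueError(
                f"no real PEG concentration attains {psi} MPa at {t} deg C"
            )
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    feasible = sorted(r for r in roots if 0.0 <= r <= MAX_PEG_CONC)
    if not feasible:
        raise ValueError(
            f"no PEG concentration in [0, {MAX_PEG_CONC}] g/L attains {psi} MPa "
            f"at {t} deg C"
        )
    return feasible[0]


def psi_vant_hoff(
    molar_concentration: float, temperature_c: float, i: float = I_NACL
) -> float:
    """Osmotic potential (MPa) of a dilute solute by the van't Hoff relation.

    ``psi = -R * (273.15 + T) * C_m * i``; exactly linear in concentration.
    """
    c = float(molar_concentration)
    if c < 0:
        raise ValueError(f"molar concentration must be >= 0, got {c}")
    if i < 1:
        raise ValueError(f"van't Hoff factor must be >= 1, got {i}")
    return -R_MPA * (273.15 + float(temperature_c)) * c * i


def nacl_concentration_for_psi(
    psi: float, temperature_c: float, molar_mass: float = NACL_MOLAR_MASS
) -> float:
    """NaCl amount (g/L) giving a target osmotic potential.

    Inverts the van't Hoff relation with i = 2 and converts mol/L to g/L
    via the molar mass (58.44 g/mol for NaCl).
    """
    molar = nacl_molar_concentration_for_psi(psi, temperature_c)
    return molar * molar_mass


def nacl_molar_concentration_for_psi(psi: float, temperature_c: float) -> float:
    """NaCl molar concentration (mol/L) giving a target osmotic potential."""
    psi = float(psi)
    if psi > 0:
        raise ValueError(f"osmotic potential must be <= 0 MPa, got {psi}")
    return -psi / (R_MPA * (273.15 + float(temperature_c)) * I_NACL)
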