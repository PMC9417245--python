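"""Physical constants and unit conversions.

Internal conventions: lengths in nm, forces in pN, energies in kT unless
stated otherwise.  PDB files carry Angstrom; conversion happens at the IO
boundary only.
"""

from __future__ import annotations

import scipy.constants as _const

#: Boltzmann constant in pN*nm/K (1 pN*nm = 1e-21 J).
KB_PN_NM = _const.k * 1e21

#: nm per Angstrom.
NM_PER_ANGSTROM = 0.1

#: nm per femtometre.
NM_PER_FM = 1e-6

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0


def kt_pn_nm(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in pN*nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_PN_NM * temperature


def spring_constant_to_kt(k_pn_per_nm: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a spring constant from pN/nm to kT/nm^2."""
    return k_pn_per_nm / kt_pn_nm(temperature)


def force_kt_to_pn(force_kt_per_nm: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a force from kT/nm to pN."""
    return force_kt_per_nm * kt_pn_nm(temperature)


def mc_step_duration(v_fm_per_step: float, pulling_speed_nm_per_s: float) -> float:
    """Physical time (s) represented by one MC step.

    The anchor recedes ``v_fm_per_step`` femtometres per MC step while
    mimicking a probe moving at ``pulling_speed_nm_per_s``; equating the two
    displacement rates fixes the implied duration of a step.
    """
    if pulling_speed_nm_per_s <= 0:
        raise ValueError("pulling speed must be positive")
    return v_fm_per_step * NM_PER_FM / pulling_speed_nm_per_s
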