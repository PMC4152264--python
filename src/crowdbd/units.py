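"""Physical constants and unit conversions.

Internal unit system: length Å, time ns, energy kcal/mol.
Diffusion coefficients are carried as Å²/ns; 1 Å²/ns = 10 µm²/s.
"""

import math

#: Boltzmann constant, kcal/mol/K
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Boltzmann constant, J/K (SI, used only inside Stokes–Einstein)
_KB_SI = 1.380649e-23

#: multiply an Å²/ns diffusion coefficient by this to get µm²/s
A2_PER_NS_TO_UM2_PER_S = 10.0


def stokes_einstein_d0(radius: float, temperature: float, viscosity: float) -> float:
    """Dilute-limit translational diffusion coefficient of a sphere.

    D0 = kB*T / (6*pi*eta*a).

    Parameters
    ----------
    radius : float
        Hydrodynamic (sphere) radius in Å.
    temperature : float
        Temperature in K.
    viscosity : float
        Solvent viscosity in mPa·s (= cP).

    Returns
    -------
    float
        D0 in Å²/ns.
    """
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    a_m = radius * 1e-10
    eta_pas = viscosity * 1e-3
    d_m2_per_s = _KB_SI * temperature / (6.0 * math.pi * eta_pas * a_m)
    # 1 m^2/s = 1e20 Å^2 / 1e9 ns = 1e11 Å^2/ns
    return d_m2_per_s * 1e11
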