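"""Physical seawater properties: oxygen solubility and potential density.

Two quantities are needed by the biological-carbon-pump diagnostics:

* the oxygen saturation concentration ``O2_sat(T, S)``, which enters the
  apparent oxygen utilization AOU = O2_sat - O2, and
* the surface-referenced potential density anomaly sigma0(T, S), which
  defines the upper-ocean stratification index.

Oxygen solubility follows the Garcia & Gordon (1992) polynomial fit in
scaled temperature, by default with the coefficient set fitted to the
Benson & Krause data (the set in common oceanographic use; the "combined
fit" set is also provided).  Density uses the classic one-atmosphere
(EOS-80) international equation of state of seawater; since ``thetao`` is
potential temperature, evaluating the surface equation at (theta, S) yields
the potential density anomaly sigma0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolubilityCoefficients",
    "BENSON_KRAUSE",
    "COMBINED_FIT",
    "oxygen_saturation",
    "potential_density",
    "RHO0",
]

#: Reference seawater density used to convert gravimetric oxygen units
#: (umol kg-1) to the CMIP6 volumetric unit (mol m-3), kg m-3.
RHO0 = 1025.0


@dataclass(frozen=True)
class SolubilityCoefficients:
    """Coefficients of the Garcia-Gordon oxygen solubility fit.

    The fit is ``ln C = sum_i a_i Ts^i + S * sum_i b_i Ts^i + c0 S^2`` with
    the scaled temperature ``Ts = ln[(298.15 - T) / (273.15 + T)]`` and C in
    umol kg-1.
    """

    a: tuple[float, ...]
    b: tuple[float, ...]
    c0: float
    label: str = field(default="", compare=False)

    def check(self) -> None:
        """Verify the fit against the published reference point.

        At T = 10 degC, S = 35 the solubility must be ~274.6 umol kg-1
        (within 0.1 %); raises ``ValueError`` otherwise.
        """
        val = _evaluate(10.0, 35.0, self)
        if abs(val - 274.61) > 0.1 * 2.7461:
            raise ValueError(
                f"solubility coefficients fail reference check: {val:.3f} umol/kg"
            )


#: Garcia & Gordon (1992) fit to the Benson & Krause data, umol kg-1.
BENSON_KRAUSE = SolubilityCoefficients(
    a=(5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369),
    b=(-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3),
    c0=-2.75915e-7,
    label="benson_krause",
)

#: Garcia & Gordon (1992) "combined fit" coefficient set, umol kg-1.
COMBINED_FIT = SolubilityCoefficients(
    a=(5.80818, 3.20684, 4.11890, 4.93845, 1.01567, 1.41575),
    b=(-7.01211e-3, -7.25958e-3, -7.93334e-3, -5.54491e-3),
    c0=-1.32412e-7,
    label="combined",
)

_FITS = {"benson_krause": BENSON_KRAUSE, "combined": COMBINED_FIT}


def _evaluate(T, S, coeffs: SolubilityCoefficients):
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    Ts = np.log((298.15 - T) / (273.15 + T))
    lnc = np.zeros(np.broadcast_shapes(T.shape, S.shape), dtype=float)
    # Horner evaluation of both polynomials in the scaled temperature.
    pa = np.zeros_like(Ts)
    for ai in reversed(coeffs.a):
        pa = pa * Ts + ai
    pb = np.zeros_like(Ts)
    for bi in reversed(coeffs.b):
        pb = pb * Ts + bi
    lnc = pa + S * pb + coeffs.c0 * S * S
    return np.exp(lnc)


def oxygen_saturation(T, S, fit: str | SolubilityCoefficients = "benson_krause"):
    """Oxygen saturation concentration, umol kg-1.

    Parameters
    ----------
    T : array_like
        Temperature in degrees Celsius. For CMIP6 ``thetao`` this is
        potential temperature, which is the conventional argument of the fit.
    S : array_like
        Practical salinity.
    fit : str or SolubilityCoefficients
        ``"benson_krause"`` (default) or ``"combined"``, or an explicit
        coefficient set.

    Returns
    -------
    ndarray
        Saturation concentration at one atmosphere total pressure including
        saturated water vapour. NaN inputs propagate to NaN.

    Notes
    -----
    The fit is valid for roughly -2 <= T <= 40 degC and 0 <= S <= 42.
    Finite inputs outside that envelope trigger a ``RuntimeWarning`` and the
    computation proceeds (extrapolation of the polynomial).
    """
    coeffs = _FITS[fit] if isinstance(fit, str) else fit
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ((T < -2.0) | (T > 40.0) | (S < 0.0) | (S > 42.0)) & np.isfinite(T) & np.isfinite(S)
    if np.any(bad):
        warnings.warn(
            f"{int(np.count_nonzero(bad))} point(s) outside the solubility fit "
            "validity range (-2..40 degC, 0..42); extrapolating",
            RuntimeWarning,
            stacklevel=2,
        )
    return _evaluate(T, S, coeffs)


def _rho_eos80_surface(S, T):
    """EOS-80 one-atmosphere density rho(S, T, p=0), kg m-3."""
    rw = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = (
        8.24493e-1
        - 4.0899e-3 * T
        + 7.6438e-5 * T**2
        - 8.2467e-7 * T**3
        + 5.3875e-9 * T**4
    )
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    with np.errstate(invalid="ignore"):
        return rw + A * S + B * S * np.sqrt(np.abs(S)) + C * S**2


def potential_density(T, S, eos: str = "eos80"):
    """Potential density anomaly sigma0, kg m-3.

    Computed as rho(S, theta, p=0) - 1000 using the one-atmosphere
    international equation of state (EOS-80).  ``T`` must be potential
    temperature (CMIP6 ``thetao`` already is), so the surface evaluation is
    the surface-referenced potential density.  Non-finite inputs propagate
    as NaN.
    """
    if eos != "eos80":
        raise ValueError(f"unknown equation of state: {eos!r}")
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    return _rho_eos80_surface(S, T) - 1000.0
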