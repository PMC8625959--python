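"""Vegetation dielectric model.

Complex relative permittivity of fresh vegetation material from its moisture
content and the radar frequency, using the Ulaby & El-Rayes dual-dispersion
semiempirical model: a nondispersive residual term plus a free-water Debye
term (with an ionic-conductivity loss) and a bound-water Cole-Cole-type term.

The engineering time convention is used throughout the public surface:
``eps = eps' - j eps''`` with ``eps'' >= 0`` reported as ``loss``.
"""

from __future__ import annotations

import cmath
import warnings
from dataclasses import dataclass

__all__ = [
    "MoistureFrequencyInput",
    "ComplexPermittivity",
    "vegetation_permittivity",
]

#: Ionic conductivity of the free-water inclusion, S/m (model's published
#: room-temperature default; no temperature dependence is modelled).
IONIC_CONDUCTIVITY_S_PER_M = 1.27

#: Frequency band over which the semiempirical fit was established, GHz.
VALID_BAND_GHZ = (0.2, 20.0)


@dataclass(frozen=True)
class MoistureFrequencyInput:
    """Moisture fraction (dimensionless, in [0, 1)) and frequency in GHz."""

    moisture: float
    frequency_ghz: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.moisture < 1.0:
            raise ValueError(
                f"moisture must lie in [0, 1), got {self.moisture!r}"
            )
        if self.frequency_ghz <= 0.0:
            raise ValueError(
                f"frequency must be positive (GHz), got {self.frequency_ghz!r}"
            )
        lo, hi = VALID_BAND_GHZ
        if not lo <= self.frequency_ghz <= hi:
            warnings.warn(
                f"frequency {self.frequency_ghz} GHz is outside the validated "
                f"band {lo}-{hi} GHz; the semiempirical fit is extrapolated",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative permittivity ``eps = real - j*loss`` (engineering sign)."""

    real: float
    loss: float

    def __post_init__(self) -> None:
        if self.real < 1.0:
            raise ValueError(f"real part must be >= 1, got {self.real!r}")
        if self.loss < 0.0:
            raise ValueError(f"loss must be >= 0, got {self.loss!r}")

    @property
    def engineering(self) -> complex:
        """``eps' - j eps''`` (time convention exp(+j omega t))."""
        return complex(self.real, -self.loss)

    @property
    def physics(self) -> complex:
        """``eps' + i eps''`` (time convention exp(-i omega t))."""
        return complex(self.real, self.loss)


def vegetation_permittivity(
    moisture: float | MoistureFrequencyInput,
    frequency_ghz: float | None = None,
) -> ComplexPermittivity:
    """Dual-dispersion permittivity of vegetation material.

    Parameters
    ----------
    moisture
        Moisture fraction in [0, 1) (the model's gravimetric moisture
        parameter; the canopy tables' printed moisture values are fed
        directly), or a :class:`MoistureFrequencyInput`.
    frequency_ghz
        Frequency in GHz; required when ``moisture`` is a plain float.

    Returns
    -------
    ComplexPermittivity
        ``eps = eps' - j eps''`` of the bulk vegetation material.

    Notes
    -----
    The model mixes three terms weighted by moisture-dependent volume
    fractions::

        eps = eps_residual(m)
              + v_fw(m) * [4.9 + 75/(1 + j f/18) - j 18 sigma/f]
              + v_b(m)  * [2.9 + 55/(1 + sqrt(j f/0.18))]

    with ``eps_residual = 1.7 - 0.74 m + 6.16 m^2``,
    ``v_fw = m (0.55 m - 0.076)``, ``v_b = 4.64 m^2 / (1 + 7.36 m^2)`` and
    ``sigma = 1.27`` S/m. At zero moisture both water terms vanish and the
    result is the purely real residual.

    The fitted free-water fraction polynomial goes (slightly) negative below
    m ~ 0.14, outside the moisture range the fit was built for; a negative
    water fraction is unphysical and would make the loss non-monotone, so
    ``v_fw`` is clamped at zero there.
    """
    if isinstance(moisture, MoistureFrequencyInput):
        inp = moisture
    else:
        if frequency_ghz is None:
            raise TypeError("frequency_ghz is required with a float moisture")
        inp = MoistureFrequencyInput(float(moisture), float(frequency_ghz))

    m = inp.moisture
    f = inp.frequency_ghz

    eps_residual = 1.7 - 0.74 * m + 6.16 * m * m
    v_fw = max(0.0, m * (0.55 * m - 0.076))
    v_b = 4.64 * m * m / (1.0 + 7.36 * m * m)

    # Engineering convention: dispersive terms carry negative imaginary parts.
    eps_fw = 4.9 + 75.0 / (1.0 + 1j * f / 18.0) \
        - 1j * 18.0 * IONIC_CONDUCTIVITY_S_PER_M / f
    eps_b = 2.9 + 55.0 / (1.0 + cmath.sqrt(1j * f / 0.18))

    eps = eps_residual + v_fw * eps_fw + v_b * eps_b
    return ComplexPermittivity(real=float(eps.real), loss=-float(eps.imag))
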