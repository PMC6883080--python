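"""Two-photon excitation point-spread-function model.

The focal volume of a two-photon microscope is well approximated by a 3D
Gaussian whose 1/e widths follow the standard diffraction-limited closed
forms for the squared illumination intensity:

.. math::

    \\omega_{xy} = \\begin{cases}
        0.320\\,\\lambda / (\\sqrt{2}\\,\\mathrm{NA}) & \\mathrm{NA} \\le 0.7\\\\
        0.325\\,\\lambda / (\\sqrt{2}\\,\\mathrm{NA}^{0.91}) & \\mathrm{NA} > 0.7
    \\end{cases}
    \\qquad
    \\omega_z = \\frac{0.532\\,\\lambda}{\\sqrt 2}
               \\frac{1}{n - \\sqrt{n^2 - \\mathrm{NA}^2}}

For the 25x NA 1.05 water-dipping objective at 810 nm excitation these give
``omega_xy = 0.18`` µm and ``omega_z = 0.59`` µm.  The widths parameterise the
Gaussian blur applied by the phantom renderer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_HIGH_NA_CUTOFF = 0.7


def lateral_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """1/e lateral width (µm) of the two-photon Gaussian PSF.

    Parameters
    ----------
    wavelength_nm:
        Two-photon excitation wavelength in nanometres (> 0).
    numerical_aperture:
        Objective NA (> 0).  The high-NA branch of the approximation is used
        above NA 0.7.

    Returns
    -------
    float
        Lateral 1/e width in micrometres.  Linear in wavelength at fixed NA
        and strictly decreasing in NA.
    """
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be > 0 nm, got {wavelength_nm}")
    if not numerical_aperture > 0:
        raise ValueError(f"NA must be > 0, got {numerical_aperture}")
    lam_um = wavelength_nm / 1000.0
    if numerical_aperture > _HIGH_NA_CUTOFF:
        return 0.325 * lam_um / (math.sqrt(2.0) * numerical_aperture**0.91)
    return 0.320 * lam_um / (math.sqrt(2.0) * numerical_aperture)


def axial_resolution(
    wavelength_nm: float, numerical_aperture: float, refractive_index: float
) -> float:
    """1/e axial width (µm) of the two-photon Gaussian PSF.

    Requires ``NA < n`` (otherwise the closed form is undefined): the axial
    extent diverges as the aperture half-angle approaches 90 degrees.
    """
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be > 0 nm, got {wavelength_nm}")
    if not numerical_aperture > 0:
        raise ValueError(f"NA must be > 0, got {numerical_aperture}")
    if not numerical_aperture < refractive_index:
        raise ValueError(
            f"axial closed form requires NA < n, got NA={numerical_aperture}, "
            f"n={refractive_index}"
        )
    lam_um = wavelength_nm / 1000.0
    root = math.sqrt(refractive_index**2 - numerical_aperture**2)
    return (0.532 * lam_um / math.sqrt(2.0)) / (refractive_index - root)


@dataclass(frozen=True)
class PSFModel:
    """Gaussian two-photon PSF: optical parameters plus derived 1/e widths."""

    wavelength_nm: float
    numerical_aperture: float
    refractive_index: float
    lateral_width_um: float
    axial_width_um: float

    def __post_init__(self) -> None:
        if not (self.lateral_width_um > 0 and self.axial_width_um > 0):
            raise ValueError("PSF widths must be > 0")
        if self.axial_width_um < self.lateral_width_um:
            raise ValueError("axial width must be >= lateral width")

    @classmethod
    def diffraction_limited(
        cls,
        wavelength_nm: float = 810.0,
        numerical_aperture: float = 1.05,
        refractive_index: float = 1.33,
    ) -> "PSFModel":
        """PSF from the closed forms; defaults match the 810 nm / NA 1.05
        water-dipping configuration."""
        return cls(
            wavelength_nm=wavelength_nm,
            numerical_aperture=numerical_aperture,
            refractive_index=refractive_index,
            lateral_width_um=lateral_resolution(wavelength_nm, numerical_aperture),
            axial_width_um=axial_resolution(
                wavelength_nm, numerical_aperture, refractive_index
            ),
        )

    @property
    def lateral_sigma_um(self) -> float:
        """Gaussian sigma such that exp(-r^2/omega^2) == exp(-r^2/(2 sigma^2))."""
        return self.lateral_width_um / math.sqrt(2.0)

    @property
    def axial_sigma_um(self) -> float:
        return self.axial_width_um / math.sqrt(2.0)
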