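"""Unit conventions and small conversion helpers.

Internal convention: transverse lengths in micrometres (µm), long
(source/detector) distances entered in centimetres and converted to µm,
energies in keV, angles in degrees at the API surface and radians
internally where noted.  Spatial frequencies are cycles/µm.
"""

from __future__ import annotations

import math

CM_TO_UM = 1.0e4
#: hc in keV·Å
HC_KEV_ANGSTROM = 12.398

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def wavelength_um(energy_kev: float) -> float:
    """X-ray wavelength in µm for a photon energy in keV (λ[Å] = 12.398/E)."""
    if energy_kev <= 0:
        raise ValueError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev * 1.0e-4


def sigma_from_fwhm(fwhm: float) -> float:
    return fwhm / _FWHM_PER_SIGMA


def fwhm_from_sigma(sigma: float) -> float:
    return sigma * _FWHM_PER_SIGMA
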