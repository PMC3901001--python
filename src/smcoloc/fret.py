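"""Solution-FRET ratio from emission spectra.

In the solution assay, donor- and acceptor-labeled holoenzyme pools are
mixed and emission spectra (500-700 nm, 490 nm excitation) are acquired
over time; subunit exchange brings donors and acceptors into the same
holoenzyme and raises energy transfer. The readout is the raw FRET ratio:
acceptor emission at 610 nm divided by donor emission at 515 nm. No FRET
efficiency or distance is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmissionSpectrum", "fret_ratio", "DONOR_NM", "ACCEPTOR_NM"]

DONOR_NM = 515.0
ACCEPTOR_NM = 610.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """Wavelength (nm, strictly ascending) vs fluorescence intensity."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelengths and intensities must be 1D and equal length")
        if len(wl) < 2:
            raise ValueError("spectrum needs at least two points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def intensity_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated intensity at an exact wavelength."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"{wavelength_nm} nm outside the scanned range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength_nm, wl, self.intensities))


def fret_ratio(
    spectrum: EmissionSpectrum,
    acceptor_nm: float = ACCEPTOR_NM,
    donor_nm: float = DONOR_NM,
) -> float:
    """Acceptor/donor emission ratio, I(610 nm) / I(515 nm) by default.

    Both intensities are read by linear interpolation at the exact
    wavelength; no bandwidth averaging is applied. Raises when the donor
    intensity is zero (ratio undefined) or a wavelength falls outside the
    scanned range. The ratio is invariant under overall scaling of the
    spectrum.
    """
    donor = spectrum.intensity_at(donor_nm)
    acceptor = spectrum.intensity_at(acceptor_nm)
    if donor == 0:
        raise ValueError(f"donor emission at {donor_nm} nm is zero; ratio undefined")
    return acceptor / donor
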