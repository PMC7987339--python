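"""Camera/relay optics arithmetic for the tracking acquisition geometry.

With an EMCCD behind a relay (tube) lens, on-chip binning enlarges the
effective object-plane pixel while extra tube-lens magnification shrinks it:

    effective pixel = native pixel × binning / tube_magnification

and the photons collected per (effective) pixel scale with its object-plane
area, so the gain from a binning/tube-lens combination is

    gain = (binning / tube_magnification)² − 1.

The tracking acquisition here uses a 130 nm native pixel, 2×2 binning and a
1.5× tube lens, giving a ~173 nm effective pixel and ~77% more photons per
pixel.
"""

from __future__ import annotations


def effective_pixel_size(
    native_pixel_nm: float = 130.0, binning: int = 2, tube_magnification: float = 1.5
) -> float:
    """Object-plane pixel size (nm) after binning and relay magnification."""
    if native_pixel_nm <= 0 or binning < 1 or tube_magnification <= 0:
        raise ValueError("optics parameters must be positive")
    return native_pixel_nm * binning / tube_magnification


def photon_gain_percent(binning: int = 2, tube_magnification: float = 1.5) -> float:
    """Percent increase in photons per pixel from binning + relay lens.

    Proportional to the change in object-plane pixel area.
    """
    ratio = binning / tube_magnification
    return (ratio**2 - 1.0) * 100.0
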