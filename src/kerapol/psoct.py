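"""Polarization-sensitive OCT signal math and en-face map utilities.

A PS-OCT system records two orthogonally polarized interference channels.
After Fourier transformation each A-scan yields two amplitude profiles
``A1(z)`` and ``A2(z)``; tissue reflectivity is ``R(z) = A1^2 + A2^2`` (up to
an arbitrary positive scale factor) and the cumulative phase retardation of
the birefringent stroma is ``PR(z) = arctan(A2/A1)``, reported here in
degrees within [0, 90].

En-face maps sample a corneal volume at a chosen surface (the posterior
stromal boundary for phase retardation, which is polarization preserving) and
are post-processed with a physical-window moving average and a centered field
crop.  Maps live on a regular grid with the origin at the scan center; the
``x`` axis increases rightward in the scan frame and ``y`` increases with the
row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "AScanPair",
    "CornealMap",
    "compute_reflectivity",
    "compute_phase_retardation",
    "extract_enface_pr",
    "smooth_map",
    "crop_field",
    "central_mean",
]


@dataclass(frozen=True)
class AScanPair:
    """Paired orthogonal-channel amplitude profiles over depth.

    Amplitudes are magnitudes of complex Fourier signals and therefore
    non-negative; both channels share one depth axis.
    """

    a1: np.ndarray
    a2: np.ndarray
    depth_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        a1 = np.asarray(self.a1, dtype=float)
        a2 = np.asarray(self.a2, dtype=float)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)
        if a1.ndim != 1 or a2.ndim != 1 or a1.shape != a2.shape:
            raise ValueError("a1 and a2 must be 1-D arrays of equal length")
        if np.any(a1 < 0) or np.any(a2 < 0):
            raise ValueError("channel amplitudes are magnitudes and must be >= 0")
        if self.depth_spacing_um <= 0:
            raise ValueError("depth_spacing_um must be positive")

    def __len__(self) -> int:
        return self.a1.shape[0]


#: quantities a CornealMap may carry, with their units
_QUANTITY_UNITS = {
    "phase_retardation": "degrees",
    "epithelium_thickness": "um",
    "bowman_thickness": "um",
    "reflectivity": "a.u.",
}


@dataclass
class CornealMap:
    """2-D scalar field on a physical grid with a validity mask.

    ``values`` has shape ``(ny, nx)``; ``spacing_mm`` is ``(dx, dy)`` in mm
    per pixel.  The physical origin sits at the grid center.  Phase
    retardation values must lie in [0, 90] degrees and thicknesses must be
    strictly positive wherever ``mask`` is True; masked-out pixels are
    unconstrained.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float]
    quantity: str
    units: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        dx, dy = self.spacing_mm
        if dx <= 0 or dy <= 0:
            raise ValueError("spacing must be positive")
        self.spacing_mm = (float(dx), float(dy))
        if self.quantity not in _QUANTITY_UNITS:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not self.units:
            self.units = _QUANTITY_UNITS[self.quantity]
        inside = self.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("map values inside the mask must be finite")
        if self.quantity == "phase_retardation" and inside.size:
            if inside.min() < 0.0 or inside.max() > 90.0:
                raise ValueError("phase retardation must lie in [0, 90] degrees")
        if self.quantity.endswith("thickness") and inside.size and inside.min() <= 0.0:
            raise ValueError("thickness values must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) in mm, grid shape times spacing."""
        ny, nx = self.values.shape
        return (nx * self.spacing_mm[0], ny * self.spacing_mm[1])

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (X, Y) in mm, origin at map center."""
        ny, nx = self.values.shape
        dx, dy = self.spacing_mm
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        y = (np.arange(ny) - (ny - 1) / 2.0) * dy
        return np.meshgrid(x, y)


def compute_reflectivity(pair: AScanPair) -> np.ndarray:
    """Relative reflectivity profile A1(z)^2 + A2(z)^2.

    The absolute scale of a spectral-domain OCT reflectivity is arbitrary;
    the sum of squared channel amplitudes is returned unscaled.
    """
    return pair.a1 ** 2 + pair.a2 ** 2


def compute_phase_retardation(pair: AScanPair) -> tuple[np.ndarray, np.ndarray]:
    """Phase retardation profile arctan(A2/A1) in degrees, with validity.

    Returns ``(pr_deg, valid)``.  ``pr_deg`` lies in [0, 90]; ``A1 = 0`` with
    ``A2 > 0`` maps to exactly 90.  Samples where both amplitudes vanish carry
    no polarization information and are flagged invalid rather than silently
    set to zero.
    """
    pr = np.degrees(np.arctan2(pair.a2, pair.a1))
    valid = (pair.a1 > 0) | (pair.a2 > 0)
    return pr, valid


def extract_enface_pr(
    volume,
    surface_index: np.ndarray,
    spacing_mm: tuple[float, float] = (0.25, 0.25),
) -> CornealMap:
    """Sample phase retardation at a per-A-scan surface depth.

    Parameters
    ----------
    volume
        Nested sequence ``volume[iy][ix]`` of :class:`AScanPair`, one A-scan
        per map pixel.
    surface_index
        Integer array of shape ``(ny, nx)`` giving the depth sample of the
        surface (e.g. the posterior stromal boundary) for each A-scan.
    spacing_mm
        Lateral pixel spacing of the resulting map.

    A-scans whose surface sample has zero amplitude in both channels are
    masked out; an out-of-range surface index raises with the offending
    A-scan's grid position.
    """
    surface_index = np.asarray(surface_index, dtype=int)
    ny, nx = surface_index.shape
    values = np.zeros((ny, nx))
    mask = np.ones((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            pair = volume[iy][ix]
            z = surface_index[iy, ix]
            if not (0 <= z < len(pair)):
                raise IndexError(
                    f"surface index {z} out of depth range for A-scan (iy={iy}, ix={ix})"
                )
            pr, valid = compute_phase_retardation(pair)
            values[iy, ix] = pr[z] if valid[z] else 0.0
            mask[iy, ix] = bool(valid[z])
    return CornealMap(values, spacing_mm, "phase_retardation", mask=mask)


def _window_pixels(window_mm: float, spacing: float) -> int:
    """Nearest odd pixel count covering at least window_mm."""
    k = int(np.ceil(window_mm / spacing - 1e-9))
    k = max(k, 1)
    return k if k % 2 == 1 else k + 1


def smooth_map(cmap: CornealMap, window_mm: tuple[float, float] = (1.0, 1.0)) -> CornealMap:
    """Physical-window moving average over valid pixels.

    Each pixel becomes the mean of valid pixels inside a centered window of
    the requested physical size (converted to the nearest odd pixel count per
    axis covering at least ``window_mm``).  At map borders the window shrinks
    to the available pixels; masked pixels never contribute and the mask
    itself is unchanged.
    """
    wx, wy = window_mm
    if wx <= 0 or wy <= 0:
        raise ValueError("window_mm must be positive")
    dx, dy = cmap.spacing_mm
    kx = _window_pixels(wx, dx)
    ky = _window_pixels(wy, dy)
    m = cmap.mask.astype(float)
    # uniform_filter with constant 0 padding: ratio of sums = masked mean,
    # shrinking naturally at the borders
    num = uniform_filter(cmap.values * m, size=(ky, kx), mode="constant", cval=0.0)
    den = uniform_filter(m, size=(ky, kx), mode="constant", cval=0.0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = np.where(cmap.mask, out, cmap.values)
    if cmap.quantity == "phase_retardation":
        out = np.clip(out, 0.0, 90.0)  # guard rounding at the range ends
    return CornealMap(out, cmap.spacing_mm, cmap.quantity, units=cmap.units, mask=cmap.mask.copy())


def crop_field(cmap: CornealMap, extent_mm: tuple[float, float]) -> CornealMap:
    """Centered crop to a requested physical extent; spacing preserved.

    The crop keeps ``round(extent / spacing)`` pixels per axis, removing
    equal margins on both sides (one extra pixel is taken from the
    right/bottom when the removed count is odd).
    """
    ny, nx = cmap.shape
    dx, dy = cmap.spacing_mm
    w, h = extent_mm
    nx_new = int(round(w / dx))
    ny_new = int(round(h / dy))
    if nx_new <= 0 or ny_new <= 0:
        raise ValueError("requested extent too small")
    if nx_new > nx or ny_new > ny:
        raise ValueError(
            f"requested extent {extent_mm} exceeds map extent {cmap.extent_mm}"
        )
    x0 = (nx - nx_new) // 2
    y0 = (ny - ny_new) // 2
    return CornealMap(
        cmap.values[y0 : y0 + ny_new, x0 : x0 + nx_new].copy(),
        cmap.spacing_mm,
        cmap.quantity,
        units=cmap.units,
        mask=cmap.mask[y0 : y0 + ny_new, x0 : x0 + nx_new].copy(),
    )


def central_mean(cmap: CornealMap, diameter_mm: float = 2.0) -> float:
    """Mean of valid pixels within a centered disk of the given diameter."""
    X, Y = cmap.coords_mm()
    sel = cmap.mask & (X ** 2 + Y ** 2 <= (diameter_mm / 2.0) ** 2)
    if not sel.any():
        raise ValueError("no valid pixels inside the central disk")
    return float(cmap.values[sel].mean())
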