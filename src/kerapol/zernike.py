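"""Zernike decomposition of corneal maps and device feature schemas.

Maps are encoded as coefficients of Zernike polynomials through radial order
6 (28 terms) fitted by least squares over the valid pixels inside a circular
pupil.  The basis uses OSA/ANSI single-index ordering with unit-RMS
(orthonormal over the unit disk) normalization, the convention standard in
ophthalmic optics; coefficient values are therefore directly interpretable as
RMS contributions in the units of the fitted map.

Three fixed feature schemas are assembled from these fits and from device
index records:

* ``PSOCT84``    — 28 coefficients each for phase retardation, epithelial
  thickness and Bowman's-layer thickness maps (84 features).
* ``PENTACAM32`` — anterior keratometry, derived topographic indices and
  front/back corneal wavefront summaries (32 features).
* ``MS39_23``    — anterior and epithelium–Bowman's interface keratometry and
  wavefront summaries plus epithelial-map Zernike summaries (23 features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .psoct import CornealMap

__all__ = [
    "ZernikeCoefficients",
    "FeatureVector",
    "n_terms",
    "osa_indices",
    "zernike_basis",
    "evaluate_zernike",
    "fit_zernike",
    "rms_summaries",
    "assemble_psoct_features",
    "assemble_pentacam_features",
    "assemble_ms39_features",
    "SCHEMA_LENGTHS",
    "PENTACAM_FIELDS",
    "MS39_FIELDS",
]


def n_terms(order_max: int) -> int:
    """Number of Zernike terms through radial order ``order_max``."""
    return (order_max + 1) * (order_max + 2) // 2


def osa_indices(order_max: int) -> list[tuple[int, int]]:
    """(n, m) pairs in OSA/ANSI single-index order j = (n(n+2)+m)/2."""
    out = []
    for n in range(order_max + 1):
        for m in range(-n, n + 1, 2):
            out.append((n, m))
    return out


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    terms = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        terms = terms + c * rho ** (n - 2 * k)
    return terms


def zernike_basis(order_max: int, points: np.ndarray) -> np.ndarray:
    """Design matrix of orthonormal Zernike terms at unit-disk points.

    ``points`` is an ``(N, 2)`` array of (x, y) with radius <= 1; columns
    follow OSA ordering.  The normalization makes each column unit-RMS over
    the continuous unit disk, so discrete inner products on a dense uniform
    grid are approximately diagonal.
    """
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    rho = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(rho > 1.0 + 1e-9):
        raise ValueError("all points must lie inside the unit disk (radius <= 1)")
    rho = np.minimum(rho, 1.0)
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    cols = []
    for n, m in osa_indices(order_max):
        r = _radial(n, abs(m), rho)
        norm = math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1.0)
        if m > 0:
            cols.append(norm * r * np.cos(m * theta))
        elif m < 0:
            cols.append(norm * r * np.sin(-m * theta))
        else:
            cols.append(norm * r)
    return np.column_stack(cols)


@dataclass(frozen=True)
class ZernikeCoefficients:
    """Result of a Zernike least-squares fit of one corneal map."""

    order_max: int
    coeffs: np.ndarray
    units: str
    fit_rmse: float
    pupil_radius_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape != (n_terms(self.order_max),):
            raise ValueError(
                f"expected {n_terms(self.order_max)} coefficients for order "
                f"{self.order_max}, got {self.coeffs.shape}"
            )
        if self.fit_rmse < 0:
            raise ValueError("fit_rmse must be >= 0")


def evaluate_zernike(coeffs: ZernikeCoefficients, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted expansion at unit-disk points."""
    return zernike_basis(coeffs.order_max, points) @ coeffs.coeffs


def fit_zernike(
    cmap: CornealMap, order_max: int = 6, pupil_diameter_mm: float = 8.0
) -> ZernikeCoefficients:
    """Least-squares Zernike fit of a map over a centered circular pupil.

    Valid pixels with radius <= pupil radius enter the fit; coordinates are
    normalized to the unit disk.  Rank deficiency (too few or degenerate
    pixels) is an error, never a silent pseudo-inverse solution.
    """
    radius = pupil_diameter_mm / 2.0
    X, Y = cmap.coords_mm()
    sel = cmap.mask & (X ** 2 + Y ** 2 <= radius ** 2)
    k = n_terms(order_max)
    if sel.sum() < k:
        raise ValueError(
            f"only {int(sel.sum())} valid pixels inside the pupil; "
            f"need at least {k} for order {order_max}"
        )
    pts = np.column_stack([X[sel] / radius, Y[sel] / radius])
    A = zernike_basis(order_max, pts)
    b = cmap.values[sel]
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < k:
        raise ValueError(f"design matrix rank deficient ({rank} < {k})")
    rmse = float(np.sqrt(np.mean((A @ coeffs - b) ** 2)))
    return ZernikeCoefficients(order_max, coeffs, cmap.units, rmse, radius)


def rms_summaries(zc: ZernikeCoefficients) -> dict[str, float]:
    """Standard RMS groupings of an orthonormal Zernike expansion.

    lo_rms: orders 1-2 excluding piston; ho_rms: orders 3+; coma_rms: the two
    third-order coma terms; defocus: c(2,0); sa: c(4,0).  With a unit-RMS
    basis these are plain root-sums-of-squares of coefficients.
    """
    idx = osa_indices(zc.order_max)
    c = zc.coeffs
    lo = sum(c[j] ** 2 for j, (n, m) in enumerate(idx) if 1 <= n <= 2)
    ho = sum(c[j] ** 2 for j, (n, m) in enumerate(idx) if n >= 3)
    coma = sum(c[j] ** 2 for j, (n, m) in enumerate(idx) if n == 3 and abs(m) == 1)
    defocus = next(c[j] for j, (n, m) in enumerate(idx) if (n, m) == (2, 0))
    sa = next((c[j] for j, (n, m) in enumerate(idx) if (n, m) == (4, 0)), 0.0)
    return {
        "lo_rms": float(np.sqrt(lo)),
        "ho_rms": float(np.sqrt(ho)),
        "coma_rms": float(np.sqrt(coma)),
        "defocus": float(defocus),
        "sa": float(sa),
    }


SCHEMA_LENGTHS = {"PSOCT84": 84, "PENTACAM32": 32, "MS39_23": 23}

# Pentacam schema: 6 anterior keratometry + 6 derived indices + 10 front
# + 10 back corneal wavefront summaries.
_PENTA_KERATOMETRY = ["K1", "K2", "KMean", "KMax", "AxisFlat", "Astigmatism"]
_PENTA_INDICES = ["ISV", "IVA", "KI", "CKI", "IHA", "IHD"]
_PENTA_WAVEFRONT = [
    "RMS_HOA",
    "RMS_LOA",
    "Astig0",
    "Defocus",
    "Astig45",
    "Trefoil0",
    "Coma0",
    "Coma90",
    "Trefoil30",
    "SphericalAberration",
]
PENTACAM_FIELDS = (
    _PENTA_KERATOMETRY
    + _PENTA_INDICES
    + [f"Front_{w}" for w in _PENTA_WAVEFRONT]
    + [f"Back_{w}" for w in _PENTA_WAVEFRONT]
)

# MS-39 schema: anterior surface, epithelium-Bowman's interface, and
# epithelial thickness-map Zernike summaries.
MS39_FIELDS = [
    "AntK1",
    "AntK2",
    "AntAxis",
    "AntKmax",
    "AntLORMS",
    "AntHORMS",
    "AntComaRMS",
    "AntDefocus",
    "AntSA",
    "BWK1",
    "BWK2",
    "BWAxis",
    "BWKmax",
    "BWLORMS",
    "BWHORMS",
    "BWComaRMS",
    "BWDefocus",
    "BWSA",
    "eLORMS",
    "eHORMS",
    "eComaRMS",
    "eDefocus",
    "eSA",
]


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric features under one of the three device schemas."""

    schema: str
    names: tuple[str, ...]
    values: np.ndarray
    eye_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "names", tuple(self.names))
        if self.schema not in SCHEMA_LENGTHS:
            raise ValueError(f"unknown schema {self.schema!r}")
        n = SCHEMA_LENGTHS[self.schema]
        if len(self.names) != n or self.values.shape != (n,):
            raise ValueError(f"schema {self.schema} requires exactly {n} features")
        if len(set(self.names)) != n:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def assemble_psoct_features(
    pr: ZernikeCoefficients,
    epi: ZernikeCoefficients,
    bowman: ZernikeCoefficients,
    eye_id: str | None = None,
) -> FeatureVector:
    """Concatenate the three order-6 map expansions into the 84-feature vector.

    Block order is fixed: phase retardation, epithelium, Bowman's layer.
    """
    blocks = [("pr", pr), ("epi", epi), ("bow", bowman)]
    for tag, zc in blocks:
        if zc.order_max != 6:
            raise ValueError(f"{tag} coefficients must be order 6 (28 terms)")
    names = [f"{tag}_z{j}" for tag, _ in blocks for j in range(28)]
    values = np.concatenate([zc.coeffs for _, zc in blocks])
    return FeatureVector("PSOCT84", tuple(names), values, eye_id=eye_id)


def _assemble_from_record(record, fields: list[str], schema: str, eye_id):
    vals = []
    for f in fields:
        try:
            vals.append(float(record[f]))
        except KeyError:
            raise KeyError(f"record is missing required field {f!r}") from None
    return FeatureVector(schema, tuple(fields), np.array(vals), eye_id=eye_id)


def assemble_pentacam_features(record, eye_id: str | None = None) -> FeatureVector:
    """32-feature Scheimpflug vector in fixed schema order.

    ``record`` is any mapping (or :class:`~kerapol.labeling.TomographyRecord`)
    supplying all 32 named fields; a missing field raises ``KeyError`` naming
    it.
    """
    return _assemble_from_record(record, PENTACAM_FIELDS, "PENTACAM32", eye_id)


def assemble_ms39_features(record, eye_id: str | None = None) -> FeatureVector:
    """23-feature hybrid Placido/OCT vector in fixed schema order."""
    return _assemble_from_record(record, MS39_FIELDS, "MS39_23", eye_id)
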