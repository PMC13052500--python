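"""Synthetic PS-OCT / tomography cohorts for the three-class screening task.

Generates reproducible eyes with the statistical structure the downstream
analysis assumes: en-face maps of stromal phase retardation (degrees) and of
epithelial and Bowman's-layer thickness (μm), plus per-eye Scheimpflug
(Pentacam-style) and hybrid Placido/OCT (MS-39-style) index records whose
class-conditional means and spreads follow published cohort statistics.

Spatial model per eye:

* phase retardation: low central retardance rising quadratically toward the
  periphery (near-normal incidence on orthogonally stacked central lamellae,
  circumferential lamellae peripherally), a fourfold angular modulation
  producing the characteristic rhombus pattern, an optional Gaussian cone
  bump for keratoconic eyes, and smooth spatial noise;
* epithelium: uniform thickness with an annular ("doughnut") depression
  around the cone when present;
* Bowman's layer: uniform thickness with focal Gaussian thinning at the cone.

Index model: Gaussian draws per index (log-normal for the heavily skewed
KISA% in keratoconus), with the screening triple (KISA%, IS, BAD-D) redrawn
by rejection until it satisfies the eye's group criteria, so a generated
cohort always passes the labeling audit.

Two features give the cohort its clinical correlation structure while
leaving every index's marginal mean and sd untouched: a per-eye latent
severity factor loads (with group-appropriate sign) on all indices and on
the map levels, so an eye that is tomographically worse also has higher
central retardation and thinner sublayers; and fellow eyes of asymmetric
keratoconus — clinically indistinguishable from healthy — are drawn from a
subclinical phenotype blended toward the healthy one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .labeling import TomographyRecord
from .psoct import AScanPair, CornealMap, smooth_map
from .zernike import fit_zernike, rms_summaries

__all__ = [
    "PhenotypeParams",
    "SyntheticEye",
    "default_phenotypes",
    "generate_eye",
    "generate_cohort",
    "blend_phenotypes",
    "synthesize_ascan_pair",
    "synthesize_pr_volume",
    "derive_eye_seed",
]

_PR_EXTENT_MM = (10.0, 8.0)
_THICK_EXTENT_MM = (8.0, 8.0)
_SPACING_MM = 0.25
_RMAX_MM = 5.0  # radius at which the radial gain is fully expressed
_MAX_REDRAWS = 1000

# hard physical bounds applied by redraw when an index strays outside
_FIELD_BOUNDS: dict[str, tuple[float, float]] = {
    "ISV": (0.0, np.inf),
    "IVA": (0.0, np.inf),
    "KI": (0.5, np.inf),
    "CKI": (0.5, np.inf),
    "IHA": (0.0, np.inf),
    "IHD": (0.0, np.inf),
    "TCT": (250.0, np.inf),
    "CCT": (250.0, np.inf),
    "CET": (20.0, np.inf),
    "K1": (30.0, np.inf),
    "K2": (30.0, np.inf),
    "KMax": (30.0, np.inf),
    "AntK1": (30.0, np.inf),
    "AntK2": (30.0, np.inf),
    "AntKmax": (30.0, np.inf),
    "BWK1": (30.0, np.inf),
    "BWK2": (30.0, np.inf),
    "BWKmax": (30.0, np.inf),
    "Front_RMS_HOA": (0.0, np.inf),
    "Front_RMS_LOA": (0.0, np.inf),
    "Back_RMS_HOA": (0.0, np.inf),
    "Back_RMS_LOA": (0.0, np.inf),
    "AntLORMS": (0.0, np.inf),
    "AntHORMS": (0.0, np.inf),
    "AntComaRMS": (0.0, np.inf),
    "BWLORMS": (0.0, np.inf),
    "BWHORMS": (0.0, np.inf),
    "BWComaRMS": (0.0, np.inf),
}


@dataclass
class PhenotypeParams:
    """Class-conditional generative parameters for one diagnostic group.

    Map-level fields are in map units (degrees or μm); ``index_means_sds``
    holds per-device dicts mapping index name to (mean, sd).  ``*_sd`` fields
    are between-eye standard deviations of the map levels; ``*_noise_sd``
    control smooth within-map spatial noise.
    """

    group: str
    pr_central_mean: float
    pr_central_sd: float
    epi_mean: float
    epi_sd: float
    bowman_mean: float
    bowman_sd: float
    cone_present: bool = False
    cone_center: tuple[float, float] = (0.8, -0.8)
    cone_radius: float = 1.5
    cone_pr_elevation: float = 0.0
    cone_epi_thinning: float = 0.0
    cone_bowman_thinning: float = 0.0
    pr_radial_gain: float = 20.0
    pr_rhombus_amp: float = 6.0
    pr_noise_sd: float = 1.0
    epi_noise_sd: float = 0.6
    bowman_noise_sd: float = 0.4
    kisa_lognormal: bool = False
    index_means_sds: dict = field(default_factory=dict)
    # latent severity: per-eye factor loading on every index and map level,
    # signed per index by the healthy→keratoconus direction of change
    severity_rho: float = 0.5
    index_severity_dir: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "skc", "kc"):
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("pr_central_sd", "epi_sd", "bowman_sd", "pr_noise_sd",
                     "epi_noise_sd", "bowman_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cone_present and self.cone_radius <= 0:
            raise ValueError("cone_radius must be > 0 when a cone is present")
        if not 0.0 <= self.severity_rho < 1.0:
            raise ValueError("severity_rho must lie in [0, 1)")
        for dev in self.index_means_sds.values():
            for k, (_, sd) in dev.items():
                if sd < 0:
                    raise ValueError(f"index sd for {k!r} must be >= 0")


@dataclass
class SyntheticEye:
    eye_id: str
    subject_id: str
    laterality: str
    true_group: str
    skc_subtype: str  # none | fellow_eye | bilateral_suspect
    pr_map: CornealMap
    epi_map: CornealMap
    bowman_map: CornealMap
    pentacam: TomographyRecord
    ms39: TomographyRecord

    def __post_init__(self) -> None:
        if (self.skc_subtype == "none") != (self.true_group != "skc"):
            raise ValueError("skc_subtype must be 'none' exactly when the group is not skc")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """Generative parameters for the three groups.

    The screening-index statistics follow the published cohort tables (IS
    0.3 ± 0.5, KISA% 8 ± 11, BAD-D 1.0 ± 0.4 for healthy eyes; BAD-D
    1.9 ± 0.5 subclinical; KISA% 912 ± 1290 log-normal, Kmax 55.0 ± 4.9 D
    keratoconic, and so on); map levels follow the reported per-eye means
    (central retardation near 26–31 degrees in non-ectatic eyes, epithelium
    ≈ 52 μm, Bowman's layer 15–17 μm in health).  Remaining keratometry and
    wavefront indices use plausible clinic-scale values documented in the
    methods note, with subclinical eyes intermediate but closer to healthy.
    """
    penta_common = {
        # name: (healthy, skc, kc) x (mean, sd)
        "kisa_percent": [(8.0, 11.0), (8.0, 10.0), (912.0, 1290.0)],
        "is_value": [(0.3, 0.5), (0.4, 0.5), (5.8, 2.3)],
        "badd": [(1.0, 0.4), (1.9, 0.5), (8.1, 2.8)],
        "KMax": [(44.5, 1.2), (46.0, 1.9), (55.0, 4.9)],
        "TCT": [(531.0, 28.0), (519.0, 38.0), (471.0, 40.0)],
        "CCT": [(534.0, 28.0), (522.0, 38.0), (490.0, 40.0)],
        "K1": [(42.8, 1.2), (43.8, 1.4), (48.5, 3.5)],
        "K2": [(43.9, 1.3), (45.0, 1.6), (52.0, 4.2)],
        "ISV": [(16.0, 5.0), (20.5, 6.5), (85.0, 25.0)],
        "IVA": [(0.12, 0.04), (0.14, 0.06), (0.9, 0.35)],
        "KI": [(1.02, 0.02), (1.04, 0.03), (1.25, 0.08)],
        "CKI": [(1.00, 0.01), (1.01, 0.012), (1.08, 0.04)],
        "IHA": [(5.0, 4.0), (6.0, 5.0), (25.0, 12.0)],
        "IHD": [(0.008, 0.005), (0.012, 0.007), (0.12, 0.05)],
        "Front_RMS_HOA": [(0.45, 0.10), (0.55, 0.15), (2.2, 0.9)],
        "Front_RMS_LOA": [(1.8, 0.6), (2.0, 0.7), (4.5, 1.8)],
        "Front_Astig0": [(0.3, 0.4), (0.35, 0.45), (0.6, 1.2)],
        "Front_Defocus": [(1.2, 0.8), (1.3, 0.8), (-0.5, 2.0)],
        "Front_Astig45": [(0.0, 0.3), (0.0, 0.35), (0.1, 0.9)],
        "Front_Trefoil0": [(0.0, 0.08), (0.0, 0.10), (0.05, 0.30)],
        "Front_Coma0": [(0.0, 0.10), (0.0, 0.12), (0.1, 0.5)],
        "Front_Coma90": [(-0.05, 0.12), (-0.12, 0.15), (-1.2, 0.8)],
        "Front_Trefoil30": [(0.0, 0.08), (0.0, 0.10), (0.0, 0.30)],
        "Front_SphericalAberration": [(0.25, 0.10), (0.22, 0.10), (-0.1, 0.4)],
        "Back_RMS_HOA": [(0.12, 0.04), (0.15, 0.05), (0.6, 0.25)],
        "Back_RMS_LOA": [(0.5, 0.15), (0.55, 0.18), (1.1, 0.4)],
        "Back_Astig0": [(-0.1, 0.1), (-0.1, 0.12), (-0.2, 0.3)],
        "Back_Defocus": [(-0.3, 0.2), (-0.32, 0.2), (0.1, 0.5)],
        "Back_Astig45": [(0.0, 0.08), (0.0, 0.09), (0.0, 0.25)],
        "Back_Trefoil0": [(0.0, 0.03), (0.0, 0.03), (0.0, 0.10)],
        "Back_Coma0": [(0.0, 0.03), (0.0, 0.04), (0.03, 0.15)],
        "Back_Coma90": [(0.01, 0.03), (0.03, 0.04), (0.3, 0.2)],
        "Back_Trefoil30": [(0.0, 0.03), (0.0, 0.03), (0.0, 0.10)],
        "Back_SphericalAberration": [(-0.06, 0.03), (-0.06, 0.03), (0.05, 0.12)],
    }
    ms39_common = {
        "AntK1": [(42.9, 1.2), (43.9, 1.4), (48.3, 3.4)],
        "AntK2": [(44.0, 1.3), (45.2, 1.6), (51.8, 4.1)],
        "AntKmax": [(44.8, 1.2), (46.4, 1.9), (54.6, 4.7)],
        "AntLORMS": [(1.9, 0.6), (2.1, 0.7), (4.6, 1.8)],
        "AntHORMS": [(0.40, 0.10), (0.50, 0.15), (2.1, 0.9)],
        "AntComaRMS": [(0.15, 0.06), (0.22, 0.09), (1.3, 0.6)],
        "AntDefocus": [(1.1, 0.7), (1.2, 0.8), (-0.4, 1.9)],
        "AntSA": [(0.22, 0.08), (0.20, 0.09), (-0.08, 0.35)],
        "BWK1": [(43.3, 1.2), (44.4, 1.4), (49.0, 3.5)],
        "BWK2": [(44.5, 1.3), (45.8, 1.6), (52.5, 4.2)],
        "BWKmax": [(45.3, 1.5), (46.9, 1.8), (55.5, 5.0)],
        "BWLORMS": [(2.0, 0.6), (2.2, 0.7), (4.8, 1.9)],
        "BWHORMS": [(0.45, 0.12), (0.55, 0.16), (2.3, 1.0)],
        "BWComaRMS": [(0.17, 0.07), (0.25, 0.10), (1.4, 0.6)],
        "BWDefocus": [(1.0, 0.7), (1.1, 0.8), (-0.3, 1.9)],
        "BWSA": [(0.20, 0.08), (0.18, 0.09), (-0.06, 0.35)],
        "CCT": [(536.0, 28.0), (524.0, 39.0), (490.0, 40.0)],
        "CET": [(54.9, 3.0), (54.0, 3.6), (49.9, 6.4)],
    }

    def _index_set(col: int) -> dict:
        return {
            "pentacam": {k: v[col] for k, v in penta_common.items()},
            "ms39": {k: v[col] for k, v in ms39_common.items()},
        }

    def _dirs() -> dict:
        # healthy→keratoconus direction of change, shared by all groups
        out: dict[str, dict[str, float]] = {}
        for dev, spec in (("pentacam", penta_common), ("ms39", ms39_common)):
            out[dev] = {k: float(np.sign(v[2][0] - v[0][0])) for k, v in spec.items()}
        return out

    dirs = _dirs()

    healthy = PhenotypeParams(
        group="healthy",
        pr_central_mean=26.0, pr_central_sd=3.2,
        epi_mean=52.3, epi_sd=3.0,
        bowman_mean=16.0, bowman_sd=1.0,
        pr_radial_gain=22.0, pr_rhombus_amp=6.0,
        index_means_sds=_index_set(0),
        index_severity_dir=dirs,
    )
    skc = PhenotypeParams(
        group="skc",
        pr_central_mean=30.0, pr_central_sd=3.7,
        epi_mean=52.0, epi_sd=3.5,
        bowman_mean=15.3, bowman_sd=1.6,
        pr_radial_gain=20.0, pr_rhombus_amp=6.0,
        pr_noise_sd=1.2, epi_noise_sd=0.7, bowman_noise_sd=0.5,
        index_means_sds=_index_set(1),
        index_severity_dir=dirs,
    )
    kc = PhenotypeParams(
        group="kc",
        pr_central_mean=38.0, pr_central_sd=4.5,
        epi_mean=50.0, epi_sd=4.0,
        bowman_mean=13.5, bowman_sd=1.8,
        cone_present=True,
        cone_center=(0.8, -0.8), cone_radius=1.5,
        cone_pr_elevation=15.0, cone_epi_thinning=7.0, cone_bowman_thinning=4.5,
        pr_radial_gain=14.0, pr_rhombus_amp=4.0,
        pr_noise_sd=2.0, epi_noise_sd=1.0, bowman_noise_sd=0.8,
        kisa_lognormal=True,
        index_means_sds=_index_set(2),
        index_severity_dir=dirs,
    )
    return {"healthy": healthy, "skc": skc, "kc": kc}


def _grid(extent_mm: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    nx = int(round(extent_mm[0] / _SPACING_MM))
    ny = int(round(extent_mm[1] / _SPACING_MM))
    x = (np.arange(nx) - (nx - 1) / 2.0) * _SPACING_MM
    y = (np.arange(ny) - (ny - 1) / 2.0) * _SPACING_MM
    return np.meshgrid(x, y)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    low = gaussian_filter(white, sigma=2.0, mode="reflect")
    s = low.std()
    return low * (sd / s) if s > 0 else low


def _draw_bounded(rng, mean, sd, lo, hi, rho=0.0, z=0.0, direction=0.0):
    """Bounded Gaussian draw with an optional latent-severity loading.

    The draw is ``mean + sd*(rho*direction*z + sqrt(1-rho^2)*eps)``: the
    marginal distribution stays N(mean, sd) while eyes share the factor
    ``z`` across indices.  Out-of-bound draws redraw only ``eps``.
    """
    shift = mean + sd * rho * direction * z
    resid = sd * np.sqrt(1.0 - rho ** 2) if direction else sd
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(shift, resid)
        if lo <= v <= hi:
            return float(v)
    raise ValueError(
        f"could not draw an index in [{lo}, {hi}] from N({mean}, {sd}); "
        "phenotype parameters are inconsistent with the bound"
    )


_GROUP_BOXES = {
    # (kisa_lo, kisa_hi, is_lo, is_hi, badd_lo, badd_hi) — open intervals
    "healthy": (0.0, 60.0, -np.inf, 1.4, 0.0, 1.65),
    "skc": (0.0, 60.0, -np.inf, 1.6, 0.0, 2.6),
    "kc": (60.0, np.inf, 3.0, np.inf, 3.0, np.inf),
}


def _draw_screening_triple(rng, params: PhenotypeParams, z: float) -> tuple[float, float, float]:
    """Rejection-sample (KISA%, IS, BAD-D) into the group's criterion box."""
    dev = params.index_means_sds["pentacam"]
    dirs = params.index_severity_dir.get("pentacam", {})
    rho = params.severity_rho
    k_mean, k_sd = dev["kisa_percent"]
    i_mean, i_sd = dev["is_value"]
    b_mean, b_sd = dev["badd"]
    klo, khi, ilo, ihi, blo, bhi = _GROUP_BOXES[params.group]
    if params.kisa_lognormal:
        sigma2 = np.log1p((k_sd / k_mean) ** 2)
        mu = np.log(k_mean) - sigma2 / 2.0
        sig = np.sqrt(sigma2)
        k_shift = mu + sig * rho * dirs.get("kisa_percent", 0.0) * z
        k_resid = sig * np.sqrt(1.0 - rho ** 2) if dirs.get("kisa_percent") else sig
        draw_k = lambda: float(np.exp(rng.normal(k_shift, k_resid)))
    else:
        k_shift = k_mean + k_sd * rho * dirs.get("kisa_percent", 0.0) * z
        k_resid = k_sd * np.sqrt(1.0 - rho ** 2) if dirs.get("kisa_percent") else k_sd
        draw_k = lambda: float(rng.normal(k_shift, k_resid))
    i_shift = i_mean + i_sd * rho * dirs.get("is_value", 0.0) * z
    i_resid = i_sd * np.sqrt(1.0 - rho ** 2) if dirs.get("is_value") else i_sd
    b_shift = b_mean + b_sd * rho * dirs.get("badd", 0.0) * z
    b_resid = b_sd * np.sqrt(1.0 - rho ** 2) if dirs.get("badd") else b_sd
    for _ in range(_MAX_REDRAWS):
        k = draw_k()
        i = float(rng.normal(i_shift, i_resid))
        b = float(rng.normal(b_shift, b_resid))
        if klo < k < khi and ilo < i < ihi and blo < b < bhi:
            return k, i, b
    raise ValueError(
        f"screening-index distribution for group {params.group!r} has negligible "
        "mass inside its criterion box; phenotype parameters are inconsistent"
    )


def _draw_indices(rng, spec, dirs, rho, z) -> dict[str, float]:
    out = {}
    for name in sorted(spec):  # fixed draw order for determinism
        mean, sd = spec[name]
        lo, hi = _FIELD_BOUNDS.get(name, (-np.inf, np.inf))
        out[name] = _draw_bounded(rng, mean, sd, lo, hi, rho, z, dirs.get(name, 0.0))
    return out


def generate_eye(
    params: PhenotypeParams,
    rng_seed: int,
    eye_id: str | None = None,
    subject_id: str | None = None,
    laterality: str = "OD",
    skc_subtype: str | None = None,
) -> SyntheticEye:
    """Generate one eye deterministically from a seed.

    Maps are built on a 0.25 mm grid (10×8 mm phase retardation field,
    8×8 mm thickness fields); the screening triple is redrawn until the eye
    satisfies its group's criteria, so labeling round-trips exactly.
    """
    rng = np.random.default_rng(rng_seed)
    if skc_subtype is None:
        skc_subtype = "fellow_eye" if params.group == "skc" else "none"

    # latent severity factor shared by maps and indices; map directions are
    # fixed (retardation rises, sublayers thin as disease advances)
    z = float(rng.standard_normal())
    rho = params.severity_rho
    resid = np.sqrt(1.0 - rho ** 2)

    def _level(mean, sd, direction):
        return mean + sd * (rho * direction * z + resid * rng.standard_normal())

    pr_c = _level(params.pr_central_mean, params.pr_central_sd, +1.0)
    epi_c = _level(params.epi_mean, params.epi_sd, -1.0)
    bow_c = _level(params.bowman_mean, params.bowman_sd, -1.0)

    if params.cone_present:
        jitter = rng.uniform(-0.5, 0.5, size=2)
        cx, cy = params.cone_center[0] + jitter[0], params.cone_center[1] + jitter[1]
        sigma = params.cone_radius / 2.0
    else:
        cx = cy = sigma = 0.0

    # phase retardation map (10 x 8 mm)
    X, Y = _grid(_PR_EXTENT_MM)
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    pr = (
        pr_c
        + params.pr_radial_gain * (r / _RMAX_MM) ** 2
        + params.pr_rhombus_amp * np.cos(4 * theta) * (r / _RMAX_MM) ** 2
    )
    if params.cone_present:
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        pr = pr + params.cone_pr_elevation * np.exp(-d2 / (2 * sigma ** 2))
    pr = pr + _smooth_noise(rng, pr.shape, params.pr_noise_sd)
    pr_map = CornealMap(np.clip(pr, 0.0, 90.0), (_SPACING_MM, _SPACING_MM), "phase_retardation")

    # thickness maps (8 x 8 mm)
    Xt, Yt = _grid(_THICK_EXTENT_MM)
    epi = np.full(Xt.shape, epi_c)
    bow = np.full(Xt.shape, bow_c)
    if params.cone_present:
        d = np.hypot(Xt - cx, Yt - cy)
        ring_sigma = params.cone_radius / 2.0
        epi = epi - params.cone_epi_thinning * np.exp(
            -((d - params.cone_radius) ** 2) / (2 * ring_sigma ** 2)
        )
        bow = bow - params.cone_bowman_thinning * np.exp(-(d ** 2) / (2 * sigma ** 2))
    epi = epi + _smooth_noise(rng, epi.shape, params.epi_noise_sd)
    bow = bow + _smooth_noise(rng, bow.shape, params.bowman_noise_sd)
    epi_map = CornealMap(np.clip(epi, 1.0, None), (_SPACING_MM, _SPACING_MM), "epithelium_thickness")
    bow_map = CornealMap(np.clip(bow, 1.0, None), (_SPACING_MM, _SPACING_MM), "bowman_thickness")

    # device index records
    kisa, isv_, badd = _draw_screening_triple(rng, params, z)
    penta_spec = {
        k: v for k, v in params.index_means_sds["pentacam"].items()
        if k not in ("kisa_percent", "is_value", "badd")
    }
    penta = _draw_indices(
        rng, penta_spec, params.index_severity_dir.get("pentacam", {}), rho, z
    )
    penta["kisa_percent"], penta["is_value"], penta["badd"] = kisa, isv_, badd
    if penta["K2"] < penta["K1"]:  # flat/steep convention
        penta["K1"], penta["K2"] = penta["K2"], penta["K1"]
    penta["KMean"] = (penta["K1"] + penta["K2"]) / 2.0
    penta["Astigmatism"] = penta["K2"] - penta["K1"]
    penta["AxisFlat"] = float(rng.uniform(0.0, 180.0))

    ms39 = _draw_indices(
        rng, params.index_means_sds["ms39"],
        params.index_severity_dir.get("ms39", {}), rho, z,
    )
    if ms39["AntK2"] < ms39["AntK1"]:
        ms39["AntK1"], ms39["AntK2"] = ms39["AntK2"], ms39["AntK1"]
    if ms39["BWK2"] < ms39["BWK1"]:
        ms39["BWK1"], ms39["BWK2"] = ms39["BWK2"], ms39["BWK1"]
    ms39["AntAxis"] = float(rng.uniform(0.0, 180.0))
    ms39["BWAxis"] = float(rng.uniform(0.0, 180.0))
    # epithelial-map Zernike summaries, as the hybrid device derives them
    epi_fit = fit_zernike(smooth_map(epi_map), order_max=6, pupil_diameter_mm=8.0)
    summ = rms_summaries(epi_fit)
    ms39["eLORMS"] = summ["lo_rms"]
    ms39["eHORMS"] = summ["ho_rms"]
    ms39["eComaRMS"] = summ["coma_rms"]
    ms39["eDefocus"] = summ["defocus"]
    ms39["eSA"] = summ["sa"]

    if eye_id is None:
        eye_id = f"eye-{rng_seed}"
    if subject_id is None:
        subject_id = f"subj-{rng_seed}"
    return SyntheticEye(
        eye_id=eye_id,
        subject_id=subject_id,
        laterality=laterality,
        true_group=params.group,
        skc_subtype=skc_subtype,
        pr_map=pr_map,
        epi_map=epi_map,
        bowman_map=bow_map,
        pentacam=TomographyRecord(penta),
        ms39=TomographyRecord(ms39),
    )


def blend_phenotypes(a: PhenotypeParams, b: PhenotypeParams, w: float) -> PhenotypeParams:
    """Interpolate phenotype ``a`` a fraction ``w`` of the way toward ``b``.

    All map levels, spreads and index means/sds are linearly interpolated;
    group identity, cone geometry and distribution shapes stay those of
    ``a``.  Used for fellow eyes of asymmetric keratoconus, which carry a
    subclinical label but sit close to the healthy phenotype.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend weight must lie in [0, 1]")

    def mix(x, y):
        return (1.0 - w) * x + w * y

    idx = {
        dev: {
            name: (mix(a.index_means_sds[dev][name][0], b.index_means_sds[dev][name][0]),
                   mix(a.index_means_sds[dev][name][1], b.index_means_sds[dev][name][1]))
            for name in a.index_means_sds[dev]
        }
        for dev in a.index_means_sds
    }
    return replace(
        a,
        pr_central_mean=mix(a.pr_central_mean, b.pr_central_mean),
        pr_central_sd=mix(a.pr_central_sd, b.pr_central_sd),
        epi_mean=mix(a.epi_mean, b.epi_mean),
        epi_sd=mix(a.epi_sd, b.epi_sd),
        bowman_mean=mix(a.bowman_mean, b.bowman_mean),
        bowman_sd=mix(a.bowman_sd, b.bowman_sd),
        pr_radial_gain=mix(a.pr_radial_gain, b.pr_radial_gain),
        pr_rhombus_amp=mix(a.pr_rhombus_amp, b.pr_rhombus_amp),
        pr_noise_sd=mix(a.pr_noise_sd, b.pr_noise_sd),
        epi_noise_sd=mix(a.epi_noise_sd, b.epi_noise_sd),
        bowman_noise_sd=mix(a.bowman_noise_sd, b.bowman_noise_sd),
        index_means_sds=idx,
    )


#: how far fellow-eye subclinical phenotypes sit toward healthy
FELLOW_EYE_BLEND = 0.6


def derive_eye_seed(base_seed: int, index: int) -> int:
    """Splittable per-eye seed: SeedSequence([base_seed, index]), masked to 31 bits."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def generate_cohort(
    n_healthy: int = 120,
    n_skc: int = 109,
    n_kc: int = 130,
    fellow_eye_fraction: float = 33.0 / 109.0,
    rng_seed: int = 0,
    phenotypes: dict[str, PhenotypeParams] | None = None,
) -> list[SyntheticEye]:
    """Generate a labeled cohort; defaults mirror the 120/109/130 study cohort.

    Subclinical eyes split into fellow eyes of asymmetric keratoconus and
    bilateral suspects by ``fellow_eye_fraction`` (round half up).  Per-eye
    seeds derive deterministically from ``rng_seed`` and the eye index.
    """
    if min(n_healthy, n_skc, n_kc) < 0:
        raise ValueError("counts must be >= 0")
    if not 0.0 <= fellow_eye_fraction <= 1.0:
        raise ValueError("fellow_eye_fraction must lie in [0, 1]")
    phen = phenotypes if phenotypes is not None else default_phenotypes()
    fellow = blend_phenotypes(phen["skc"], phen["healthy"], FELLOW_EYE_BLEND)
    n_fellow = int(np.floor(fellow_eye_fraction * n_skc + 0.5))
    plan: list[tuple[PhenotypeParams, str, str]] = (
        [(phen["healthy"], "healthy", "none")] * n_healthy
        + [(fellow, "skc", "fellow_eye")] * n_fellow
        + [(phen["skc"], "skc", "bilateral_suspect")] * (n_skc - n_fellow)
        + [(phen["kc"], "kc", "none")] * n_kc
    )
    cohort = []
    for i, (params, _, subtype) in enumerate(plan):
        cohort.append(
            generate_eye(
                params,
                derive_eye_seed(rng_seed, i),
                eye_id=f"eye{i:04d}",
                subject_id=f"subj{i:04d}",
                laterality="OD" if i % 2 == 0 else "OS",
                skc_subtype=subtype,
            )
        )
    return cohort


def synthesize_ascan_pair(
    true_pr: float,
    amplitude: float = 1.0,
    n_depth: int = 8,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> AScanPair:
    """Two-channel A-scan with a prescribed phase retardation.

    The noiseless channels satisfy ``A2/A1 = tan(true_pr)`` at every depth
    sample, so retardation recovery through ``arctan(A2/A1)`` is exact at
    ``noise_sd = 0``.  Channel noise is additive Gaussian, clipped at zero
    because amplitudes are magnitudes.
    """
    if not 0.0 <= true_pr <= 90.0:
        raise ValueError("true_pr must lie in [0, 90] degrees")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(rng_seed)
    theta = np.radians(true_pr)
    a1 = np.full(n_depth, amplitude * np.cos(theta))
    a2 = np.full(n_depth, amplitude * np.sin(theta))
    if noise_sd > 0:
        a1 = a1 + rng.normal(0.0, noise_sd, n_depth)
        a2 = a2 + rng.normal(0.0, noise_sd, n_depth)
    return AScanPair(np.clip(a1, 0.0, None), np.clip(a2, 0.0, None))


def synthesize_pr_volume(
    pr_field: np.ndarray,
    amplitude: float = 1.0,
    n_depth: int = 4,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
):
    """A-scan volume realizing a known retardation field, plus surface indices.

    Convenience for exercising the en-face extraction path: returns
    ``(volume, surface_index)`` where ``volume[iy][ix]`` is an A-scan pair
    with the field's retardation at that pixel and the surface sits at the
    last depth sample.
    """
    pr_field = np.asarray(pr_field, dtype=float)
    ny, nx = pr_field.shape
    volume = []
    for iy in range(ny):
        row = []
        for ix in range(nx):
            row.append(
                synthesize_ascan_pair(
                    pr_field[iy, ix], amplitude, n_depth, noise_sd,
                    rng_seed=derive_eye_seed(rng_seed, iy * nx + ix),
                )
            )
        volume.append(row)
    surface = np.full((ny, nx), n_depth - 1, dtype=int)
    return volume, surface
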