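"""End-to-end glue: cohort → device feature tables → model runs.

The PS-OCT path mirrors the acquisition pipeline: each en-face map is
smoothed with the 1×1 mm floating average, then fitted with order-6 Zernike
polynomials over an 8 mm pupil; the three 28-coefficient blocks concatenate
into the 84-feature vector.  The Pentacam and MS-39 paths read their fixed
index schemas straight from the per-eye device records.
"""

from __future__ import annotations

import pandas as pd

from .model import ModelRun, RFConfig, run_model
from .psoct import crop_field, smooth_map
from .zernike import (
    FeatureVector,
    assemble_ms39_features,
    assemble_pentacam_features,
    assemble_psoct_features,
    fit_zernike,
)

__all__ = ["psoct_features", "cohort_features", "features_frame", "run_device_models"]

SCHEMAS = ("PSOCT84", "PENTACAM32", "MS39_23")


def psoct_features(eye, order_max: int = 6, pupil_mm: float = 8.0,
                   smooth_mm: float = 1.0) -> FeatureVector:
    """84-feature PS-OCT vector for one eye (smooth → crop → fit × 3 maps)."""
    pr = crop_field(smooth_map(eye.pr_map, (smooth_mm, smooth_mm)), (8.0, 8.0))
    epi = smooth_map(eye.epi_map, (smooth_mm, smooth_mm))
    bow = smooth_map(eye.bowman_map, (smooth_mm, smooth_mm))
    return assemble_psoct_features(
        fit_zernike(pr, order_max, pupil_mm),
        fit_zernike(epi, order_max, pupil_mm),
        fit_zernike(bow, order_max, pupil_mm),
        eye_id=eye.eye_id,
    )


def cohort_features(cohort, schema: str, order_max: int = 6,
                    pupil_mm: float = 8.0) -> list[FeatureVector]:
    """Feature vectors for a whole cohort under one device schema."""
    if schema == "PSOCT84":
        return [psoct_features(e, order_max, pupil_mm) for e in cohort]
    if schema == "PENTACAM32":
        return [assemble_pentacam_features(e.pentacam, eye_id=e.eye_id) for e in cohort]
    if schema == "MS39_23":
        return [assemble_ms39_features(e.ms39, eye_id=e.eye_id) for e in cohort]
    raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")


def features_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (eye_id index, schema feature columns)."""
    if not features:
        raise ValueError("no feature vectors")
    names = features[0].names
    return pd.DataFrame(
        [f.values for f in features],
        index=pd.Index([f.eye_id for f in features], name="eye_id"),
        columns=list(names),
    )


def run_device_models(cohort, cfg: RFConfig = RFConfig(),
                      schemas=SCHEMAS) -> dict[str, ModelRun]:
    """Train and evaluate one LOOCV model per device schema on a cohort."""
    labels = [e.true_group for e in cohort]
    return {s: run_model(cohort_features(cohort, s), labels, cfg, schema=s) for s in schemas}
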