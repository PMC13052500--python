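"""Ground-truth diagnostic grouping from Scheimpflug tomography indices.

Eyes are assigned to one of three screening groups from the KISA% index, the
inferior–superior (IS) dioptric asymmetry, and the Belin/Ambrósio total
deviation score (BAD-D):

* keratoconus (kc):  KISA% > 60, IS > 3.0, BAD-D > 3.0 — all three;
* healthy:           KISA% < 60, IS < 1.4, BAD-D < 1.65 — all three, and no
  clinical suspicion;
* subclinical (skc): KISA% < 60, IS < 1.6, BAD-D < 2.6 — all three, with
  clinical suspicion (fellow eye of asymmetric keratoconus, or bilateral
  suspect findings on imaging).

The healthy index box is a strict subset of the subclinical box: the two
groups are distinguished by clinical context, carried here by the
``clinical_suspect`` flag, not by the indices alone.  All thresholds are
strict inequalities; an eye falling in none of the applicable boxes (or
exactly on a threshold) is ``indeterminate`` rather than silently assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["TomographyRecord", "GroupLabel", "classify_group", "audit_cohort_labels", "GROUPS"]

GROUPS = ("healthy", "skc", "kc")


@dataclass
class TomographyRecord:
    """Per-eye device indices as a named-field mapping.

    One record holds the export of a single device; the three screening
    indices are exposed as properties.  Field access by name (``rec["KMax"]``)
    serves the feature assemblers, which raise on missing fields.
    """

    indices: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.indices[key]

    def __contains__(self, key: str) -> bool:
        return key in self.indices

    def get(self, key: str, default=None):
        return self.indices.get(key, default)

    @property
    def kisa_percent(self) -> float:
        return self.indices["kisa_percent"]

    @property
    def is_value(self) -> float:
        return self.indices["is_value"]

    @property
    def badd(self) -> float:
        return self.indices["badd"]


@dataclass(frozen=True)
class GroupLabel:
    """Assigned group plus the per-criterion comparison trace."""

    label: str
    criteria_trace: dict[str, bool]


def classify_group(rec, clinical_suspect: bool = False) -> GroupLabel:
    """Assign healthy / skc / kc / indeterminate from the screening triple.

    ``rec`` is a :class:`TomographyRecord` or any object with
    ``kisa_percent``, ``is_value`` and ``badd`` attributes.  Precedence:
    the keratoconus box is checked first; then healthy (requires
    ``clinical_suspect`` False); then subclinical (requires it True).
    """
    k, i, b = float(rec.kisa_percent), float(rec.is_value), float(rec.badd)
    if not (math.isfinite(k) and math.isfinite(i) and math.isfinite(b)):
        raise ValueError("screening indices must be finite")
    trace = {
        "kc_kisa_gt_60": k > 60.0,
        "kc_is_gt_3.0": i > 3.0,
        "kc_badd_gt_3.0": b > 3.0,
        "healthy_kisa_lt_60": k < 60.0,
        "healthy_is_lt_1.4": i < 1.4,
        "healthy_badd_lt_1.65": b < 1.65,
        "skc_kisa_lt_60": k < 60.0,
        "skc_is_lt_1.6": i < 1.6,
        "skc_badd_lt_2.6": b < 2.6,
        "clinical_suspect": bool(clinical_suspect),
    }
    if trace["kc_kisa_gt_60"] and trace["kc_is_gt_3.0"] and trace["kc_badd_gt_3.0"]:
        label = "kc"
    elif (
        not clinical_suspect
        and trace["healthy_kisa_lt_60"]
        and trace["healthy_is_lt_1.4"]
        and trace["healthy_badd_lt_1.65"]
    ):
        label = "healthy"
    elif (
        clinical_suspect
        and trace["skc_kisa_lt_60"]
        and trace["skc_is_lt_1.6"]
        and trace["skc_badd_lt_2.6"]
    ):
        label = "skc"
    else:
        label = "indeterminate"
    return GroupLabel(label, trace)


def audit_cohort_labels(cohort) -> list[dict]:
    """Cross-check generated eyes against the index-based group criteria.

    Re-derives each eye's group from its Scheimpflug record (treating true
    subclinical eyes as clinically suspect) and reports every eye whose
    indices violate its intended group's criteria.  A valid synthetic cohort
    yields an empty list.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    mismatches = []
    for eye in cohort:
        assigned = classify_group(eye.pentacam, clinical_suspect=(eye.true_group == "skc"))
        if assigned.label != eye.true_group:
            mismatches.append(
                {
                    "eye_id": eye.eye_id,
                    "true_group": eye.true_group,
                    "assigned": assigned.label,
                    "trace": assigned.criteria_trace,
                }
            )
    return mismatches
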