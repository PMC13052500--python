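"""Cross-device model agreement, reclassification and proportion tests.

Three per-device models predicting the same eyes are compared by an exact
agreement partition (all three agree; exactly one pair agrees, attributed to
that pair; all three disagree), by reclassification tables within a
ground-truth subgroup (e.g. the fraction of subclinical eyes a model calls
healthy), by 2x2 chi-square proportion comparisons (no continuity correction
by default), and by Welch two-sample contrasts of per-eye parameters between
predicted subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import GROUPS

__all__ = [
    "VennPartition",
    "ReclassTable",
    "venn_partition",
    "reclassification",
    "compare_proportions",
    "parameter_table",
    "subgroup_contrast",
]


@dataclass(frozen=True)
class VennPartition:
    """Counts of per-eye agreement patterns among three prediction vectors."""

    n_total: int
    all_three_agree: int
    pair_only_ab: int
    pair_only_bc: int
    pair_only_ac: int
    none_agree: int

    def __post_init__(self) -> None:
        total = (
            self.all_three_agree
            + self.pair_only_ab
            + self.pair_only_bc
            + self.pair_only_ac
            + self.none_agree
        )
        if total != self.n_total:
            raise ValueError("agreement pattern counts do not partition the eye set")


@dataclass(frozen=True)
class ReclassTable:
    """Predicted-label tabulation of one ground-truth subgroup."""

    source_group: str
    counts: dict[str, int]
    proportions: dict[str, float]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def venn_partition(preds_a, preds_b, preds_c) -> VennPartition:
    """Exact per-eye agreement partition of three aligned prediction vectors.

    With three raters there are only three patterns per eye: all equal,
    exactly one equal pair, or all distinct; the counts therefore always sum
    to the number of eyes.
    """
    a, b, c = (np.asarray(v) for v in (preds_a, preds_b, preds_c))
    if not (len(a) == len(b) == len(c)):
        raise ValueError("prediction vectors must have equal length")
    ab, bc, ac = a == b, b == c, a == c
    all3 = ab & bc
    return VennPartition(
        n_total=len(a),
        all_three_agree=int(all3.sum()),
        pair_only_ab=int((ab & ~all3).sum()),
        pair_only_bc=int((bc & ~all3).sum()),
        pair_only_ac=int((ac & ~all3).sum()),
        none_agree=int((~ab & ~bc & ~ac).sum()),
    )


def reclassification(
    per_eye: pd.DataFrame,
    source_group: str,
    subgroup_filter: str | None = None,
    subtypes: dict[str, str] | None = None,
) -> ReclassTable:
    """Tabulate model predictions within one ground-truth subgroup.

    ``subgroup_filter`` optionally restricts to a subclinical subtype
    (``fellow_eye`` or ``bilateral_suspect``), looked up per eye in
    ``subtypes``.
    """
    sel = per_eye["true"] == source_group
    if subgroup_filter is not None:
        if subtypes is None:
            raise ValueError("subgroup_filter requires a subtypes mapping")
        sel &= per_eye["eye_id"].map(lambda e: subtypes.get(e) == subgroup_filter)
    sub = per_eye[sel]
    if len(sub) == 0:
        raise ValueError(f"no eyes with true group {source_group!r}"
                         + (f" and subtype {subgroup_filter!r}" if subgroup_filter else ""))
    counts = {g: int((sub["predicted"] == g).sum()) for g in GROUPS}
    n = len(sub)
    return ReclassTable(source_group, counts, {g: counts[g] / n for g in GROUPS})


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square comparison of two proportions (1 df, two-sided).

    Tests k1/n1 against k2/n2 on the 2x2 table ``[[k1, n1-k1], [k2, n2-k2]]``.
    The continuity correction is off by default; a structurally degenerate
    table (an all-zero margin) is an error.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def parameter_table(cohort) -> pd.DataFrame:
    """Per-eye clinical parameters used in subgroup contrasts.

    Central (2 mm) means of the three PS-OCT maps plus the main tomography
    indices of both devices, indexed by eye_id.
    """
    from .psoct import central_mean

    rows = []
    for eye in cohort:
        rows.append(
            {
                "eye_id": eye.eye_id,
                "PR": central_mean(eye.pr_map),
                "ELT": central_mean(eye.epi_map),
                "BLT": central_mean(eye.bowman_map),
                "BAD-D": eye.pentacam.badd,
                "IS": eye.pentacam.is_value,
                "KISA": eye.pentacam.kisa_percent,
                "Kmax": eye.pentacam["KMax"],
                "TCT": eye.pentacam["TCT"],
                "CCT": eye.pentacam["CCT"],
                "AntKmax": eye.ms39["AntKmax"],
                "BWKmax": eye.ms39["BWKmax"],
                "CET": eye.ms39["CET"],
            }
        )
    return pd.DataFrame(rows).set_index("eye_id")


def subgroup_contrast(
    per_eye: pd.DataFrame,
    params: pd.DataFrame,
    source_group: str = "skc",
    split: tuple[str, str] = ("healthy", "skc"),
) -> pd.DataFrame:
    """Welch contrasts of per-eye parameters between two predicted subgroups.

    Restricts to eyes whose true group is ``source_group``, splits them by
    predicted label into ``split[0]`` vs ``split[1]``, and reports mean, sd,
    min and max per subgroup with a Welch two-sample p-value per parameter.
    Subgroups smaller than 2, or parameters with zero variance in both
    subgroups, are summarized without a test and flagged.
    """
    sub = per_eye[per_eye["true"] == source_group]
    ids_a = sub.loc[sub["predicted"] == split[0], "eye_id"]
    ids_b = sub.loc[sub["predicted"] == split[1], "eye_id"]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"both predicted subgroups {split} must be nonempty")
    rows = []
    for col in params.columns:
        xa = params.loc[ids_a, col].to_numpy(dtype=float)
        xb = params.loc[ids_b, col].to_numpy(dtype=float)
        row = {"parameter": col, "n_a": len(xa), "n_b": len(xb)}
        for tag, x in (("a", xa), ("b", xb)):
            row[f"mean_{tag}"] = float(x.mean())
            row[f"sd_{tag}"] = float(x.std(ddof=1)) if len(x) > 1 else np.nan
            row[f"min_{tag}"] = float(x.min())
            row[f"max_{tag}"] = float(x.max())
        degenerate = (
            len(xa) < 2
            or len(xb) < 2
            or (np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0)
        )
        if degenerate:
            row["t"], row["p"], row["flagged"] = np.nan, np.nan, True
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            row["t"], row["p"], row["flagged"] = float(t), float(p), False
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
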