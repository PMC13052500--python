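"""Plain-text storage for corneal maps, cohorts and analysis tables.

A map file is a whitespace-delimited numeric grid preceded by a single
header line ``# {json}`` carrying extent (mm), spacing (mm), units, quantity
and the mask encoding; invalid pixels are written as NaN.  A cohort
directory holds ``metadata.csv`` (identity, group, subtype and one column
block per device record, prefixed ``pentacam_`` / ``ms39_``) plus a ``maps/``
folder with three map files per eye.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import TomographyRecord
from .psoct import CornealMap
from .simulate import SyntheticEye

__all__ = ["write_map", "read_map", "write_cohort", "read_cohort"]

_MAP_SUFFIXES = {"pr_map": "pr", "epi_map": "epi", "bowman_map": "bowman"}


def write_map(cmap: CornealMap, path) -> None:
    header = {
        "extent_mm": list(cmap.extent_mm),
        "spacing_mm": list(cmap.spacing_mm),
        "units": cmap.units,
        "quantity": cmap.quantity,
        "mask": "nan",
    }
    values = np.where(cmap.mask, cmap.values, np.nan)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, values, fmt="%.8g")


def read_map(path) -> CornealMap:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[2:])
        values = np.loadtxt(fh, ndmin=2)
    mask = ~np.isnan(values)
    values = np.where(mask, values, 0.0)
    return CornealMap(
        values,
        tuple(header["spacing_mm"]),
        header["quantity"],
        units=header["units"],
        mask=mask,
    )


def write_cohort(cohort, out_dir) -> None:
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in cohort:
        row = {
            "eye_id": eye.eye_id,
            "subject_id": eye.subject_id,
            "laterality": eye.laterality,
            "true_group": eye.true_group,
            "skc_subtype": eye.skc_subtype,
        }
        row.update({f"pentacam_{k}": v for k, v in sorted(eye.pentacam.indices.items())})
        row.update({f"ms39_{k}": v for k, v in sorted(eye.ms39.indices.items())})
        rows.append(row)
        for attr, suffix in _MAP_SUFFIXES.items():
            write_map(getattr(eye, attr), out / "maps" / f"{eye.eye_id}_{suffix}.txt")
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)


def read_cohort(in_dir) -> list[SyntheticEye]:
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    cohort = []
    for _, row in meta.iterrows():
        maps = {
            attr: read_map(src / "maps" / f"{row['eye_id']}_{suffix}.txt")
            for attr, suffix in _MAP_SUFFIXES.items()
        }
        penta = {
            k[len("pentacam_"):]: float(v)
            for k, v in row.items() if k.startswith("pentacam_")
        }
        ms39 = {k[len("ms39_"):]: float(v) for k, v in row.items() if k.startswith("ms39_")}
        cohort.append(
            SyntheticEye(
                eye_id=row["eye_id"],
                subject_id=row["subject_id"],
                laterality=row["laterality"],
                true_group=row["true_group"],
                skc_subtype=row["skc_subtype"],
                pr_map=maps["pr_map"],
                epi_map=maps["epi_map"],
                bowman_map=maps["bowman_map"],
                pentacam=TomographyRecord(penta),
                ms39=TomographyRecord(ms39),
            )
        )
    return cohort
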