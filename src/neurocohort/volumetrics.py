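"""Derived imaging measures from precomputed segmentation tables.

This module consumes segmentation *result* tables (one row per subject for
tissue volumes, one row per lesion for white-matter lesions) and derives
the quantities the baseline analyses consume:

* TIV-normalized tissue and hippocampal volume fractions,
* brain parenchymal fraction (GM + WM over total intracranial volume),
* white-matter-lesion aggregates by class (periventricular,
  juxtacortical, deep white), as TIV fractions plus a total lesion count.

All fractions are stored unitless; report layers multiply by 100 when a
percent presentation is wanted.  Visual ratings (e.g. Fazekas) are carried
through untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "LESION_CLASSES",
    "WMLSummary",
    "tiv_normalize",
    "parenchymal_fraction",
    "aggregate_wml",
    "derive_measures",
    "read_aseg_stats",
]

LESION_CLASSES = ("periventricular", "juxtacortical", "deep_white")

VOLUME_COLUMNS = (
    "tiv",
    "gm_volume",
    "wm_volume",
    "csf_volume",
    "hippocampus_left",
    "hippocampus_right",
)


@dataclass
class WMLSummary:
    """Per-subject white-matter-lesion aggregate (TIV fractions)."""

    subject_id: str
    total_lesion_count: int
    total_lesion_volume_frac: float
    periventricular_frac: float
    juxtacortical_frac: float
    deep_white_frac: float


def tiv_normalize(volume: float, tiv: float) -> float:
    """Express a volume as a fraction of total intracranial volume."""
    if not np.isfinite(tiv) or tiv <= 0:
        raise ValidationError(f"tiv must be positive, got {tiv!r}")
    if not np.isfinite(volume) or volume < 0:
        raise ValidationError(f"volume must be >= 0, got {volume!r}")
    return volume / tiv


def parenchymal_fraction(gm: float, wm: float, tiv: float) -> float:
    """Brain parenchymal fraction: (GM + WM) / TIV, a global atrophy index."""
    return tiv_normalize(gm, tiv) + tiv_normalize(wm, tiv)


def aggregate_wml(lesions: pd.DataFrame, tiv: float, subject_id: str = "") -> WMLSummary:
    """Aggregate one subject's lesion records into class-wise TIV fractions.

    ``lesions`` has one row per lesion with ``lesion_class`` and ``volume``
    (mm^3) columns; classes absent from the input contribute zero.
    """
    if not np.isfinite(tiv) or tiv <= 0:
        raise ValidationError(f"tiv must be positive, got {tiv!r}")
    per_class = dict.fromkeys(LESION_CLASSES, 0.0)
    count = 0
    if len(lesions):
        for col in ("lesion_class", "volume"):
            if col not in lesions.columns:
                raise SchemaError(f"lesion table lacks column {col!r}")
        unknown = set(lesions["lesion_class"]) - set(LESION_CLASSES)
        if unknown:
            raise ValidationError(f"unknown lesion class labels: {sorted(unknown)}")
        if (lesions["volume"] <= 0).any():
            raise ValidationError("lesion volumes must be positive")
        sums = lesions.groupby("lesion_class")["volume"].sum()
        for cls, v in sums.items():
            per_class[cls] = v / tiv
        count = int(len(lesions))
    total = sum(per_class.values())
    return WMLSummary(
        subject_id=subject_id,
        total_lesion_count=count,
        total_lesion_volume_frac=total,
        periventricular_frac=per_class["periventricular"],
        juxtacortical_frac=per_class["juxtacortical"],
        deep_white_frac=per_class["deep_white"],
    )


def derive_measures(volumes: pd.DataFrame, lesions: pd.DataFrame) -> pd.DataFrame:
    """Join TIV-normalized volume fractions with the WML summary per subject.

    ``volumes`` carries one row per subject (``subject_id``, the columns of
    :data:`VOLUME_COLUMNS`, and any thickness / visual-rating columns, which
    pass through untouched); ``lesions`` one row per lesion.
    """
    for col in ("subject_id",) + VOLUME_COLUMNS:
        if col not in volumes.columns:
            raise SchemaError(f"volumetrics table lacks column {col!r}")
    if len(lesions) and "subject_id" not in lesions.columns:
        raise SchemaError("lesion table lacks column 'subject_id'")

    rows = []
    grouped = lesions.groupby("subject_id") if len(lesions) else None
    for _, r in volumes.iterrows():
        tiv = float(r["tiv"])
        gm, wm, csf = (float(r[c]) for c in ("gm_volume", "wm_volume", "csf_volume"))
        if gm + wm + csf > tiv * 1.05:
            raise ValidationError(
                f"gm+wm+csf exceeds 1.05 x TIV for subject {r['subject_id']}"
            )
        sub_lesions = (
            grouped.get_group(r["subject_id"])
            if grouped is not None and r["subject_id"] in grouped.groups
            else pd.DataFrame()
        )
        wml = aggregate_wml(sub_lesions, tiv, subject_id=str(r["subject_id"]))
        derived = {
            "subject_id": r["subject_id"],
            "tiv": tiv,
            "gm_frac": tiv_normalize(gm, tiv),
            "wm_frac": tiv_normalize(wm, tiv),
            "csf_frac": tiv_normalize(csf, tiv),
            "parenchymal_frac": parenchymal_fraction(gm, wm, tiv),
            "hippocampus_left_frac": tiv_normalize(float(r["hippocampus_left"]), tiv),
            "hippocampus_right_frac": tiv_normalize(float(r["hippocampus_right"]), tiv),
            "total_lesion_count": wml.total_lesion_count,
            "total_lesion_volume_frac": wml.total_lesion_volume_frac,
            "periventricular_frac": wml.periventricular_frac,
            "juxtacortical_frac": wml.juxtacortical_frac,
            "deep_white_frac": wml.deep_white_frac,
        }
        # pass-through columns: cortical thickness, visual ratings, ...
        for c in volumes.columns:
            if c not in derived and c not in VOLUME_COLUMNS:
                derived[c] = r[c]
        rows.append(derived)
    return pd.DataFrame(rows)


# FreeSurfer aseg.stats-style measure lines look like
#   # Measure EstimatedTotalIntraCranialVol, eTIV, ..., 1485929.141, mm^3
_MEASURE_RE = re.compile(r"^#\s*Measure\s+(\S+?),\s*(\S+?),.*?,\s*([\d.eE+-]+),\s*(\S+)\s*$")


def read_aseg_stats(path) -> dict:
    """Read global measures from a FreeSurfer ``aseg.stats``-style text file.

    Returns a mapping from measure short name (e.g. ``eTIV``,
    ``TotalGrayVol``) to its value in the file's units.
    """
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            m = _MEASURE_RE.match(line.strip())
            if m:
                out[m.group(2)] = float(m.group(3))
    if not out:
        raise SchemaError(f"no '# Measure' lines found in {path}")
    return out
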