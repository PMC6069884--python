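"""Normalisation, fold changes and Al-responsiveness calls.

Counts are globally normalised to counts-per-million of valid reads per
library, replicates are averaged after scaling, and the Al/control log2
fold change is computed per genotype.  Zeros are not pseudocounted: a
miRNA seen in exactly one of the two conditions gets the EXCLUSIVE
sentinel (direction recorded via the call), one seen in neither gets
ABSENT.  Regulation thresholds are inclusive at +/-0.5:
up iff fc >= 0.5, down iff fc <= -0.5, otherwise unchanged.

A miRNA is responsive when (1) its largest normalised value over the four
genotype x treatment conditions exceeds 100 reads, (2) for newly found
miRNAs (candidates) the precursor MFEI exceeds 0.85, and (3) it is up,
down or treatment-exclusive in at least one genotype.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSIVE",
    "ABSENT",
    "ExpressionProfile",
    "normalize",
    "fold_change",
    "classify_regulation",
    "call_responsive",
    "classify_table",
]


class _Sentinel(enum.Enum):
    EXCLUSIVE = "exclusive"
    ABSENT = "absent"

    def __repr__(self):
        return self.value


EXCLUSIVE = _Sentinel.EXCLUSIVE
ABSENT = _Sentinel.ABSENT

FC_THRESHOLD = 0.5
MIN_NORMALIZED = 100.0
MIN_MFEI = 0.85
CPM_SCALE = 1e6


@dataclass
class ExpressionProfile:
    """Per-miRNA normalised expression and regulation calls."""

    mirna: str
    normalized: Dict[tuple, float]  # (genotype, treatment) -> CPM
    fc: Dict[str, object] = field(default_factory=dict)  # genotype -> float | sentinel
    call: Dict[str, str] = field(default_factory=dict)
    responsive: bool = False


def normalize(
    counts: pd.DataFrame,
    design: Mapping[str, tuple] | None = None,
    scale: float = CPM_SCALE,
):
    """Scale each library to ``scale`` total, then average replicates.

    ``counts`` is a tag/miRNA x library matrix of raw valid-read counts;
    ``design`` maps library id -> (genotype, treatment); when omitted it is
    parsed from ids of the form ``<genotype>_<treatment>_<replicate>``.
    Returns (cpm, condition_means) where condition_means has one column per
    (genotype, treatment).
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"library {zero.index[0]!r} has zero total count")
    cpm = counts * (scale / totals)
    if design is None:
        design = {}
        for lib in counts.columns:
            parts = str(lib).split("_")
            if len(parts) < 3:
                raise ValueError(f"cannot parse design from library id {lib!r}")
            design[lib] = (parts[0], parts[1])
    groups: Dict[tuple, list] = {}
    for lib, cond in design.items():
        groups.setdefault(tuple(cond), []).append(lib)
    cond_means = pd.DataFrame(
        {cond: cpm[libs].mean(axis=1) for cond, libs in sorted(groups.items())}
    )
    return cpm, cond_means


def fold_change(al: float, control: float):
    """log2(Al/control); EXCLUSIVE if exactly one is zero, ABSENT if both."""
    if al < 0 or control < 0:
        raise ValueError("normalized reads must be >= 0")
    if al == 0 and control == 0:
        return ABSENT
    if al == 0 or control == 0:
        return EXCLUSIVE
    return float(math.log2(al / control))


def classify_regulation(fc: float, threshold: float = FC_THRESHOLD) -> str:
    if not np.isfinite(fc):
        raise ValueError("fold change must be finite")
    if fc >= threshold:
        return "up"
    if fc <= -threshold:
        return "down"
    return "unchanged"


def _call(al: float, control: float) -> tuple:
    fc = fold_change(al, control)
    if fc is ABSENT:
        return fc, "absent"
    if fc is EXCLUSIVE:
        return fc, "exclusive_present"
    return fc, classify_regulation(fc)


def build_profiles(
    cond_means: pd.DataFrame,
    genotypes=("GP", "XZ29"),
    treatments=("control", "Al"),
) -> Dict[str, ExpressionProfile]:
    """Fold changes and calls for every row of the condition-mean matrix."""
    ctrl, al = treatments
    profiles = {}
    for name, row in cond_means.iterrows():
        norm = {c: float(row[c]) for c in cond_means.columns}
        prof = ExpressionProfile(mirna=name, normalized=norm)
        for g in genotypes:
            fc, call = _call(norm.get((g, al), 0.0), norm.get((g, ctrl), 0.0))
            prof.fc[g] = fc
            prof.call[g] = call
        profiles[name] = prof
    return profiles


def call_responsive(
    profiles: Mapping[str, ExpressionProfile],
    records: Optional[Mapping[str, object]] = None,
    min_normalized: float = MIN_NORMALIZED,
    min_mfei: float = MIN_MFEI,
) -> pd.DataFrame:
    """Apply the three responsiveness rules; returns the report table.

    ``records`` maps miRNA name -> MiRNARecord (for class and MFEI); rule 2
    applies to candidate-class miRNAs only.  Sets ``profile.responsive``
    in place and returns a table with one row per miRNA.
    """
    rows = []
    for name, prof in profiles.items():
        max_norm = max(prof.normalized.values(), default=0.0)
        rule1 = max_norm > min_normalized
        rec = records.get(name) if records else None
        mfei = None
        rule2 = True
        if rec is not None and getattr(rec, "class_label", None) == "candidate":
            mfei = rec.metrics.mfei if rec.metrics else None
            rule2 = mfei is not None and mfei > min_mfei
        rule3 = any(c in ("up", "down", "exclusive_present") for c in prof.call.values())
        prof.responsive = bool(rule1 and rule2 and rule3)
        row = {"mirna": name, "max_normalized": max_norm, "mfei": mfei}
        for g, fc in prof.fc.items():
            row[f"{g}_fc"] = fc.value if isinstance(fc, _Sentinel) else round(fc, 4)
            row[f"{g}_call"] = prof.call[g]
        row["responsive"] = prof.responsive
        rows.append(row)
    return pd.DataFrame(rows)


def classify_table(
    fc_table: pd.DataFrame,
    genotypes=("GP", "XZ29"),
    threshold: float = FC_THRESHOLD,
):
    """Per-genotype regulation counts from a fold-change table.

    ``fc_table`` needs columns ``<genotype>_fc`` and optionally
    ``exclusive_to`` naming the only genotype expressing that miRNA; a
    printed fold change of 0.00 for a genotype the miRNA is absent from is
    counted as exclusive (absent), not unchanged.  Returns (per-genotype
    counts dict, union responsive count).
    """
    counts = {g: {"up": 0, "down": 0, "unchanged": 0, "exclusive": 0} for g in genotypes}
    responsive_rows = 0
    for idx, row in fc_table.iterrows():
        responsive = False
        for g in genotypes:
            col = f"{g}_fc"
            if col not in row:
                raise ValueError(f"row {idx}: missing column {col!r}")
            excl = row.get("exclusive_to", "")
            excl = "" if pd.isna(excl) else str(excl).strip()
            if excl and excl != g:
                counts[g]["exclusive"] += 1
                continue
            try:
                fc = float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"row {idx}: malformed fold change {row[col]!r}") from None
            call = classify_regulation(fc, threshold)
            counts[g][call] += 1
            if call != "unchanged":
                responsive = True
        if responsive:
            responsive_rows += 1
    return counts, responsive_rows
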