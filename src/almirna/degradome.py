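"""Degradome (PARE) mapping and cleavage-site categorisation.

Degradome reads mark uncapped mRNA 5' ends; a pile-up of 5' ends opposite
miRNA positions 10-11 of a predicted site evidences miRNA-guided cleavage.
Reads are anchored by their first 20 nt with exact sense-strand matching;
a read matching n transcripts contributes 1/n to each.  The signal at a
predicted cleavage site is ranked into categories 0-4 relative to the rest
of its transcript profile:

    0: more than one read, unique transcript maximum
    1: more than one read, shares the maximum, above the transcript mean
    4: exactly one raw read at the site
    2: above the transcript mean, not a maximum
    3: at most the mean, but non-zero

evaluated in that order; a site with no reads is undetected (N).  By
default a target is called present (Y) at category <= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .io import normalize_seq

__all__ = [
    "DegradationProfile",
    "DegradomeHit",
    "map_degradome",
    "categorize",
    "annotate_interactions",
]

ANCHOR_LEN = 20
MIN_READ_LEN = 18
DETECT_MAX_CATEGORY = 2


@dataclass
class DegradationProfile:
    """Per-position degradome 5'-end counts for one transcript."""

    transcript: str
    counts: Dict[int, float] = field(default_factory=dict)  # 1-based position
    length: int = 0

    @property
    def total(self) -> float:
        return sum(self.counts.values())


@dataclass
class DegradomeHit:
    transcript: str
    cleavage_pos: int
    reads_at_site: float
    category: Optional[int]
    detected: str  # 'Y' | 'N'


def map_degradome(
    reads: Iterable, transcripts: List[Tuple[str, str]], anchor_len: int = ANCHOR_LEN
) -> Dict[str, DegradationProfile]:
    """Map reads to transcripts by exact 5'-anchored matching.

    ``reads`` are sequences or (name, sequence) pairs, >= 18 nt after
    trimming; the first ``anchor_len`` nt must match a transcript exactly
    (sense strand).  Multi-mapping reads count 1/n per location.
    """
    index: Dict[str, List[Tuple[str, int]]] = {}
    profiles: Dict[str, DegradationProfile] = {}
    for tid, seq in transcripts:
        seq = normalize_seq(seq)
        profiles[tid] = DegradationProfile(tid, length=len(seq))
        for p in range(0, len(seq) - anchor_len + 1):
            index.setdefault(seq[p : p + anchor_len], []).append((tid, p + 1))
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        seq = normalize_seq(seq)
        if len(seq) < MIN_READ_LEN:
            continue
        hits = index.get(seq[:anchor_len])
        if not hits:
            continue
        w = 1.0 / len(hits)
        for tid, pos in hits:
            prof = profiles[tid]
            prof.counts[pos] = prof.counts.get(pos, 0.0) + w
    return profiles


def categorize(
    profile: DegradationProfile,
    cleavage_pos: int,
    detect_max_category: int = DETECT_MAX_CATEGORY,
) -> DegradomeHit:
    """Rank the degradome signal at a predicted cleavage site."""
    if profile.length and not 1 <= cleavage_pos <= profile.length:
        raise ValueError(
            f"position {cleavage_pos} outside transcript {profile.transcript}"
        )
    at_site = profile.counts.get(cleavage_pos, 0.0)
    if at_site <= 0:
        return DegradomeHit(profile.transcript, cleavage_pos, 0.0, None, "N")
    values = list(profile.counts.values())
    vmax = max(values)
    # mean over covered positions of the transcript profile
    mean = profile.total / max(profile.length, 1)
    n_max = sum(1 for v in values if v == vmax)
    if at_site > 1 and at_site == vmax and n_max == 1:
        cat = 0
    elif at_site > 1 and at_site == vmax and at_site > mean:
        cat = 1
    elif abs(at_site - 1.0) < 1e-9:
        cat = 4
    elif at_site > mean:
        cat = 2
    else:
        cat = 3
    detected = "Y" if cat <= detect_max_category else "N"
    return DegradomeHit(profile.transcript, cleavage_pos, at_site, cat, detected)


def annotate_interactions(
    interactions,
    profiles: Dict[str, DegradationProfile],
    detect_max_category: int = DETECT_MAX_CATEGORY,
):
    """Attach degradome category and Y/N to predicted target interactions.

    Returns (interactions, summary) where summary counts detected
    interactions and miRNAs.
    """
    for it in interactions:
        prof = profiles.get(it.transcript)
        if prof is None or prof.total == 0:
            it.degradome_category = None
            it.degradome_detected = "N"
            continue
        hit = categorize(prof, it.cleavage_site, detect_max_category)
        it.degradome_category = hit.category
        it.degradome_detected = hit.detected
    detected = [it for it in interactions if it.degradome_detected == "Y"]
    summary = {
        "interactions": len(list(interactions)),
        "detected_interactions": len(detected),
        "detected_mirnas": len({it.mirna for it in detected}),
        "detected_transcripts": len({it.transcript for it in detected}),
    }
    return interactions, summary


def profiles_table(profiles: Dict[str, DegradationProfile]) -> pd.DataFrame:
    rows = []
    for tid, prof in sorted(profiles.items()):
        for pos in sorted(prof.counts):
            rows.append({"transcript": tid, "position": pos, "count": prof.counts[pos]})
    return pd.DataFrame(rows, columns=["transcript", "position", "count"])
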