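"""Assign unique tags to miRNA classes: known, new member, or candidate.

A tag is *known* when it matches a mature reference end-gap-free with at
most two internal mismatches and up to three nucleotides of 5'/3' length
variation.  A tag failing that but lying (<=2 substitutions, no indels) on
one arm of a reference precursor hairpin is a *new member* of that known
family.  Remaining tags with an exact genome hit become *candidates* when
one of the 120-nt flank windows around the hit folds into a stem-loop
passing all ten hairpin criteria.  Precedence is known > new_member >
candidate and every distinct mature sequence yields at most one record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import fold as _fold
from .io import normalize_seq, revcomp

__all__ = [
    "MiRNARecord",
    "KnownMatch",
    "PrecursorIndex",
    "match_known",
    "match_precursor_arm",
    "discover_candidates",
    "classify_all",
    "ClassificationResult",
]

MAX_MISMATCHES = 2
MAX_END_OFFSET = 3
MAX_GENOME_HITS = 20
FLANK = 120
MAX_LOOP_OVERLAP = 4  # nt of a tag allowed to protrude into the terminal loop


@dataclass(frozen=True)
class KnownMatch:
    reference_id: str
    mismatches: int
    offset5: int  # tag start relative to reference start (+ = overhang)
    offset3: int


@dataclass
class MiRNARecord:
    name: str
    class_label: str  # known | new_member | candidate
    mature_seq: str
    match: Optional[KnownMatch] = None
    arm: Optional[str] = None  # for new members: 5p | 3p
    locus: Optional[Tuple[str, int, int, str]] = None  # chrom, start, end, strand
    precursor: Optional[_fold.HairpinStructure] = None
    metrics: Optional[_fold.FoldMetrics] = None
    report: Optional[_fold.CriteriaReport] = None


def match_known(
    tag: str,
    mature_ref: List[Tuple[str, str]],
    max_mismatches: int = MAX_MISMATCHES,
    max_end_offset: int = MAX_END_OFFSET,
) -> Optional[KnownMatch]:
    """Best end-gap-free match of a tag against the mature reference.

    The tag may start up to ``max_end_offset`` nt before or after the
    reference 5' end and likewise at the 3' end; substitutions are counted
    over the overlap only.  Best hit = fewest mismatches, then smallest
    total end offset, then first reference in file order.
    """
    if not mature_ref:
        raise ValueError("empty mature reference")
    tag = normalize_seq(tag)
    best = None
    for order, (name, ref) in enumerate(mature_ref):
        ref = normalize_seq(ref)
        for d in range(-max_end_offset, max_end_offset + 1):
            off3 = d + len(tag) - len(ref)
            if abs(off3) > max_end_offset:
                continue
            mm = 0
            for i, c in enumerate(tag):
                j = d + i
                if 0 <= j < len(ref) and ref[j] != c:
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                key = (mm, abs(d) + abs(off3), order)
                if best is None or key < best[0]:
                    best = (key, KnownMatch(name, mm, d, off3))
    return best[1] if best else None


class PrecursorIndex:
    """Reference precursors folded once, with their arm boundaries."""

    def __init__(self, precursor_ref: List[Tuple[str, str]]):
        self.entries = []  # (name, seq, inner_i, inner_j) 1-based loop-closing pair
        for name, seq in precursor_ref:
            seq = normalize_seq(seq)
            if len(seq) < 20:
                warnings.warn(f"precursor {name} too short to fold; skipped")
                continue
            st = _fold.fold(seq)
            pairs = sorted(st.pairs)
            if not pairs or _fold._terminal_loops(pairs) != 1:
                warnings.warn(f"precursor {name} does not fold into a single hairpin; skipped")
                continue
            inner_i, inner_j = pairs[-1]
            self.entries.append((name, seq, inner_i, inner_j))


def match_precursor_arm(
    tag: str,
    precursors: PrecursorIndex | List[Tuple[str, str]],
    max_mismatches: int = MAX_MISMATCHES,
):
    """Locate a tag on the 5' or 3' arm of a reference precursor.

    Substitution-only matching (no indels); the tag may protrude at most
    ``MAX_LOOP_OVERLAP`` nt into the terminal loop.  Returns
    (precursor_name, arm, mismatches, start) or None.
    """
    if not isinstance(precursors, PrecursorIndex):
        precursors = PrecursorIndex(precursors)
    tag = normalize_seq(tag)
    L = len(tag)
    best = None
    for order, (name, seq, inner_i, inner_j) in enumerate(precursors.entries):
        for s in range(0, len(seq) - L + 1):
            start, end = s + 1, s + L  # 1-based inclusive
            if end <= inner_i + MAX_LOOP_OVERLAP:
                arm = "5p"
            elif start >= inner_j - MAX_LOOP_OVERLAP:
                arm = "3p"
            else:
                continue
            mm = sum(1 for a, b in zip(tag, seq[s : s + L]) if a != b)
            if mm <= max_mismatches:
                key = (mm, order, s)
                if best is None or key < best[0]:
                    best = (key, (name, arm, mm, start))
    return best[1] if best else None


class _GenomeIndex:
    def __init__(self, genome: str, chrom: str = "chr1"):
        self.seq = normalize_seq(genome)
        self.chrom = chrom

    def hits(self, tag: str):
        """All exact occurrences as (start0, strand); sense first."""
        out = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            p = self.seq.find(query)
            while p >= 0:
                out.append((p, strand))
                p = self.seq.find(query, p + 1)
        return out


def _candidate_windows(genome: str, h: int, L: int, strand: str, flank: int = FLANK):
    """Yield (window_seq, mature_span, genome_start0) for the three flank windows.

    Windows are oriented so the tag reads sense within them; the cheaper
    one-sided windows come before the full window.
    """
    n = len(genome)
    specs = [
        (max(0, h - flank), h + L),      # 5'-extended
        (h, min(n, h + L + flank)),      # 3'-extended
        (max(0, h - flank), min(n, h + L + flank)),  # full
    ]
    for (a, b) in specs:
        win = genome[a:b]
        s0 = h - a  # tag offset within the + strand window
        if strand == "-":
            win = revcomp(win)
            s0 = len(win) - (s0 + L)
        if len(win) < 20:
            continue
        yield win, (s0 + 1, s0 + L), a


def discover_candidates(
    tags: List[str],
    genome: str,
    chrom: str = "chr1",
    max_hits: int = MAX_GENOME_HITS,
    flank: int = FLANK,
    name_prefix: str = "PC-miR",
    start_index: int = 1,
) -> List[MiRNARecord]:
    """Genome-anchored hairpin discovery for unmatched tags.

    Tags are sorted before naming so discovery order (and hence PC-miR
    numbering) is independent of input order.  A tag with more than
    ``max_hits`` exact genome hits is skipped; the first hit in genome
    order anchors the locus.
    """
    idx = _GenomeIndex(genome, chrom)
    records = []
    k = start_index
    for tag in sorted(set(normalize_seq(t) for t in tags)):
        hits = idx.hits(tag)
        if not hits or len(hits) > max_hits:
            continue
        h, strand = hits[0]
        L = len(tag)
        found = None
        for win, span, _a in _candidate_windows(idx.seq, h, L, strand, flank):
            structure = _fold.fold(win)
            for sub, sub_span in _fold.enclosing_stemloops(structure, span):
                rep = _fold.check_criteria(sub, sub_span)
                if rep.passed:
                    found = (sub, rep)
                    break
            if found:
                break
        if found is None:
            continue
        sub, rep = found
        records.append(
            MiRNARecord(
                name=f"{name_prefix}{k}",
                class_label="candidate",
                mature_seq=tag,
                locus=(chrom, h + 1, h + L, strand),
                precursor=sub,
                metrics=_fold.fold_metrics(sub),
                report=rep,
            )
        )
        k += 1
    return records


@dataclass
class ClassificationResult:
    records: List[MiRNARecord]
    by_sequence: Dict[str, MiRNARecord]
    class_counts: Dict[str, int]
    length_summary: pd.DataFrame  # class x length counts
    venn: Dict[str, int]  # per-genotype detected / shared counts
    detected: Dict[str, set] = field(default_factory=dict)


def classify_all(
    tags,
    mature_ref: List[Tuple[str, str]],
    precursor_ref: List[Tuple[str, str]],
    genome: str,
    chrom: str = "chr1",
) -> ClassificationResult:
    """Classify every valid tag; returns records plus summary tables.

    ``tags`` maps sequence -> UniqueTag (only bin == 'valid' is used).
    Known matches inherit the reference name; collisions get a numeric
    suffix.  Genotype detection sets use per-library counts, with the
    genotype read from the library id prefix (``<genotype>_...``).
    """
    valid = {s: t for s, t in tags.items() if getattr(t, "bin", "valid") == "valid"}
    pre_index = PrecursorIndex(precursor_ref)
    records: List[MiRNARecord] = []
    by_seq: Dict[str, MiRNARecord] = {}
    used_names: Dict[str, int] = {}

    def unique_name(base: str) -> str:
        if base not in used_names:
            used_names[base] = 1
            return base
        used_names[base] += 1
        return f"{base}_{used_names[base]}"

    unmatched = []
    for seq in sorted(valid):
        m = match_known(seq, mature_ref) if mature_ref else None
        if m is not None:
            rec = MiRNARecord(unique_name(m.reference_id), "known", seq, match=m)
            records.append(rec)
            by_seq[seq] = rec
            continue
        arm_hit = match_precursor_arm(seq, pre_index) if pre_index.entries else None
        if arm_hit is not None:
            pname, arm, mm, start = arm_hit
            base = pname[:-4] if pname.endswith("-pre") else pname
            rec = MiRNARecord(
                unique_name(f"{base}-{arm}"),
                "new_member",
                seq,
                match=KnownMatch(pname, mm, start, 0),
                arm=arm,
            )
            records.append(rec)
            by_seq[seq] = rec
            continue
        unmatched.append(seq)

    for rec in discover_candidates(unmatched, genome, chrom):
        rec.name = unique_name(rec.name)
        records.append(rec)
        by_seq[rec.mature_seq] = rec

    class_counts = {"known": 0, "new_member": 0, "candidate": 0}
    for rec in records:
        class_counts[rec.class_label] += 1

    lengths = sorted({len(r.mature_seq) for r in records}) or [0]
    length_summary = pd.DataFrame(
        0, index=["known", "new_member", "candidate"], columns=lengths
    )
    for rec in records:
        length_summary.loc[rec.class_label, len(rec.mature_seq)] += 1

    detected: Dict[str, set] = {}
    for seq, rec in by_seq.items():
        tag = valid[seq]
        for lib, count in tag.counts.items():
            if count > 0:
                detected.setdefault(lib.split("_")[0], set()).add(rec.name)
    genos = sorted(detected)
    venn = {g: len(detected[g]) for g in genos}
    if len(genos) == 2:
        shared = detected[genos[0]] & detected[genos[1]]
        venn["shared"] = len(shared)
        venn["total"] = len(detected[genos[0]] | detected[genos[1]])
    return ClassificationResult(records, by_seq, class_counts, length_summary, venn, detected)
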