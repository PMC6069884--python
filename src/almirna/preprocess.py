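"""Raw-read preprocessing: adapter trimming, filtering, annotation subtraction.

Turns raw small-RNA reads into annotated unique tags and per-library
accounting.  Every read lands in exactly one bin, in a fixed precedence
order: adapter failure, length failure, junk/low-complexity, Rfam-style
ncRNA, mRNA, repeat, and finally valid.  Valid tags are 18-25 nt.

Reads may be supplied either as plain sequences or as (sequence, count)
pairs; identical reads are processed once and weighted by their count, so
deeply sequenced libraries cost no more than their unique-read diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import pandas as pd

from .io import normalize_seq, revcomp

__all__ = [
    "UniqueTag",
    "LibraryAccounting",
    "trim_adapter",
    "filter_length",
    "is_junk",
    "subtract_annotations",
    "collapse_unique",
    "preprocess_libraries",
    "length_distribution",
    "BINS",
]

BINS = ("adapter_fail", "length_fail", "junk", "rfam", "mrna", "repeat", "valid")

MIN_TAG_LEN = 18
MAX_TAG_LEN = 25


@dataclass
class UniqueTag:
    """A distinct trimmed read sequence with per-library counts and a bin."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)
    bin: str = "valid"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class LibraryAccounting:
    """Per-library read accounting mirroring a sequencing-profile table.

    ``table`` holds one row per bin (raw first) and a (library, total|unique)
    column pair per library; the removed bins plus valid partition raw.
    """

    ROWS = ("raw",) + ("adapter_length",) + BINS[2:]

    def __init__(self, libraries):
        self.libraries = list(libraries)
        cols = pd.MultiIndex.from_product([self.libraries, ["total", "unique"]])
        self.table = pd.DataFrame(0, index=list(self.ROWS), columns=cols)

    def add(self, row: str, library: str, total: int, unique: int = 0) -> None:
        self.table.loc[row, (library, "total")] += int(total)
        self.table.loc[row, (library, "unique")] += int(unique)

    def verify_partition(self) -> bool:
        """raw = adapter/length + junk + rfam + mrna + repeat + valid, per library."""
        t = self.table.xs("total", axis=1, level=1)
        removed = t.loc[["adapter_length", "junk", "rfam", "mrna", "repeat", "valid"]].sum()
        return bool((t.loc["raw"] == removed).all())


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Return the insert preceding the 3' adapter, or None on failure.

    The leftmost full adapter occurrence wins; otherwise the longest prefix
    of the adapter (>= ``min_overlap``) matching the read end is trimmed.
    """
    if not read:
        raise ValueError("empty read")
    if not (len(adapter) >= min_overlap >= 4):
        raise ValueError("require adapter length >= min_overlap >= 4")
    read = normalize_seq(read)
    adapter = normalize_seq(adapter)
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    for ov in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
        if read.endswith(adapter[:ov]):
            return read[:-ov]
    return None


def filter_length(seq: str, min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> bool:
    return min_len <= len(seq) <= max_len


def is_junk(seq: str, max_base_frac: float = 0.8, max_dinuc_frac: float = 0.8) -> bool:
    """Low-complexity test: N content, dominant base, or dinucleotide repeat.

    Junk if the sequence contains N, any single base makes up >=
    ``max_base_frac`` of the length, or a 2-periodic repeat covers >=
    ``max_dinuc_frac`` of the length.
    """
    seq = normalize_seq(seq)
    n = len(seq)
    if n == 0 or "N" in seq:
        return True
    if max(seq.count(c) for c in "ACGT") >= max_base_frac * n:
        return True
    # longest run where s[i] == s[i-2] (covers period-1 and period-2 repeats)
    best = run = 2 if n >= 2 else n
    for i in range(2, n):
        run = run + 1 if seq[i] == seq[i - 2] else 2
        best = max(best, run)
    return best >= max_dinuc_frac * n


class _ReferenceIndex:
    """Exact substring membership over reference sets, both strands."""

    def __init__(self, refs: Mapping[str, Iterable]):
        self._texts = {}
        for klass, entries in refs.items():
            parts = []
            for _, seq in entries:
                s = normalize_seq(seq)
                parts.append(s)
                parts.append(revcomp(s))
            self._texts[klass] = "\n".join(parts)

    def lookup(self, tag: str):
        for klass, text in self._texts.items():
            if tag in text:
                return klass
        return None


def subtract_annotations(tags, rfam_ref, mrna_ref, repeat_ref):
    """Bin tags by the first reference class containing them as a substring.

    Class precedence is rfam, mrna, repeat (a tag present in several keeps
    the first); matching is exact, on either strand.  Unmatched tags stay
    ``valid``.  References are (name, sequence) iterables.
    """
    index = _ReferenceIndex(
        {"rfam": list(rfam_ref), "mrna": list(mrna_ref), "repeat": list(repeat_ref)}
    )
    for tag in tags:
        hit = index.lookup(tag.sequence)
        if hit is not None:
            tag.bin = hit
    return tags


def collapse_unique(reads_per_library: Mapping[str, Iterable]):
    """Collapse reads into unique-sequence tags with per-library counts.

    ``reads_per_library`` maps library id to an iterable of sequences or
    (sequence, count) pairs.  No filtering is applied here.
    """
    tags: Dict[str, UniqueTag] = {}
    for lib, reads in reads_per_library.items():
        for item in reads:
            seq, count = item if isinstance(item, tuple) else (item, 1)
            seq = normalize_seq(seq)
            tag = tags.get(seq)
            if tag is None:
                tag = tags[seq] = UniqueTag(seq)
            tag.counts[lib] = tag.counts.get(lib, 0) + int(count)
    return tags


def preprocess_libraries(
    reads_per_library: Mapping[str, Iterable],
    adapter: str,
    rfam_ref=(),
    mrna_ref=(),
    repeat_ref=(),
    min_overlap: int = 6,
):
    """Full preprocessing chain; returns (tags, accounting).

    ``tags`` maps trimmed sequence -> UniqueTag for every non-adapter-fail
    bin (valid, contaminant and junk/length tags alike, each with its bin);
    ``accounting`` reconciles all raw reads per library.
    """
    libs = list(reads_per_library)
    acc = LibraryAccounting(libs)
    trimmed: Dict[str, Dict[str, int]] = {lib: {} for lib in libs}
    fail_unique = {lib: set() for lib in libs}
    for lib, reads in reads_per_library.items():
        raw_unique = set()
        for item in reads:
            seq, count = item if isinstance(item, tuple) else (item, 1)
            seq = normalize_seq(seq)
            raw_unique.add(seq)
            acc.add("raw", lib, count)
            insert = trim_adapter(seq, adapter, min_overlap=min_overlap)
            if insert is None:
                acc.add("adapter_length", lib, count)
                fail_unique[lib].add(("A", seq))
                continue
            if not filter_length(insert):
                acc.add("adapter_length", lib, count)
                fail_unique[lib].add(("L", insert))
                continue
            trimmed[lib][insert] = trimmed[lib].get(insert, 0) + count
        acc.table.loc["raw", (lib, "unique")] = len(raw_unique)
        acc.table.loc["adapter_length", (lib, "unique")] = len(fail_unique[lib])

    tags = collapse_unique({lib: list(d.items()) for lib, d in trimmed.items()})
    for tag in tags.values():
        if is_junk(tag.sequence):
            tag.bin = "junk"
    subtract_annotations(
        [t for t in tags.values() if t.bin == "valid"], rfam_ref, mrna_ref, repeat_ref
    )
    for tag in tags.values():
        row = tag.bin
        for lib, count in tag.counts.items():
            acc.add(row, lib, count, unique=1)
    return tags, acc


def length_distribution(tags, libraries=None) -> pd.DataFrame:
    """Per-length fractions of valid reads per library (columns sum to 1)."""
    valid = [t for t in tags.values() if t.bin == "valid"] if isinstance(tags, dict) else [
        t for t in tags if t.bin == "valid"
    ]
    libs = libraries or sorted({lib for t in valid for lib in t.counts})
    lengths = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    df = pd.DataFrame(0.0, index=list(lengths), columns=libs)
    for t in valid:
        for lib, c in t.counts.items():
            if lib in df.columns:
                df.loc[len(t.sequence), lib] += c
    totals = df.sum()
    return df.div(totals.where(totals > 0, 1.0), axis=1)
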