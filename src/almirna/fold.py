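"""RNA hairpin folding, energy metrics and pre-miRNA structure criteria.

The folding engine is a Nussinov-style minimum-energy dynamic program over
nested (pseudoknot-free) structures, extended with a nearest-neighbour
stacking bonus and a flat loop-initiation penalty.  The energy model is a
deliberately small, fully documented constant table (see ``PAIR_ENERGY``,
``STACK_WEIGHT``, ``LOOP_PENALTY``), not the Turner rules: every quantity it
produces can be checked against exhaustive enumeration of all nested
structures, which the test suite does for short sequences.

Energy of a structure S on sequence x::

    E(S) = sum_{(i,j) in S} e_pair(x_i, x_j)
         + sum_{(i,j),(i+1,j-1) in S} e_stack(type(i,j), type(i+1,j-1))
         + LOOP_PENALTY * #{(i,j) in S : (i+1,j-1) not in S}

i.e. every helix-closing pair that is not stacked directly on an inner pair
pays one loop-initiation penalty (hairpin, bulge, internal and multibranch
loops are penalised uniformly).  Only AU, GC and GU pairs are allowed and a
hairpin loop holds at least ``MIN_LOOP`` unpaired bases.  The table depends
only on the unordered pair types, so the model is strand-symmetric: the
reverse complement of a sequence folds to the same minimum energy.

Ties in energy are broken in favour of the structure with more base pairs
(encoded exactly in the integer DP objective); remaining ties fall to a
fixed deterministic traceback that pairs the leftmost position first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HairpinStructure",
    "FoldMetrics",
    "CriteriaReport",
    "fold",
    "fold_metrics",
    "check_criteria",
    "structure_energy",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "enclosing_stemloops",
    "write_dotbracket",
]

# ---------------------------------------------------------------------------
# Energy model (kcal/mol; internally centi-kcal integers)

MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop
LOOP_PENALTY = 3.0  # kcal/mol per non-stacked closing pair

#: pairing energies per pair type, kcal/mol
PAIR_ENERGY = {"GC": -2.0, "AU": -1.1, "GU": -0.5}

#: stacking bonus between adjacent pairs p,q: -0.3 * (w(p) + w(q)) kcal/mol
STACK_WEIGHT = {"GC": 2.0, "AU": 1.0, "GU": 0.5}
STACK_COEF = -0.3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_INF = np.int64(1) << 50

# pair-type table indexed by (code_i, code_j); None = cannot pair
_PTYPE = {}
for _a, _b, _t in [
    ("G", "C", "GC"), ("C", "G", "GC"),
    ("A", "T", "AU"), ("T", "A", "AU"),
    ("G", "T", "GU"), ("T", "G", "GU"),
]:
    _PTYPE[(_CODE[_a], _CODE[_b])] = _t


def _centi(x: float) -> int:
    return int(round(x * 100))


_PAIR_E = np.full((4, 4), _INF, dtype=np.int64)
for (_i, _j), _t in _PTYPE.items():
    _PAIR_E[_i, _j] = _centi(PAIR_ENERGY[_t])

_TYPES = ["GC", "AU", "GU"]
_TIDX = {t: k for k, t in enumerate(_TYPES)}
_STACK_E = np.zeros((3, 3), dtype=np.int64)
for _p in _TYPES:
    for _q in _TYPES:
        _STACK_E[_TIDX[_p], _TIDX[_q]] = _centi(
            STACK_COEF * (STACK_WEIGHT[_p] + STACK_WEIGHT[_q])
        )
_LOOP_E = _centi(LOOP_PENALTY)

# combined DP objective: value = energy_centi * SCALE - n_pairs  (minimised;
# SCALE exceeds any possible pair count so energy dominates, pair count
# breaks exact energy ties toward more pairs)
_SCALE = 1024


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def _pair_type(a: int, b: int) -> str | None:
    return _PTYPE.get((a, b))


# ---------------------------------------------------------------------------
# Data types


@dataclass(frozen=True)
class HairpinStructure:
    """A folded sequence: dot-bracket string, base pairs and its energy.

    ``pairs`` are 1-based (i, j) with i < j; the structure is nested and all
    pairs are AU/GC/GU with at least ``MIN_LOOP`` unpaired loop bases.
    """

    sequence: str
    dotbracket: str
    pairs: frozenset
    mfe: float

    def __post_init__(self):
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str, mfe: float) -> "HairpinStructure":
        return cls(sequence, dotbracket, frozenset(dotbracket_to_pairs(dotbracket)), mfe)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FoldMetrics:
    """MFE-derived metrics: AMFE (MFE per 100 nt) and the MFEI discriminator."""

    mfe: float
    amfe: float
    mfei: float
    gc_percent: float


@dataclass
class CriteriaReport:
    """Evaluation of the ten pre-miRNA hairpin criteria.

    ``structure_ok`` is False when the structure is not a single stem-loop
    (no pairs, or more than one terminal loop); all criteria then fail.
    """

    structure_ok: bool = False
    c1: bool = False  # max bulge in stem <= 12 nt
    c2: bool = False  # stem pairs >= 16
    c3: bool = False  # MFE <= -15 kcal/mol
    c4: bool = False  # 50 < hairpin length < 200
    c5: bool = False  # max bulge in mature region <= 4 nt
    c6: bool = False  # biased errors in one mature bulge <= 2
    c7: bool = False  # biased bulges in mature region <= 2
    c8: bool = False  # errors (unpaired) in mature region <= 4
    c9: bool = False  # base pairs in mature region >= 12
    c10: bool = False  # percent of mature in stem >= 80
    stem_bulge_max_nt: int = 0
    stem_pairs: int = 0
    hairpin_len: int = 0
    mature_bulge_max_nt: int = 0
    mature_biased_errors: int = 0
    mature_biased_bulges: int = 0
    mature_errors: int = 0
    mature_pairs: int = 0
    mature_in_stem_pct: float = 0.0

    @property
    def passed(self) -> bool:
        return self.structure_ok and all(
            getattr(self, f"c{k}") for k in range(1, 11)
        )

    def as_dict(self) -> dict:
        d = {f"c{k}": getattr(self, f"c{k}") for k in range(1, 11)}
        d.update(
            structure_ok=self.structure_ok,
            passed=self.passed,
            stem_bulge_max_nt=self.stem_bulge_max_nt,
            stem_pairs=self.stem_pairs,
            hairpin_len=self.hairpin_len,
            mature_bulge_max_nt=self.mature_bulge_max_nt,
            mature_biased_errors=self.mature_biased_errors,
            mature_biased_bulges=self.mature_biased_bulges,
            mature_errors=self.mature_errors,
            mature_pairs=self.mature_pairs,
            mature_in_stem_pct=self.mature_in_stem_pct,
        )
        return d


# ---------------------------------------------------------------------------
# Structure utilities


def dotbracket_to_pairs(db: str) -> set:
    stack = []
    pairs = set()
    for k, c in enumerate(db, start=1):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.add((stack.pop(), k))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def pairs_to_dotbracket(pairs: Iterable, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return "".join(db)


def structure_energy(seq: str, pairs: Iterable) -> float:
    """Energy of an explicit structure under the documented model (kcal/mol)."""
    codes = _encode(seq)
    pset = {(int(i), int(j)) for i, j in pairs}
    e = 0
    for i, j in pset:
        t = _pair_type(codes[i - 1], codes[j - 1])
        if t is None:
            raise ValueError(f"positions {i},{j} cannot pair")
        e += _centi(PAIR_ENERGY[t])
        if (i + 1, j - 1) in pset:
            t2 = _pair_type(codes[i], codes[j - 2])
            e += int(_STACK_E[_TIDX[t], _TIDX[t2]])
        else:
            e += _LOOP_E
    return e / 100.0


# ---------------------------------------------------------------------------
# Minimum-energy folding


def fold(seq: str) -> HairpinStructure:
    """Fold a sequence into its minimum-energy nested structure.

    Accepts 1-300 nt over {A,C,G,T,U}; returns the optimal structure under
    the module's energy model with ties broken toward more base pairs.
    """
    n = len(seq)
    if not 1 <= n <= 300:
        raise ValueError(f"sequence length {n} outside [1, 300]")
    codes = _encode(seq)
    V, W, Wns = _fill(codes)
    pairs = _traceback(codes, V, W, Wns)
    mfe = structure_energy(seq, pairs) if pairs else 0.0
    db = pairs_to_dotbracket(pairs, n)
    return HairpinStructure(seq.upper().replace("U", "T"), db, frozenset(pairs), mfe)


def _fill(codes: np.ndarray):
    n = len(codes)
    V = np.full((n, n), _INF, dtype=np.int64)
    W = np.zeros((n, n), dtype=np.int64)
    Wns = np.zeros((n, n), dtype=np.int64)
    pe = _PAIR_E
    se = _STACK_E
    loop = _LOOP_E * _SCALE
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # V[i, j]: i pairs j
            if span > MIN_LOOP:
                t = _PTYPE.get((codes[i], codes[j]))
                if t is not None:
                    best = loop + Wns[i + 1, j - 1]
                    if V[i + 1, j - 1] < _INF:
                        t2 = _PTYPE[(codes[i + 1], codes[j - 1])]
                        cand = int(se[_TIDX[t], _TIDX[t2]]) * _SCALE + V[i + 1, j - 1]
                        if cand < best:
                            best = cand
                    V[i, j] = int(pe[codes[i], codes[j]]) * _SCALE - 1 + best
            # Wns[i, j]: best with i NOT paired to j
            best = W[i + 1, j]
            if span > MIN_LOOP + 1:
                ks = V[i, i + MIN_LOOP + 1 : j] + W[i + MIN_LOOP + 2 : j + 1, j]
                m = ks.min()
                if m < best:
                    best = m
            Wns[i, j] = best
            W[i, j] = min(best, V[i, j])
    return V, W, Wns


def _traceback(codes: np.ndarray, V, W, Wns) -> set:
    n = len(codes)
    pairs = set()
    stack = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if j - i < MIN_LOOP + 1 and kind != "V":
            continue
        if kind in ("W", "Wns"):
            target = W[i, j] if kind == "W" else Wns[i, j]
            # prefer pairing i (leftmost '(') with the largest partner first
            hi = j if kind == "W" else j - 1
            found = False
            for k in range(hi, i + MIN_LOOP, -1):
                if V[i, k] >= _INF:
                    continue
                rest = W[k + 1, j] if k < j else 0
                if V[i, k] + rest == target:
                    stack.append(("V", i, k))
                    if k + 1 <= j:
                        stack.append(("W", k + 1, j))
                    found = True
                    break
            if not found:
                # i unpaired
                stack.append(("W", i + 1, j))
        else:  # V
            pairs.add((i + 1, j + 1))
            t = _PTYPE[(codes[i], codes[j])]
            base = int(_PAIR_E[codes[i], codes[j]]) * _SCALE - 1
            ii, jj = i + 1, j - 1
            if V[ii, jj] < _INF:
                t2 = _PTYPE[(codes[ii], codes[jj])]
                if base + int(_STACK_E[_TIDX[t], _TIDX[t2]]) * _SCALE + V[ii, jj] == V[i, j]:
                    stack.append(("V", ii, jj))
                    continue
            if jj - ii >= MIN_LOOP + 1:
                stack.append(("Wns", ii, jj))
            # else: hairpin loop, nothing inside
    return pairs


# ---------------------------------------------------------------------------
# Metrics


def fold_metrics(structure: HairpinStructure, seq: str | None = None) -> FoldMetrics:
    """AMFE = mfe / length * 100; MFEI = |AMFE| / GC%."""
    seq = (seq or structure.sequence).upper().replace("U", "T")
    n = len(seq)
    gc = 100.0 * sum(1 for c in seq if c in "GC") / n
    if gc == 0:
        raise ValueError("MFEI undefined for sequence with 0% GC")
    amfe = structure.mfe / n * 100.0
    mfei = abs(amfe) / gc
    return FoldMetrics(mfe=structure.mfe, amfe=amfe, mfei=mfei, gc_percent=gc)


# ---------------------------------------------------------------------------
# Hairpin criteria


def _chain(pairs: Sequence) -> list:
    return sorted(pairs)


def _terminal_loops(pairs: Iterable) -> int:
    ps = set(pairs)
    n_term = 0
    for (i, j) in ps:
        if not any(i < x < y < j for (x, y) in ps):
            n_term += 1
    return n_term


def check_criteria(structure: HairpinStructure, mature_span: tuple) -> CriteriaReport:
    """Evaluate the ten hairpin criteria for a mature span on a precursor.

    ``mature_span`` is 1-based inclusive on the structure's sequence.  The
    structure must be a single stem-loop (exactly one terminal loop); other
    topologies fail with ``structure_ok=False``.

    Conventions (the source analysis tool leaves these undefined):
    stem = all paired positions outside the terminal loop; a bulge is a
    maximal unpaired run between consecutive stem pairs on one strand; an
    error in the mature region is an unpaired mature position; a bulge/loop
    is *biased* when its two strand-side runs differ in length, and its
    biased-error count is that length difference.
    """
    a, b = int(mature_span[0]), int(mature_span[1])
    n = structure.length
    if not (1 <= a <= b <= n):
        raise ValueError(f"mature span ({a}, {b}) outside sequence of length {n}")
    rep = CriteriaReport(hairpin_len=n)
    pairs = _chain(structure.pairs)
    if not pairs or _terminal_loops(pairs) != 1:
        return rep
    # single terminal loop => pairs form a strictly nested chain
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            return rep
    rep.structure_ok = True

    outer_i, outer_j = pairs[0]
    inner_i, inner_j = pairs[-1]
    loop_positions = set(range(inner_i + 1, inner_j))
    stem_span = set(range(outer_i, outer_j + 1)) - loop_positions
    paired_pos = {i for i, _ in pairs} | {j for _, j in pairs}
    mature = set(range(a, b + 1))

    # stem bulges: unpaired runs between consecutive chain pairs
    bulge_runs = []  # (side_run_positions, opposite_run_positions)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        left = list(range(i1 + 1, i2))
        right = list(range(j2 + 1, j1))
        if left or right:
            bulge_runs.append((left, right))
    rep.stem_bulge_max_nt = max(
        (max(len(l), len(r)) for l, r in bulge_runs), default=0
    )
    rep.stem_pairs = len(pairs)

    rep.mature_errors = len(mature - paired_pos)
    rep.mature_pairs = len(mature & paired_pos)
    rep.mature_in_stem_pct = 100.0 * len(mature & stem_span) / len(mature)

    mature_bulge_max = 0
    biased_err_max = 0
    biased_bulges = 0
    for left, right in bulge_runs:
        in_l = len(mature.intersection(left))
        in_r = len(mature.intersection(right))
        if in_l == 0 and in_r == 0:
            continue
        mature_bulge_max = max(mature_bulge_max, in_l + in_r)
        diff = abs(len(left) - len(right))
        if diff > 0:
            biased_bulges += 1
            biased_err_max = max(biased_err_max, diff)
    rep.mature_bulge_max_nt = mature_bulge_max
    rep.mature_biased_errors = biased_err_max
    rep.mature_biased_bulges = biased_bulges

    rep.c1 = rep.stem_bulge_max_nt <= 12
    rep.c2 = rep.stem_pairs >= 16
    rep.c3 = structure.mfe <= -15.0
    rep.c4 = 50 < n < 200
    rep.c5 = rep.mature_bulge_max_nt <= 4
    rep.c6 = rep.mature_biased_errors <= 2
    rep.c7 = rep.mature_biased_bulges <= 2
    rep.c8 = rep.mature_errors <= 4
    rep.c9 = rep.mature_pairs >= 12
    rep.c10 = rep.mature_in_stem_pct >= 80.0
    return rep


# ---------------------------------------------------------------------------
# Hairpin excision from a larger folded window


def enclosing_stemloops(structure: HairpinStructure, span: tuple):
    """Yield excised single-stem-loop substructures enclosing ``span``.

    For each base pair (i, j) that encloses the 1-based inclusive ``span``
    and whose nested subtree contains exactly one terminal loop, yields
    ``(substructure, shifted_span)`` where the substructure covers sequence
    positions i..j and carries the energy of its own pair set.  Outermost
    levels are yielded first.
    """
    a, b = int(span[0]), int(span[1])
    pairs = sorted(structure.pairs)
    enclosing = [(i, j) for (i, j) in pairs if i <= a and b <= j]
    for (i, j) in sorted(enclosing):
        sub = {(x, y) for (x, y) in pairs if i <= x < y <= j}
        if _terminal_loops(sub) != 1:
            continue
        shifted = {(x - i + 1, y - i + 1) for (x, y) in sub}
        subseq = structure.sequence[i - 1 : j]
        mfe = structure_energy(subseq, shifted)
        yield (
            HairpinStructure(
                subseq,
                pairs_to_dotbracket(shifted, len(subseq)),
                frozenset(shifted),
                mfe,
            ),
            (a - i + 1, b - i + 1),
        )


# ---------------------------------------------------------------------------
# Vienna-style output


def write_dotbracket(path, entries) -> None:
    """Write (name, HairpinStructure) entries as Vienna dot-bracket records."""
    with open(path, "w") as fh:
        for name, st in entries:
            fh.write(f">{name}\n")
            fh.write(st.sequence.replace("T", "U") + "\n")
            fh.write(f"{st.dotbracket} ({st.mfe:.2f})\n")
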