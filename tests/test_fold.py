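"""Folding engine: exhaustive-enumeration oracle, metrics and criteria."""

import random

import pytest

from almirna.fold import (
    HairpinStructure,
    check_criteria,
    dotbracket_to_pairs,
    enclosing_stemloops,
    fold,
    fold_metrics,
    pairs_to_dotbracket,
    structure_energy,
)
from almirna.io import revcomp

# --------------------------------------------------------------------------
# Independent oracle: brute-force enumeration over all nested structures,
# scored from the documented constant table (restated here on purpose).

ORACLE_PAIR_E = {"GC": -2.0, "AU": -1.1, "GU": -0.5}
ORACLE_STACK_W = {"GC": 2.0, "AU": 1.0, "GU": 0.5}
ORACLE_STACK_COEF = -0.3
ORACLE_LOOP = 3.0
PT = {}
for a, b, t in [
    ("G", "C", "GC"), ("C", "G", "GC"),
    ("A", "T", "AU"), ("T", "A", "AU"),
    ("G", "T", "GU"), ("T", "G", "GU"),
]:
    PT[(a, b)] = t


def brute_force_min_energy(seq: str) -> float:
    """Minimum energy over every nested structure (min loop 3), by explicit
    enumeration with incremental scoring."""
    s = seq.upper().replace("U", "T")

    def gen(i, j):
        # yields (energy, closing_type); closing_type set iff (i, j) paired
        if j - i < 4:
            yield (0.0, None)
            return
        for e, _ in gen(i + 1, j):
            yield (e, None)
        for k in range(i + 4, j + 1):
            t = PT.get((s[i], s[k]))
            if t is None:
                continue
            pe = ORACLE_PAIR_E[t]
            for ein, ct in gen(i + 1, k - 1):
                close = (
                    ORACLE_STACK_COEF * (ORACLE_STACK_W[t] + ORACLE_STACK_W[ct])
                    if ct
                    else ORACLE_LOOP
                )
                left = pe + close + ein
                if k == j:
                    yield (left, t)
                else:
                    for er, _ in gen(k + 1, j):
                        yield (left + er, None)

    return round(min(e for e, _ in gen(0, len(s) - 1)), 6)


def brute_force_best_pairs(seq: str) -> int:
    """Maximum pair count among minimum-energy structures, by enumeration."""
    s = seq.upper().replace("U", "T")
    n = len(s)
    best = (float("inf"), 0)

    def gen(i, j):
        if j - i < 4:
            yield []
            return
        yield from gen(i + 1, j)
        for k in range(i + 4, j + 1):
            if (s[i], s[k]) in PT:
                for inner in gen(i + 1, k - 1):
                    for rest in gen(k + 1, j):
                        yield [(i + 1, k + 1)] + inner + rest

    for pairs in gen(0, n - 1):
        e = round(structure_energy(s, pairs), 6) if pairs else 0.0
        cand = (e, -len(pairs))
        if cand < best:
            best = cand
    return -best[1]


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# --------------------------------------------------------------------------
# fold()


def test_homopolymer_folds_to_no_pairs():
    st = fold("A" * 20)
    assert st.mfe == 0.0
    assert st.dotbracket == "." * 20
    assert not st.pairs


def test_minimal_hairpin_exact_structure():
    st = fold("GGGAAACCC")
    assert st.dotbracket == "(((...)))"
    assert len(st.pairs) == 3
    # 3 GC pairs, 2 GC/GC stacks, 1 loop penalty
    assert st.mfe == pytest.approx(3 * -2.0 + 2 * -1.2 + 3.0)


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError):
        fold("GGGAXACCC" + "A" * 15)


@pytest.mark.parametrize("trial", range(60))
def test_fold_energy_matches_brute_force(trial):
    rng = random.Random(1000 + trial)
    seq = random_seq(rng, rng.randint(8, 24))
    st = fold(seq)
    assert st.mfe == pytest.approx(brute_force_min_energy(seq))
    # the returned structure's own energy is the reported mfe
    assert structure_energy(seq, st.pairs) == pytest.approx(st.mfe)


@pytest.mark.parametrize("trial", range(10))
def test_fold_ties_prefer_more_pairs(trial):
    rng = random.Random(2000 + trial)
    seq = random_seq(rng, rng.randint(10, 18))
    st = fold(seq)
    assert len(st.pairs) == brute_force_best_pairs(seq)


@pytest.mark.parametrize("trial", range(15))
def test_reversal_energy_symmetry(trial):
    # the energy table depends only on unordered pair types, so reversing
    # the sequence maps every structure onto one of identical energy
    # (reverse *complementation* does not: a G:U pair maps to invalid A:C)
    rng = random.Random(3000 + trial)
    seq = random_seq(rng, rng.randint(20, 60))
    assert fold(seq).mfe == pytest.approx(fold(seq[::-1]).mfe)


def test_fold_is_deterministic():
    seq = random_seq(random.Random(5), 80)
    a, b = fold(seq), fold(seq)
    assert a.dotbracket == b.dotbracket and a.mfe == b.mfe


def test_dotbracket_roundtrip():
    db = "..((((...))))...((...)).."
    assert pairs_to_dotbracket(dotbracket_to_pairs(db), len(db)) == db


# --------------------------------------------------------------------------
# fold_metrics


def _structure_with(length, gc_count, mfe):
    seq = "G" * (gc_count // 2) + "C" * (gc_count - gc_count // 2) + "A" * (length - gc_count)
    return HairpinStructure(seq, "." * length, frozenset(), mfe)


def test_metrics_closed_form():
    m = fold_metrics(_structure_with(100, 40, -30.0))
    assert m.amfe == pytest.approx(-30.0)
    assert m.mfei == pytest.approx(0.75)


def test_metrics_zero_mfe():
    assert fold_metrics(_structure_with(100, 40, 0.0)).mfei == 0.0


def test_metrics_boundary_085():
    # length 120, mfe -51, GC 50% -> mfei exactly 0.85 (not > 0.85)
    m = fold_metrics(_structure_with(120, 60, -51.0))
    assert m.mfei == pytest.approx(0.85)
    assert not m.mfei > 0.85 + 1e-12


def test_metrics_gc_zero_errors():
    with pytest.raises(ValueError):
        fold_metrics(_structure_with(50, 0, -10.0))


@pytest.mark.parametrize("trial", range(20))
def test_metrics_identity_randomized(trial):
    rng = random.Random(4000 + trial)
    length = rng.randint(60, 200)
    gc = rng.randint(1, length)
    mfe = -rng.uniform(0, 80)
    m = fold_metrics(_structure_with(length, gc, mfe))
    assert m.mfei == pytest.approx(abs(mfe) * 100 / (length * m.gc_percent))


# --------------------------------------------------------------------------
# criteria


def _hairpin(n_pairs, loop=3, tail=0, mfe=-20.0, lead=0):
    """lead dots + n_pairs '(' + loop dots + n_pairs ')' + tail dots."""
    db = "." * lead + "(" * n_pairs + "." * loop + ")" * n_pairs + "." * tail
    seq = "A" * len(db)
    return HairpinStructure(seq, db, frozenset(dotbracket_to_pairs(db)), mfe)


def test_perfect_hairpin_passes_all_criteria():
    # 60-nt stem-loop: 28 pairs, 4-nt loop, mature fully paired in the stem
    st = _hairpin(28, loop=4)
    rep = check_criteria(st, (4, 24))
    assert rep.passed and all(getattr(rep, f"c{k}") for k in range(1, 11))
    assert rep.stem_pairs == 28
    assert rep.mature_errors == 0
    assert rep.mature_pairs == 21
    assert rep.mature_in_stem_pct == 100.0


@pytest.mark.parametrize(
    "build,span,flipped",
    [
        # stem pairs 15 vs 16 (16 passes; 15 flips only c2)
        (lambda: _hairpin(15, loop=3, tail=18), (2, 13), "c2"),
        # mfe -14.9 vs -15.0
        (lambda: _hairpin(24, loop=3, mfe=-14.9), (2, 13), "c3"),
        # hairpin length exactly 50 ('larger than 50' is strict)
        (lambda: _hairpin(23, loop=4, tail=0), (2, 13), "c4"),
        # hairpin length exactly 200 ('less than 200' is strict)
        (lambda: _hairpin(40, loop=4, tail=116), (2, 13), "c4"),
        # mature 19 nt with 4 in the terminal loop: 15/19 = 79% in stem
        (lambda: _hairpin(24, loop=8), (10, 28), "c10"),
    ],
)
def test_criterion_boundaries_flip_exactly_one(build, span, flipped):
    rep = build()
    report = check_criteria(rep, span)
    failing = [f"c{k}" for k in range(1, 11) if not getattr(report, f"c{k}")]
    assert failing == [flipped]


def test_boundary_passing_variants():
    assert check_criteria(_hairpin(16, loop=3, tail=16), (2, 13)).passed
    assert check_criteria(_hairpin(24, loop=3, mfe=-15.0), (2, 13)).passed
    assert check_criteria(_hairpin(24, loop=4, tail=0), (2, 13)).passed  # len 52
    assert check_criteria(_hairpin(40, loop=4, tail=115), (2, 13)).passed  # len 199
    # mature 20 nt with 4 in the loop: exactly 80% in stem, 4 errors
    rep = check_criteria(_hairpin(24, loop=8), (9, 28))
    assert rep.passed and rep.mature_in_stem_pct == pytest.approx(80.0)
    assert rep.mature_errors == 4


def test_multiloop_structure_fails():
    db = "..((..((...))..((...))..)).."
    st = HairpinStructure("A" * len(db), db, frozenset(dotbracket_to_pairs(db)), -30.0)
    rep = check_criteria(st, (3, 10))
    assert not rep.structure_ok and not rep.passed


def test_mature_span_validation():
    with pytest.raises(ValueError):
        check_criteria(_hairpin(20), (0, 10))
    with pytest.raises(ValueError):
        check_criteria(_hairpin(20), (5, 1000))


def test_stem_bulge_counters():
    # 12-nt bulge on the 5' side between two helices: c1 still true at 12
    db = "(" * 10 + "." * 12 + "(" * 10 + "..." + ")" * 20
    st = HairpinStructure("A" * len(db), db, frozenset(dotbracket_to_pairs(db)), -30.0)
    rep = check_criteria(st, (23, 42))
    assert rep.stem_bulge_max_nt == 12 and rep.c1
    db = "(" * 10 + "." * 13 + "(" * 10 + "..." + ")" * 20
    st = HairpinStructure("A" * len(db), db, frozenset(dotbracket_to_pairs(db)), -30.0)
    assert not check_criteria(st, (24, 43)).c1


def test_mature_bulge_and_bias_counters():
    # asymmetric internal loop (3 vs 1) inside the mature region
    db = "(" * 8 + "..." + "(" * 10 + "..." + ")" * 10 + "." + ")" * 8
    st = HairpinStructure("A" * len(db), db, frozenset(dotbracket_to_pairs(db)), -30.0)
    rep = check_criteria(st, (5, 24))  # covers the 3-nt bulge
    assert rep.mature_bulge_max_nt == 3
    assert rep.mature_biased_bulges == 1
    assert rep.mature_biased_errors == 2  # |3 - 1|


def test_mutating_paired_mature_base_never_reduces_errors():
    rng = random.Random(11)
    arm = "GCAGCUGACGGUACCAGGCAU".replace("U", "T")
    pre = "ACGGA" + arm + "CAACAACA" + revcomp(arm) + "TCCGT"
    span = (6, 5 + len(arm))
    base_rep = check_criteria(fold(pre), span)
    assert base_rep.passed
    for _ in range(5):
        pos = rng.randrange(span[0] - 1, span[1])
        mutated = pre[:pos] + "A" + pre[pos + 1 :]
        rep = check_criteria(fold(mutated), span)
        if rep.structure_ok:
            assert rep.mature_errors >= base_rep.mature_errors
            if not base_rep.c8:
                assert not rep.c8


def test_enclosing_stemloop_excision():
    rng = random.Random(3)
    arm = random_seq(rng, 30)
    hair = arm + "CAACAACA" + revcomp(arm)
    window = random_seq(rng, 60) + hair + random_seq(rng, 60)
    st = fold(window)
    span = (61, 60 + len(arm))
    subs = list(enclosing_stemloops(st, span))
    assert subs, "no enclosing stem-loop found around the planted hairpin"
    passed = [r for sub, sp in subs for r in [check_criteria(sub, sp)] if r.passed]
    assert passed, "planted hairpin not recovered from the embedding window"
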