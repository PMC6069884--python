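"""Plant-style miRNA target prediction by complementarity penalty scoring.

A miRNA is aligned antiparallel against transcript windows; each position
contributes a penalty: 0 for a Watson-Crick pair, 0.5 for a G:U wobble,
1.0 for a mismatch and 1.0 per bulged nucleotide, with all penalties
doubled in the seed-proximal region (miRNA positions 2-13 from the 5'
end).  At most one single-nucleotide bulge (on either strand) is allowed.
Sites scoring at or below the cutoff (default 4.0) are reported with the
predicted cleavage position: the transcript base paired to miRNA
position 10.

The whole-transcriptome scan is vectorised over window starts with numpy
prefix sums; `score_duplex` evaluates a single duplex explicitly and is
used for reporting and cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import normalize_seq

__all__ = [
    "DuplexAlignment",
    "TargetInteraction",
    "score_duplex",
    "scan_transcriptome",
    "MISMATCH_PENALTY",
    "GU_PENALTY",
    "BULGE_PENALTY",
    "SEED_RANGE",
    "MAX_SCORE",
]

MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
BULGE_PENALTY = 1.0
SEED_RANGE = (2, 13)  # miRNA positions with doubled penalties, inclusive
SEED_FACTOR = 2.0
MAX_SCORE = 4.0
CLEAVAGE_MIRNA_POS = 10

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def _pair_penalty(mir_base: str, target_base: str) -> float:
    a, b = _CODE[mir_base], _CODE[target_base]
    if _COMP[a] == b:
        return 0.0
    if {mir_base, target_base} == {"G", "T"}:
        return GU_PENALTY
    return MISMATCH_PENALTY


def _seeded(pos: int, penalty: float) -> float:
    lo, hi = SEED_RANGE
    return penalty * SEED_FACTOR if lo <= pos <= hi else penalty


@dataclass
class DuplexAlignment:
    """An aligned miRNA:target-site duplex with per-position states."""

    mirna_seq: str
    site_seq: str
    states: List[str]  # per miRNA 5'->3' position (+bulge entries)
    score: float
    bulge: Optional[Tuple[str, int]] = None  # ('target'|'mirna', miRNA-side position)
    site_start: int = 0  # 1-based inclusive on transcript, when known
    site_end: int = 0
    cleavage_site: int = 0


@dataclass
class TargetInteraction:
    mirna: str
    transcript: str
    site_start: int
    site_end: int
    score: float
    cleavage_site: int
    alignment: DuplexAlignment
    degradome_category: Optional[int] = None
    degradome_detected: Optional[str] = None


def _score_ungapped(mir: str, site: str) -> Tuple[float, List[str]]:
    L = len(mir)
    states = []
    total = 0.0
    for k in range(1, L + 1):
        t = site[L - k]
        p = _pair_penalty(mir[k - 1], t)
        total += _seeded(k, p)
        states.append("match" if p == 0 else ("GU" if p == GU_PENALTY else "mismatch"))
    return total, states


def score_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score one duplex; site is the target window 5'->3' on the transcript.

    Site length must be len(mirna)-1, len(mirna) or len(mirna)+1 (one
    bulged nucleotide on the miRNA or the target at most); the minimum
    penalty over all bulge placements is returned.
    """
    mir = normalize_seq(mirna)
    site = normalize_seq(site)
    if not (15 <= len(mir) <= 30 and 15 <= len(site) <= 30):
        raise ValueError("miRNA and site must be 15-30 nt")
    L = len(mir)
    diff = len(site) - L
    best: Optional[DuplexAlignment] = None

    def consider(score, states, bulge):
        nonlocal best
        if best is None or score < best.score:
            best = DuplexAlignment(mir, site, states, score, bulge)

    if diff == 0:
        score, states = _score_ungapped(mir, site)
        consider(score, states, None)
    elif diff == 1:
        # one unpaired target base between miRNA positions p and p+1
        for p in range(1, L):
            total = 0.0
            states = []
            for k in range(1, L + 1):
                idx = (L + 1 - k) if k <= p else (L - k)
                pen = _pair_penalty(mir[k - 1], site[idx])
                total += _seeded(k, pen)
                states.append("match" if pen == 0 else ("GU" if pen == GU_PENALTY else "mismatch"))
                if k == p:
                    states.append("bulge_target")
            total += _seeded(min(p + 1, L), BULGE_PENALTY)
            consider(total, states, ("target", p))
    elif diff == -1:
        # miRNA position p unpaired
        for p in range(1, L + 1):
            total = _seeded(p, BULGE_PENALTY)
            states = []
            for k in range(1, L + 1):
                if k == p:
                    states.append("bulge_mirna")
                    continue
                idx = (L - 1 - k) if k < p else (L - k)
                pen = _pair_penalty(mir[k - 1], site[idx])
                total += _seeded(k, pen)
                states.append("match" if pen == 0 else ("GU" if pen == GU_PENALTY else "mismatch"))
            consider(total, states, ("mirna", p))
    else:
        raise ValueError("site length must be within one nucleotide of the miRNA length")
    return best


def _penalty_rows(mir: str) -> np.ndarray:
    """P[k-1, base] = seed-weighted penalty of miRNA position k vs target base."""
    L = len(mir)
    P = np.zeros((L, 4))
    for k in range(1, L + 1):
        for base, b in _CODE.items():
            P[k - 1, b] = _seeded(k, _pair_penalty(mir[k - 1], base))
    return P


def _site_positions(L: int, diff: int, p: Optional[int]) -> List[Optional[int]]:
    """0-based site index paired with each miRNA position (None = bulged)."""
    if diff == 0:
        return [L - k for k in range(1, L + 1)]
    if diff == 1:
        return [(L + 1 - k) if k <= p else (L - k) for k in range(1, L + 1)]
    out = []
    for k in range(1, L + 1):
        out.append(None if k == p else ((L - 1 - k) if k < p else (L - k)))
    return out


def scan_transcriptome(
    mirna: str,
    transcripts: List[Tuple[str, str]],
    max_score: float = MAX_SCORE,
    mirna_name: str = "mirna",
) -> List[TargetInteraction]:
    """All windows scoring <= max_score, deduplicated to the best site per
    (miRNA, transcript); ties resolved to the leftmost site."""
    mir = normalize_seq(mirna)
    L = len(mir)
    P = _penalty_rows(mir)
    hits = []
    for tid, tseq in transcripts:
        tseq = normalize_seq(tseq)
        if len(tseq) < L + 1:
            continue
        t = np.array([_CODE.get(c, 0) for c in tseq], dtype=np.int64)
        n = len(t)
        best_score, best_start, best_diff, best_p = np.inf, -1, 0, None

        # ungapped windows, window length L: score(a) = sum_k P[k-1, t[a+L-k]]
        n_win = n - L + 1
        scores = np.zeros(n_win)
        for k in range(1, L + 1):
            scores += P[k - 1, t[L - k : L - k + n_win]]
        a0 = int(np.argmin(scores))
        if scores[a0] < best_score:
            best_score, best_start, best_diff, best_p = float(scores[a0]), a0, 0, None

        # one bulged target base (window length L+1)
        n_win = n - L
        if n_win > 0:
            U = np.stack([P[k - 1, t[L + 1 - k : L + 1 - k + n_win]] for k in range(1, L + 1)])
            V = np.stack([P[k - 1, t[L - k : L - k + n_win]] for k in range(1, L + 1)])
            cu = np.cumsum(U, axis=0)  # cu[p-1] = sum_{k<=p}
            cv_total = V.sum(axis=0)
            cv = np.cumsum(V, axis=0)
            for p in range(1, L):
                s = cu[p - 1] + (cv_total - cv[p - 1]) + _seeded(min(p + 1, L), BULGE_PENALTY)
                a0 = int(np.argmin(s))
                if s[a0] < best_score:
                    best_score, best_start, best_diff, best_p = float(s[a0]), a0, 1, p

        # one bulged miRNA base (window length L-1)
        n_win = n - L + 2
        if n_win > 0 and L - 1 >= 1:

            def _row(k: int, start: int) -> np.ndarray:
                # pad rows whose slice runs off the transcript end; such rows
                # are never selected by the cumsum bounds below
                sl = P[k - 1, t[start : start + n_win]]
                if len(sl) < n_win:
                    sl = np.concatenate([sl, np.zeros(n_win - len(sl))])
                return sl

            X = np.stack([_row(k, L - 1 - k) if L - 1 - k >= 0 else np.zeros(n_win)
                          for k in range(1, L + 1)])
            Y = np.stack([_row(k, L - k) for k in range(1, L + 1)])
            cx = np.cumsum(X, axis=0)
            cy = np.cumsum(Y, axis=0)
            cy_total = Y.sum(axis=0)
            for p in range(1, L + 1):
                left = cx[p - 2] if p >= 2 else 0.0
                right = cy_total - cy[p - 1]
                s = left + right + _seeded(p, BULGE_PENALTY)
                a0 = int(np.argmin(s))
                if s[a0] < best_score:
                    best_score, best_start, best_diff, best_p = float(s[a0]), a0, -1, p

        if best_score > max_score:
            continue
        site_len = L + best_diff
        a = best_start
        site = tseq[a : a + site_len]
        aln = score_duplex(mir, site)
        positions = _site_positions(L, best_diff, best_p)
        cleav_idx = positions[CLEAVAGE_MIRNA_POS - 1]
        if cleav_idx is None:
            cleav_idx = positions[CLEAVAGE_MIRNA_POS]
        aln.site_start, aln.site_end = a + 1, a + site_len
        aln.cleavage_site = a + 1 + cleav_idx
        hits.append(
            TargetInteraction(
                mirna=mirna_name,
                transcript=tid,
                site_start=a + 1,
                site_end=a + site_len,
                score=round(float(aln.score), 4),
                cleavage_site=aln.cleavage_site,
                alignment=aln,
            )
        )
    return hits


def interactions_table(interactions: List[TargetInteraction]) -> pd.DataFrame:
    rows = []
    for it in interactions:
        rows.append(
            {
                "mirna": it.mirna,
                "transcript": it.transcript,
                "site_start": it.site_start,
                "site_end": it.site_end,
                "score": it.score,
                "cleavage_site": it.cleavage_site,
                "degradome_category": it.degradome_category,
                "degradome_detected": it.degradome_detected,
            }
        )
    return pd.DataFrame(rows)
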