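"""Global pairwise alignment of amplicon reads against a reference window.

Every read in the fidelity pipeline maps to one known reference interval, so a
deterministic end-to-end (global) pairwise aligner is sufficient — no multiple
alignment is needed.  The aligner is Needleman-Wunsch with affine gap
penalties (Gotoh's three-state recurrence).  Default scores: match +1,
mismatch -2, gap open -4 (cost of the first gapped base), gap extend -1 (each
additional base).

Determinism rules, chosen so that consensus calls from different reads of the
same molecule land on identical coordinates:

* on score ties the traceback prefers a (mis)match column over a gap, then a
  gap in the query (deletion) over a gap in the reference (insertion), and
  prefers extending an open gap over opening a new one;
* after traceback every indel is left-normalized (shifted to the upstream-most
  equivalent position, as in VCF normalization), so indels inside repeats have
  canonical coordinates.

``read_diffs`` adds a fast path: for equal-length pairs with at most two
mismatches the diagonal alignment is provably optimal under the default
scores (regaining two mismatches is worth at most 6 while the cheapest gap
pair costs 8), so the full dynamic program is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_VALID = frozenset("ACGTN")
_NEG = -1e18

#: Substitution, insertion and deletion labels used throughout the package.
SUB, INS, DEL = "sub", "ins", "del"


@dataclass(frozen=True)
class AlignScores:
    """Scoring scheme for global alignment.

    ``gap_open`` is the score of the first base of a gap; ``gap_extend`` is
    the score of each subsequent base, i.e. a gap of length ``k`` scores
    ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


DEFAULT_SCORES = AlignScores()


@dataclass(frozen=True, order=True)
class Diff:
    """One difference of a query sequence relative to the reference.

    ``pos`` is the 0-based reference coordinate: the substituted or deleted
    reference base, or — for insertions — the reference position *before*
    which the bases are inserted.
    """

    pos: int
    kind: str  # SUB | INS | DEL
    ref: str
    alt: str


@dataclass
class Alignment:
    """A global alignment: score, gapped strings and the derived diff list."""

    score: float
    aligned_query: str
    aligned_ref: str
    diffs: tuple[Diff, ...]

    @property
    def n_mismatches(self) -> int:
        return sum(1 for d in self.diffs if d.kind == SUB)

    @property
    def n_indels(self) -> int:
        return sum(1 for d in self.diffs if d.kind != SUB)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"{name} contains non-ACGTN characters: {sorted(bad)!r}"
        )


def _fill_matrices(query: str, ref: str, s: AlignScores):
    """Fill the three Gotoh state matrices.

    M[i, j]: best score with query[i-1] aligned to ref[j-1].
    I[i, j]: best score ending in a gap in the reference (query base inserted).
    D[i, j]: best score ending in a gap in the query (reference base deleted).

    Rows are filled with vectorized numpy ops; the within-row recursion of D
    is resolved with a running-maximum (cummax) trick.
    """
    n, m = len(query), len(ref)
    go, ge = s.gap_open, s.gap_extend
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    # N never matches anything (including itself).
    sub = np.where(
        (q[:, None] == r[None, :]) & (q[:, None] != ord("N")),
        s.match,
        s.mismatch,
    )

    M = np.full((n + 1, m + 1), _NEG)
    I = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    D[0, 1:] = go + (j - 1) * ge
    i = np.arange(1, n + 1)
    I[1:, 0] = go + (i - 1) * ge

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], I[i - 1]), D[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        I[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], D[i - 1, 1:]) + go, I[i - 1, 1:] + ge
        )
        # D[i, j] = max_{k <= j-1} ( max(M, I)[i, k] + go + (j - 1 - k) * ge )
        mi = np.maximum(M[i], I[i])
        g = mi + go - ge * np.arange(m + 1)
        D[i, 1:] = ge * np.arange(1, m + 1) - ge + np.maximum.accumulate(g)[:-1]
    return M, I, D, sub


def _traceback(query: str, ref: str, s: AlignScores, M, I, D, sub):
    """Recover one optimal path with the documented tie-break priorities."""
    go, ge = s.gap_open, s.gap_extend
    i, j = len(query), len(ref)
    # Priority at the terminus and inside M: match > deletion > insertion.
    finals = (("M", M[i, j]), ("D", D[i, j]), ("I", I[i, j]))
    best = max(v for _, v in finals)
    state = next(name for name, v in finals if v >= best - 1e-9)
    cols: list[tuple[str, str]] = []
    while i > 0 or j > 0:
        if state == "M":
            cols.append((query[i - 1], ref[j - 1]))
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("D", D[i, j]), ("I", I[i, j])):
                if abs(val - target) <= 1e-9:
                    state = cand
                    break
        elif state == "D":
            cols.append(("-", ref[j - 1]))
            val = D[i, j]
            j -= 1
            if j >= 0 and abs(D[i, j] + ge - val) <= 1e-9:
                state = "D"  # prefer extending the gap
            elif abs(M[i, j] + go - val) <= 1e-9:
                state = "M"
            else:
                state = "I"
        else:  # state == "I"
            cols.append((query[i - 1], "-"))
            val = I[i, j]
            i -= 1
            if i >= 0 and abs(I[i, j] + ge - val) <= 1e-9:
                state = "I"
            elif abs(M[i, j] + go - val) <= 1e-9:
                state = "M"
            else:
                state = "D"
        if i == 0 and j > 0:
            state = "D"
        elif j == 0 and i > 0:
            state = "I"
    cols.reverse()
    aq = "".join(c[0] for c in cols)
    ar = "".join(c[1] for c in cols)
    return aq, ar


def _diffs_from_gapped(aligned_query: str, aligned_ref: str, ref: str):
    """Convert gapped strings to a left-normalized diff list."""
    diffs: list[Diff] = []
    rpos = 0
    k = 0
    L = len(aligned_query)
    while k < L:
        qc, rc = aligned_query[k], aligned_ref[k]
        if qc == "-":  # deletion run
            start = rpos
            bases = []
            while k < L and aligned_query[k] == "-":
                bases.append(aligned_ref[k])
                rpos += 1
                k += 1
            p, run = _left_shift_del(ref, start, "".join(bases))
            diffs.append(Diff(p, DEL, run, ""))
        elif rc == "-":  # insertion run
            bases = []
            while k < L and aligned_ref[k] == "-":
                bases.append(aligned_query[k])
                k += 1
            p, run = _left_shift_ins(ref, rpos, "".join(bases))
            diffs.append(Diff(p, INS, "", run))
        else:
            if qc != rc:
                diffs.append(Diff(rpos, SUB, rc, qc))
            rpos += 1
            k += 1
    return tuple(sorted(diffs))


def _left_shift_del(ref: str, pos: int, bases: str) -> tuple[int, str]:
    L = len(bases)
    while pos > 0 and ref[pos - 1] == ref[pos + L - 1]:
        pos -= 1
    return pos, ref[pos : pos + L]


def _left_shift_ins(ref: str, pos: int, bases: str) -> tuple[int, str]:
    while pos > 0 and ref[pos - 1] == bases[-1]:
        bases = ref[pos - 1] + bases[:-1]
        pos -= 1
    return pos, bases


def global_align(query: str, ref: str, scores: AlignScores = DEFAULT_SCORES) -> Alignment:
    """Optimal global alignment of ``query`` against ``ref``.

    Raises ``ValueError`` on empty sequences or non-ACGTN characters.
    """
    _check_sequence(query, "query")
    _check_sequence(ref, "reference")
    M, I, D, sub = _fill_matrices(query, ref, scores)
    score = float(max(M[-1, -1], I[-1, -1], D[-1, -1]))
    aq, ar = _traceback(query, ref, scores, M, I, D, sub)
    return Alignment(score, aq, ar, _diffs_from_gapped(aq, ar, ref))


def _hamming_diffs(query: str, ref: str) -> tuple[Diff, ...]:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    pos = np.nonzero(q != r)[0]
    return tuple(Diff(int(p), SUB, ref[p], query[p]) for p in pos)


def read_diffs(query: str, ref: str, scores: AlignScores = DEFAULT_SCORES) -> tuple[Diff, ...]:
    """Differences of ``query`` vs ``ref``, with a safe diagonal fast path.

    Equal-length pairs with <= 2 mismatches take the diagonal alignment
    directly (optimal under the default scores, see module docstring); all
    other pairs go through the full dynamic program.
    """
    if query == ref:
        return ()
    # Fast path is only sound when regaining two mismatches cannot pay for
    # the cheapest gap pair.
    safe = 2.0 * (scores.match - scores.mismatch) < -2.0 * scores.gap_open
    if safe and len(query) == len(ref):
        d = _hamming_diffs(query, ref)
        if len(d) <= 2 and not any(x.alt == "N" or x.ref == "N" for x in d):
            return d
    return global_align(query, ref, scores).diffs


def hamming_mismatches(query: str, ref: str) -> int:
    """Count of positionally mismatched bases between equal-length strings."""
    if len(query) != len(ref):
        raise ValueError("hamming_mismatches requires equal lengths")
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    return int(np.count_nonzero(q != r))
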