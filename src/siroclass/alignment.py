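"""Pairwise and multiple protein alignment with affine gap costs.

This module is the package's deliberately simple stand-in for a production
aligner: a three-state (Gotoh) global dynamic program with an optional
free-end-gap mode for fitting a short reference into a longer query, a
center-star multiple alignment built on it, and a gap-fraction column
trimmer. It makes no attempt to reproduce MUSCLE or Gblocks output; it is
meant to be exactly reproducible and easy to reason about, which is what
anchor-column mapping and the synthetic-data tests require.

Gap cost convention: a gap run of length L costs ``gap_open +
(L-1) * gap_extend`` (i.e. ``gap_open`` is the full cost of a length-1
gap). This matches the common BLOSUM62 pairing of open=-11 / extend=-1.

Traceback tie-break, in decreasing preference: substitution (both residues
consumed), gap in the query (reference residue consumed), gap in the
reference (query residue consumed). The optimum score is unique; only the
reported alignment path depends on this order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError
from .seq_io import ALPHABET, ProteinRecord

_NEG = -1.0e30
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """Symmetric substitution table over the 21-letter alphabet + gap costs."""

    matrix: np.ndarray  # (21, 21) float
    gap_open: float
    gap_extend: float
    name: str = "custom"

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise AlignmentError("substitution table must be 21x21 (amino acids + X)")
        if not np.allclose(m, m.T):
            raise AlignmentError("substitution table must be symmetric")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise AlignmentError("require gap_open <= gap_extend <= 0")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_INDEX[a], _INDEX[b]])

    @classmethod
    def blosum62(cls, gap_open: float = -11.0, gap_extend: float = -1.0) -> "ScoringScheme":
        """Packaged default: the BLOSUM62 log-odds matrix."""
        blosum = substitution_matrices.load("BLOSUM62")
        m = np.zeros((len(ALPHABET), len(ALPHABET)))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                m[i, j] = blosum[a][b]
        return cls(m, gap_open, gap_extend, name="BLOSUM62")

    @classmethod
    def identity(
        cls,
        match: float = 1.0,
        mismatch: float = 0.0,
        gap_open: float = -2.0,
        gap_extend: float = -1.0,
    ) -> "ScoringScheme":
        """Simple match/mismatch table, mainly for tests and oracles."""
        n = len(ALPHABET)
        m = np.full((n, n), mismatch, dtype=float)
        np.fill_diagonal(m, match)
        return cls(m, gap_open, gap_extend, name="identity")


@dataclasses.dataclass(frozen=True)
class PairAlignment:
    """A scored global alignment of a reference and a query.

    ``ref_to_query[p]`` (key ``p`` is 1-based into the reference) gives the
    1-based query position aligned to reference position ``p``, or ``None``
    when that reference residue sits opposite a gap. The map is strictly
    increasing over its non-None entries, and removing ``-`` from either
    aligned string recovers the original sequence.
    """

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    ref_to_query: tuple  # tuple of (int | None), index 0 <-> ref position 1

    def query_position(self, ref_position: int):
        return self.ref_to_query[ref_position - 1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:  # pragma: no cover - records are pre-validated
        raise AlignmentError(f"invalid residue {exc.args[0]!r}") from exc


def _dp(a: str, b: str, scheme: ScoringScheme, free_end_gaps: bool):
    """Fill the three Gotoh matrices. Rows index the reference ``a``."""
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    ai, bi = _encode(a), _encode(b)
    sub = scheme.matrix

    M = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)  # gap in query (consumes ref)
    I = np.full((n + 1, m + 1), _NEG)  # gap in ref (consumes query)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1, dtype=float)
    I[0, 1:] = 0.0 if free_end_gaps else go + (j - 1.0) * ge

    jcol = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        D[i, 0] = 0.0 if free_end_gaps else go + (i - 1.0) * ge
        srow = sub[ai[i - 1], bi]
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], D[i - 1, :-1]), I[i - 1, :-1])
        M[i, 1:] = srow + prev_best
        D[i, 1:] = np.maximum(
            D[i - 1, 1:] + ge, np.maximum(M[i - 1, 1:], I[i - 1, 1:]) + go
        )
        # I has an intra-row dependency; closed form via a running prefix max:
        # I[i,j] = go + (j-1)*ge + max_{k<j} (G[k] - k*ge), G = max(M, D).
        G = np.maximum(M[i, :], D[i, :])
        run = np.maximum.accumulate(G[:-1] - jcol[:-1] * ge)
        I[i, 1:] = go + (jcol[1:] - 1.0) * ge + run
    return M, D, I


def _traceback(a, b, scheme, M, D, I, end_i, end_j, end_state):
    go, ge = scheme.gap_open, scheme.gap_extend
    tol = 1e-9
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = end_i, end_j, end_state
    while i > 0 or j > 0:
        if i == 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - scheme.score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("D", D[i, j]), ("I", I[i, j])):
                if abs(val - target) <= tol:
                    state = cand
                    break
            else:  # pragma: no cover - defensive
                raise AlignmentError("traceback failed in state M")
        elif state == "D":
            out_a.append(a[i - 1])
            out_b.append("-")
            target = D[i, j]
            i -= 1
            for cand, val in (("M", M[i, j] + go), ("D", D[i, j] + ge), ("I", I[i, j] + go)):
                if abs(val - target) <= tol:
                    state = cand
                    break
            else:  # pragma: no cover - defensive
                raise AlignmentError("traceback failed in state D")
        else:  # state == "I"
            out_a.append("-")
            out_b.append(b[j - 1])
            target = I[i, j]
            j -= 1
            for cand, val in (("M", M[i, j] + go), ("D", D[i, j] + go), ("I", I[i, j] + ge)):
                if abs(val - target) <= tol:
                    state = cand
                    break
            else:  # pragma: no cover - defensive
                raise AlignmentError("traceback failed in state I")
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def global_align(
    ref: ProteinRecord | str,
    query: ProteinRecord | str,
    scheme: ScoringScheme,
    free_end_gaps: bool = False,
) -> PairAlignment:
    """Optimal global alignment of ``ref`` and ``query`` under affine gaps.

    With ``free_end_gaps=True`` terminal gap runs in either sequence cost
    nothing (semiglobal mode), which is how a short domain reference is
    fitted inside a longer multi-domain query.
    """
    ref_id, a = (ref.id, ref.sequence) if isinstance(ref, ProteinRecord) else ("ref", ref)
    query_id, b = (
        (query.id, query.sequence) if isinstance(query, ProteinRecord) else ("query", query)
    )
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    M, D, I = _dp(a, b, scheme, free_end_gaps)
    n, m = len(a), len(b)

    if not free_end_gaps:
        end_i, end_j = n, m
        end_state, score = max(
            (("M", M[n, m]), ("D", D[n, m]), ("I", I[n, m])), key=lambda t: t[1]
        )
        ar, aq = _traceback(a, b, scheme, M, D, I, end_i, end_j, end_state)
    else:
        # Best cell on the last row or last column; trailing gaps are free.
        best = (_NEG, -1, -1, "M")
        candidates = [(n, jj) for jj in range(m, -1, -1)] + [
            (ii, m) for ii in range(n, -1, -1)
        ]
        for ii, jj in candidates:
            for st, val in (("M", M[ii, jj]), ("D", D[ii, jj]), ("I", I[ii, jj])):
                if val > best[0] + 1e-12:
                    best = (val, ii, jj, st)
        score, end_i, end_j, end_state = best
        ar, aq = _traceback(a, b, scheme, M, D, I, end_i, end_j, end_state)
        ar = ar + a[end_i:] + "-" * (m - end_j)
        aq = aq + "-" * (n - end_i) + b[end_j:]

    mapping: list[int | None] = []
    qpos = 0
    for ca, cb in zip(ar, aq):
        if cb != "-":
            qpos += 1
        if ca != "-":
            mapping.append(qpos if cb != "-" else None)
    assert len(mapping) == n
    return PairAlignment(ref_id, query_id, ar, aq, float(score), tuple(mapping))


@dataclasses.dataclass(frozen=True)
class MultiAlignment:
    """Equal-length aligned rows in input order; degapping recovers inputs."""

    ids: tuple
    rows: tuple  # aligned strings

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(self.rows) and len(lens) != 1:
            raise AlignmentError("all MSA rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, index: int) -> str:
        return self.rows[index].replace("-", "")

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_rows, self.n_cols
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as out:
            for rid, row in zip(self.ids, self.rows):
                out.write(f">{rid}\n{row}\n")


def center_star_msa(
    records: Sequence[ProteinRecord], scheme: ScoringScheme
) -> MultiAlignment:
    """Star multiple alignment around the best-scoring center sequence.

    The center is the record maximizing the summed pairwise global-alignment
    score against all others (ties broken by smallest id). Each pairwise
    center/other alignment is merged with the usual once-a-gap-always-a-gap
    rule, so every pairwise gap pattern is preserved in the final rows.
    """
    records = list(records)
    if len(records) < 2:
        raise AlignmentError("center-star MSA needs at least 2 records")
    k = len(records)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = global_align(records[i], records[j], scheme).score
            scores[i, j] = scores[j, i] = s
    sums = scores.sum(axis=1)
    order = sorted(range(k), key=lambda i: (-sums[i], records[i].id))
    c = order[0]
    center = records[c]
    n = len(center.sequence)

    # gaps[p] = number of gap columns inserted after center position p (p=0..n)
    pairs = []
    gaps = np.zeros(n + 1, dtype=int)
    for idx, rec in enumerate(records):
        if idx == c:
            pairs.append(None)
            continue
        aln = global_align(center, rec, scheme)
        ins = np.zeros(n + 1, dtype=int)
        blocks: list[list[str]] = [[] for _ in range(n + 1)]
        aligned_chars: list[str] = []
        p = 0
        for ca, cq in zip(aln.aligned_ref, aln.aligned_query):
            if ca == "-":
                ins[p] += 1
                blocks[p].append(cq)
            else:
                p += 1
                aligned_chars.append(cq)
        pairs.append((idx, ins, blocks, aligned_chars))
        gaps = np.maximum(gaps, ins)

    def build_row(ins, blocks, aligned_chars):
        parts = []
        for p in range(n + 1):
            parts.append("".join(blocks[p]) + "-" * (gaps[p] - ins[p]))
            if p < n:
                parts.append(aligned_chars[p])
        return "".join(parts)

    rows: list[str | None] = [None] * k
    center_blocks = [[] for _ in range(n + 1)]
    rows[c] = build_row(np.zeros(n + 1, dtype=int), center_blocks, list(center.sequence))
    for entry in pairs:
        if entry is None:
            continue
        idx, ins, blocks, aligned_chars = entry
        rows[idx] = build_row(ins, blocks, aligned_chars)
    return MultiAlignment(tuple(r.id for r in records), tuple(rows))


def trim_columns(
    msa: MultiAlignment, max_gap_fraction: float
) -> tuple[MultiAlignment, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the kept columns as 1-based indices
    into the input (new->old coordinate map). Idempotent at a fixed
    threshold; may legitimately return zero columns.
    """
    if msa.n_rows == 0:
        return msa, []
    arr = msa.to_array()
    gap_frac = (arr == b"-").mean(axis=0)
    kept = [int(i) for i in np.flatnonzero(gap_frac <= max_gap_fraction)]
    sub = arr[:, kept]
    rows = tuple(sub[i].tobytes().decode() for i in range(msa.n_rows))
    return MultiAlignment(msa.ids, rows), [i + 1 for i in kept]


def sp_score(msa: MultiAlignment, scheme: ScoringScheme) -> float:
    """Sum-of-pairs score of an MSA under the scheme's affine gap costs.

    Each induced pairwise alignment is scored after removing dual-gap
    columns, with gap runs costing ``gap_open + (L-1)*gap_extend``.
    """
    total = 0.0
    k = msa.n_rows
    for i in range(k):
        for j in range(i + 1, k):
            a, b = msa.rows[i], msa.rows[j]
            in_gap_a = in_gap_b = False
            for ca, cb in zip(a, b):
                if ca == "-" and cb == "-":
                    continue
                if ca == "-":
                    total += scheme.gap_extend if in_gap_a else scheme.gap_open
                    in_gap_a, in_gap_b = True, False
                elif cb == "-":
                    total += scheme.gap_extend if in_gap_b else scheme.gap_open
                    in_gap_b, in_gap_a = True, False
                else:
                    total += scheme.score(ca, cb)
                    in_gap_a = in_gap_b = False
    return total
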