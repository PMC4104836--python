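"""Pairwise local alignment with affine gaps and Karlin-Altschul E-values.

This is the stand-in for an all-against-all blastp run: Smith-Waterman
under BLOSUM62 with 11/1 gap penalties, E-values from the standard
Karlin-Altschul form E = K * m * n * exp(-lambda * S) with the published
gapped constants for this scoring scheme, and a 12-column blast-tabular
writer. Identity is matches over all alignment columns, gap columns
included.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _align
from .io import AMINO_ACIDS, SequenceRecord


def _blosum62_scores() -> np.ndarray:
    """BLOSUM62 as a 21x21 integer array in residue-code order; X scores 0."""
    mat = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((_align.N_CODES, _align.N_CODES))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sub[i, j] = mat[a][b]
    # code 20 (X wildcard) scores 0 against everything
    return sub


BLOSUM62 = _blosum62_scores()


@dataclass
class AlignmentParams:
    """Scoring scheme for pairwise local alignment.

    Defaults match blastp's: BLOSUM62, gap open 11 / extend 1 (a gap of
    length L costs 11 + L), and the published gapped Karlin-Altschul
    constants for that scheme (lambda = 0.267, K = 0.041).
    """

    matrix: np.ndarray = field(default_factory=lambda: BLOSUM62.copy())
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.ka_lambda <= 0 or self.ka_K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass
class PairHit:
    """One local alignment between two sequences.

    Coordinates are 1-based inclusive; a raw_score of 0 denotes an empty
    alignment (all coordinates 0, identity 0).
    """

    id_a: str
    id_b: str
    raw_score: int
    evalue: float
    identity: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int = 0
    columns: int = 0


def evalue(raw_score: float, m: int, n: int, params: AlignmentParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.ka_K * m * n * math.exp(-params.ka_lambda * raw_score)


def _query_rows(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(matrix[codes])


def align_local(a: SequenceRecord, b: SequenceRecord,
                params: AlignmentParams | None = None) -> PairHit:
    """Optimal Smith-Waterman local alignment of two records.

    Traceback is deterministic (ties: diagonal > up > left). Raises on
    residues absent from the scoring matrix (validation happens at
    encoding).
    """
    params = params or AlignmentParams()
    ca = _align.encode(a.residues)
    cb = _align.encode(b.residues)
    qrows = _query_rows(ca, params.matrix)
    score, a1, a2, b1, b2, matches, cols = _align.sw_align(
        qrows, ca, cb, float(params.gap_open), float(params.gap_extend))
    raw = int(round(score))
    ident = matches / cols if cols else 0.0
    return PairHit(
        id_a=a.id, id_b=b.id, raw_score=raw,
        evalue=evalue(raw, len(a), len(b), params),
        identity=ident, a_start=a1, a_end=a2, b_start=b1, b_end=b2,
        matches=matches, columns=cols,
    )


def all_vs_all(records: Sequence[SequenceRecord],
               params: AlignmentParams | None = None,
               evalue_cutoff: float = 1e-2,
               include_self: bool = False) -> list[PairHit]:
    """All unordered pairs with E <= cutoff.

    Scores every pair with the score-only kernel and runs the full
    traceback only for pairs that pass the cutoff, so the hit carries
    identity and coordinates. Self-pairs are emitted only when
    ``include_self`` is set.
    """
    params = params or AlignmentParams()
    if len(records) < 2 and not include_self:
        raise ValueError("all_vs_all needs at least 2 records")
    codes = [_align.encode(r.residues) for r in records]
    qrows = [_query_rows(c, params.matrix) for c in codes]
    go, ge = float(params.gap_open), float(params.gap_extend)
    hits: list[PairHit] = []
    n_rec = len(records)
    for i in range(n_rec):
        start_j = i if include_self else i + 1
        for j in range(start_j, n_rec):
            if i == j:
                if not include_self:
                    continue
                score = _align.sw_score(qrows[i], codes[i], go, ge)
            else:
                score = _align.sw_score(qrows[i], codes[j], go, ge)
            e = evalue(round(score), len(records[i]), len(records[j]), params)
            if e <= evalue_cutoff:
                hits.append(align_local(records[i], records[j], params))
    return hits


def write_hits_m8(hits: Iterable[PairHit], path: str | Path,
                  params: AlignmentParams | None = None) -> Path:
    """Write hits in 12-column blast-tabular (-m8-like) format.

    Columns: qid, sid, pident, length, mismatches, gapopens, qstart,
    qend, sstart, send, evalue, bitscore. Bit score uses the module's
    Karlin-Altschul constants: S' = (lambda*S - ln K) / ln 2. Gap opens
    are not tracked per-hit and are reported as the number of gap
    columns.
    """
    params = params or AlignmentParams()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            aspan = h.a_end - h.a_start + 1
            bspan = h.b_end - h.b_start + 1
            gaps = 2 * h.columns - aspan - bspan if h.columns else 0
            mismatches = h.columns - h.matches - gaps if h.columns else 0
            bits = (params.ka_lambda * h.raw_score - math.log(params.ka_K)) / math.log(2)
            writer.writerow([
                h.id_a, h.id_b, f"{100.0 * h.identity:.2f}", h.columns,
                mismatches, gaps, h.a_start, h.a_end, h.b_start, h.b_end,
                f"{h.evalue:.3g}", f"{bits:.1f}",
            ])
    return path
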