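"""Position-specific profile search with extreme-value E-value calibration.

A profile is built from a seed alignment: columns with at least 50%
residue occupancy become match columns carrying per-residue log-odds
scores (bits). Sequences are scored against the profile with the same
affine-gap local dynamic program used for pairwise alignment; the null
score distribution is calibrated empirically by scoring i.i.d.
background-random sequences and fitting a Gumbel law by maximum
likelihood, so that a bit score S converts to

    E = db_size * (1 - exp(-exp(-lambda * (S - mu))))

The hit's envelope is the target span of the optimal local alignment;
its start is what the downstream domain partition uses as the barrel's
N-terminal border.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _align
from .io import AMINO_ACIDS, BACKGROUND_FREQUENCIES, SequenceRecord


def default_background() -> np.ndarray:
    """Robinson-Robinson background frequencies, normalized."""
    bg = np.array([BACKGROUND_FREQUENCIES[a] for a in AMINO_ACIDS])
    return bg / bg.sum()


@dataclass
class GumbelParams:
    """Fitted null-score distribution: P(S >= s) = 1 - exp(-exp(-lambda*(s-mu)))."""

    lam: float
    mu: float
    n_calibration: int
    calibration_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel lambda must be positive")


@dataclass
class ProfileModel:
    """Log-odds profile over match columns, with affine gap scores in bits."""

    name: str
    match_scores: np.ndarray          # (n_columns, 21); X column = 0
    gap_open: float = -4.0            # bits, negative
    gap_extend: float = -0.5
    background: np.ndarray | None = None
    calibration: GumbelParams | None = None

    def __post_init__(self) -> None:
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != _align.N_CODES:
            raise ValueError("match_scores must have shape (n_columns, 21)")
        if not np.all(np.isfinite(self.match_scores)):
            raise ValueError("profile scores must be finite")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap scores must be negative")
        if self.background is None:
            self.background = default_background()
        if abs(float(np.sum(self.background)) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.match_scores.shape[0]


@dataclass
class Hit:
    """A profile match on one target sequence (1-based inclusive envelope)."""

    query_profile: str
    target_id: str
    score: float
    evalue: float
    env_start: int
    env_end: int
    #: profile columns covered by the alignment (1-based inclusive);
    #: 0 when unknown (e.g. hits re-read from TSV)
    profile_start: int = 0
    profile_end: int = 0


def build_profile(seed_rows: Sequence[tuple[str, str]], name: str = "profile",
                  pseudocount_weight: float = 1.0,
                  background: np.ndarray | None = None,
                  gap_open: float = -4.0, gap_extend: float = -0.5) -> ProfileModel:
    """Build a log-odds profile from an aligned seed.

    ``seed_rows`` are (id, padded row) pairs of equal length. Columns
    with >= 50% residue occupancy become match columns; emissions are
    log2(((count_a + w*p_a) / (total + w)) / p_a) with pseudocount
    weight w. ``X`` residues in the seed are ignored for counting.
    """
    if not seed_rows:
        raise ValueError("empty seed alignment")
    width = len(seed_rows[0][1])
    if any(len(row) != width for _, row in seed_rows):
        raise ValueError("seed rows must have equal padded length")
    if background is None:
        background = default_background()
    n_seq = len(seed_rows)
    columns: list[np.ndarray] = []
    for col in range(width):
        letters = [row[col] for _, row in seed_rows]
        occupied = [ch for ch in letters if ch != "-"]
        if len(occupied) / n_seq < 0.5:
            continue
        counts = np.zeros(20)
        for ch in occupied:
            if ch == "X":
                continue
            counts[AMINO_ACIDS.index(ch)] += 1.0
        total = counts.sum()
        freq = (counts + pseudocount_weight * background) / (total + pseudocount_weight)
        scores = np.zeros(_align.N_CODES)
        scores[:20] = np.log2(freq / background)
        columns.append(scores)
    if not columns:
        raise ValueError("seed alignment yields zero match columns")
    return ProfileModel(name=name, match_scores=np.array(columns),
                        gap_open=gap_open, gap_extend=gap_extend,
                        background=np.asarray(background, dtype=float))


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (lambda, mu)."""
    scores = np.asarray(scores, dtype=float)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate score sample: all values equal")
    mu, scale = stats.gumbel_r.fit(scores)
    return 1.0 / scale, mu


def calibrate(profile: ProfileModel, n_random: int = 500, length: int = 350,
              seed: int = 0) -> GumbelParams:
    """Fit the profile's null score distribution on random sequences.

    Scores ``n_random`` i.i.d. sequences drawn from the profile's
    background composition and fits a Gumbel by maximum likelihood.
    The fitted parameters are stored on the profile and returned.
    """
    if n_random < 200:
        raise ValueError("calibration needs at least 200 random sequences")
    rng = np.random.default_rng(seed)
    go, ge = -profile.gap_open, -profile.gap_extend
    qrows = np.ascontiguousarray(profile.match_scores)
    scores = np.empty(n_random)
    for k in range(n_random):
        cb = rng.choice(20, size=length, p=profile.background).astype(np.uint8)
        scores[k] = _align.sw_score(qrows, cb, go, ge)
    lam, mu = fit_gumbel(scores)
    params = GumbelParams(lam=lam, mu=mu, n_calibration=n_random,
                          calibration_length=length, seed=seed)
    profile.calibration = params
    return params


def score_to_evalue(score: float, calibration: GumbelParams, db_size: int) -> float:
    """E = db_size * P(null score >= score) under the fitted Gumbel."""
    x = -calibration.lam * (score - calibration.mu)
    # P(S >= s) = 1 - exp(-exp(x)); -expm1 is stable for small exp(x)
    if x > 40:  # deep left tail: probability is 1
        p = 1.0
    else:
        p = -math.expm1(-math.exp(x))
    return db_size * p


def search(profile: ProfileModel, records: Sequence[SequenceRecord],
           inclusion_evalue: float = 10.0, db_size: int | None = None) -> list[Hit]:
    """Score every record against the profile; keep hits with E <= threshold.

    Requires a calibrated profile. One hit per target (the optimal local
    alignment); hits sorted by E-value, ties by target id.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    if db_size is None:
        db_size = len(records)
    qrows = np.ascontiguousarray(profile.match_scores)
    dummy_ca = np.full(profile.n_columns, 255, dtype=np.uint8)
    go, ge = -profile.gap_open, -profile.gap_extend
    hits: list[Hit] = []
    for rec in records:
        cb = _align.encode(rec.residues)
        score, q1, q2, b1, b2, _, _ = _align.sw_align(qrows, dummy_ca, cb,
                                                      go, ge)
        if score <= 0.0:
            continue
        e = score_to_evalue(score, profile.calibration, db_size)
        if e <= inclusion_evalue:
            hits.append(Hit(query_profile=profile.name, target_id=rec.id,
                            score=float(score), evalue=e,
                            env_start=b1, env_end=b2,
                            profile_start=q1, profile_end=q2))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def merge_hits(hits_a: Iterable[Hit], hits_b: Iterable[Hit]) -> dict[str, Hit]:
    """Union of two hit lists; per target keep the higher-scoring hit.

    Ties go to the lower E-value, then to the lexicographically smaller
    profile name.
    """
    merged: dict[str, Hit] = {}
    for hit in list(hits_a) + list(hits_b):
        other = merged.get(hit.target_id)
        if other is None:
            merged[hit.target_id] = hit
            continue
        key_new = (-hit.score, hit.evalue, hit.query_profile)
        key_old = (-other.score, other.evalue, other.query_profile)
        if key_new < key_old:
            merged[hit.target_id] = hit
    return merged


def write_hits(hits: Iterable[Hit], path: str | Path) -> Path:
    """Write hits as TSV: query, target, score_bits, evalue, env_start, env_end."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["query", "target", "score_bits", "evalue",
                         "env_start", "env_end"])
        for h in hits:
            writer.writerow([h.query_profile, h.target_id, f"{h.score:.2f}",
                             f"{h.evalue:.3g}", h.env_start, h.env_end])
    return path
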