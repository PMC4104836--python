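"""Domain partitioning: barrel/N-terminus split, POTRA carving, lipobox calls.

The barrel's N-terminal border is the envelope start of the best profile
hit; the barrel runs from there to the end of the protein. Whatever
precedes it is the N-terminal region, kept only when at least 20 aa
remain. POTRA repeats are carved from the N-terminal region by iterated
profile scanning (find best hit, mask, repeat) with a 25-125 aa length
band, and per cluster only one POTRA set is defined: sequences with more
segments than the cluster's modal count are trimmed to their best ones.
Lipoprotein signals are called with an explicit rule: a lipobox motif
[LVI][ASTVIG][GAS]C whose cysteine falls in a configured N-terminal
window, preceded by a hydrophobic stretch.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io import SequenceRecord
from .profiles import Hit, ProfileModel, search

# Kyte-Doolittle hydropathy
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

LIPOBOX_RE = re.compile(r"[LVI][ASTVIG][GAS]C")


@dataclass
class DomainPartition:
    """Barrel/N-terminus split of one sequence (1-based inclusive)."""

    id: str
    barrel: tuple[int, int]
    nterm: tuple[int, int] | None
    source_profile: str


@dataclass
class PotraSegment:
    """One POTRA repeat, numbered P1..Pk from the N-terminus."""

    id: str
    index: int
    start: int
    end: int
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LipoboxCall:
    id: str
    positive: bool
    cys_position: int | None = None


def split_domains(record: SequenceRecord, best_hit: Hit,
                  min_nterm: int = 20) -> DomainPartition:
    """Partition a sequence at the best hit's envelope start.

    barrel = [env_start, len]; nterm = [1, env_start - 1] when at least
    ``min_nterm`` residues remain, else absent (the sequence then skips
    N-terminus analyses but stays in barrel analyses).
    """
    n = len(record)
    if best_hit.env_start > n:
        raise ValueError(
            f"hit envelope start {best_hit.env_start} beyond sequence "
            f"length {n} for {record.id!r}")
    barrel = (best_hit.env_start, n)
    nterm_len = best_hit.env_start - 1
    nterm = (1, nterm_len) if nterm_len >= min_nterm else None
    return DomainPartition(id=record.id, barrel=barrel, nterm=nterm,
                           source_profile=best_hit.query_profile)


def scan_potras(nterm_record: SequenceRecord, potra_profile: ProfileModel,
                min_len: int = 25, max_len: int = 125,
                evalue_threshold: float = 0.1,
                max_segments: int = 50) -> list[PotraSegment]:
    """Iterated profile scan of an N-terminal region for POTRA repeats.

    Finds the best hit, masks it with X, and repeats until no hit
    reaches ``evalue_threshold`` (single-sequence E-values). The
    recorded envelope is the alignment span projected out to the full
    profile length (profile columns the alignment did not reach are
    assumed to sit just outside it), clipped to the sequence and to
    previously assigned segments — local alignment trims diverged repeat
    ends, and the raw span would systematically undershoot the repeat.
    Segments outside [min_len, max_len] are discarded; survivors are
    numbered P1..Pk from the N-terminus.
    """
    if potra_profile.calibration is None:
        raise ValueError("POTRA profile must be calibrated")
    n = len(nterm_record.residues)
    n_cols = potra_profile.n_columns
    residues = nterm_record.residues
    segments: list[PotraSegment] = []
    for _ in range(max_segments):
        masked = SequenceRecord(id=nterm_record.id, residues=residues)
        hits = search(potra_profile, [masked],
                      inclusion_evalue=evalue_threshold, db_size=1)
        if not hits:
            break
        hit = hits[0]
        start = hit.env_start
        end = hit.env_end
        if hit.profile_start:
            start -= hit.profile_start - 1
            end += n_cols - hit.profile_end
        start = max(1, start)
        end = min(n, end)
        for seg in segments:  # stay clear of already-assigned repeats
            if seg.end < hit.env_start:
                start = max(start, seg.end + 1)
            if seg.start > hit.env_end:
                end = min(end, seg.start - 1)
        segments.append(PotraSegment(id=nterm_record.id, index=0,
                                     start=start, end=end, score=hit.score))
        residues = (residues[:start - 1] + "X" * (end - start + 1)
                    + residues[end:])
    segments = [s for s in segments if min_len <= s.length <= max_len]
    segments.sort(key=lambda s: s.start)
    for k, seg in enumerate(segments, start=1):
        seg.index = k
    return segments


def consensus_potra_set(cluster_segments: Mapping[str, Sequence[PotraSegment]],
                        ) -> dict[str, list[PotraSegment]]:
    """Enforce one POTRA set per cluster.

    The cluster's modal segment count k* (ties broken toward the larger
    count) caps every sequence: sequences with more segments keep their
    k* highest-scoring ones, renumbered N to C. Sequences with fewer
    keep what they have; missing repeats are never invented.
    """
    if not cluster_segments:
        raise ValueError("empty cluster")
    counts = Counter(len(v) for v in cluster_segments.values())
    top = max(counts.values())
    k_star = max(k for k, c in counts.items() if c == top)
    out: dict[str, list[PotraSegment]] = {}
    for sid, segs in cluster_segments.items():
        segs = list(segs)
        if len(segs) > k_star:
            best = sorted(segs, key=lambda s: (-s.score, s.start))[:k_star]
            segs = sorted(best, key=lambda s: s.start)
        for k, seg in enumerate(segs, start=1):
            seg.index = k
        out[sid] = segs
    return out


def detect_lipobox(record: SequenceRecord, window_start: int = 15,
                   window_end: int = 40, core_length: int = 8,
                   min_hydropathy: float = 1.0) -> LipoboxCall:
    """Call a lipoprotein signal from the sequence itself.

    Positive iff a lipobox [LVI][ASTVIG][GAS]C occurs with its cysteine
    at a 1-based position inside [window_start, window_end] AND the
    ``core_length`` residues immediately preceding the motif average a
    Kyte-Doolittle hydropathy above ``min_hydropathy``. The first
    qualifying cysteine is reported.
    """
    seq = record.residues
    limit = min(window_end, len(seq))
    for m in LIPOBOX_RE.finditer(seq, 0, limit):
        cys_pos = m.end()  # 1-based position of C
        if not (window_start <= cys_pos <= limit):
            continue
        core_start = m.start() - core_length
        if core_start < 0:
            continue
        core = seq[core_start:m.start()]
        mean_kd = sum(KD_HYDROPATHY[ch] for ch in core) / core_length
        if mean_kd > min_hydropathy:
            return LipoboxCall(id=record.id, positive=True, cys_position=cys_pos)
    return LipoboxCall(id=record.id, positive=False)


def extract_region(record: SequenceRecord, span: tuple[int, int],
                   suffix: str = "") -> SequenceRecord:
    """Subsequence record for a 1-based inclusive span, id optionally suffixed."""
    start, end = span
    return SequenceRecord(id=record.id + suffix,
                          residues=record.residues[start - 1:end],
                          taxon_id=record.taxon_id)


def write_partitions(partitions: Sequence[DomainPartition],
                     path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        # coordinates are 1-based inclusive
        writer.writerow(["id", "kind", "start", "end", "source_profile"])
        for p in sorted(partitions, key=lambda x: x.id):
            if p.nterm is not None:
                writer.writerow([p.id, "nterm", p.nterm[0], p.nterm[1],
                                 p.source_profile])
            writer.writerow([p.id, "barrel", p.barrel[0], p.barrel[1],
                             p.source_profile])
    return path


def write_potras(segments: Mapping[str, Sequence[PotraSegment]],
                 path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "index", "start", "end", "score"])
        for sid in sorted(segments):
            for seg in segments[sid]:
                writer.writerow([sid, f"P{seg.index}", seg.start, seg.end,
                                 f"{seg.score:.2f}"])
    return path


def write_lipobox(calls: Sequence[LipoboxCall], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "positive", "cys_position"])
        for c in sorted(calls, key=lambda x: x.id):
            writer.writerow([c.id, int(c.positive),
                             c.cys_position if c.cys_position else ""])
    return path
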