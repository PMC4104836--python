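"""Cluster-level contaminant curation and the global length filter.

A permissive profile search drags in proteins from unrelated families
that share weak similarity with the superfamily ("contaminants"). The
curation rule works at cluster level: confident labels propagate to all
unannotated members of a cluster. A cluster containing contaminant
labels and no superfamily labels is discarded wholly; a cluster with
superfamily labels and no contaminants is kept wholly; clusters with
only unknowns are kept (they were retrieved by the search in the first
place). Mixed clusters are flagged ambiguous and discarded loudly,
since silent keeping would defeat the curation.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cluster import Clustering
from .io import SequenceRecord

logger = logging.getLogger(__name__)

LABEL_MEMBER = "omp85_like"
LABEL_UNKNOWN = "unknown"
CONTAMINANT_PREFIX = "contaminant:"


@dataclass
class CurationResult:
    kept_ids: set[str]
    discarded_ids: set[str]
    cluster_status: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept_ids & self.discarded_ids:
            raise ValueError("kept and discarded id sets overlap")


def _classify_label(label: str) -> str:
    if label == LABEL_MEMBER:
        return "member"
    if label.startswith(CONTAMINANT_PREFIX):
        return "contaminant"
    if label == LABEL_UNKNOWN or label == "":
        return "unknown"
    raise ValueError(f"unrecognized annotation label {label!r}")


def propagate_labels(clustering: Clustering,
                     annotations: Mapping[str, str]) -> CurationResult:
    """Propagate confident cluster labels to unannotated members.

    Per cluster: any contaminant and no superfamily label -> discarded;
    any superfamily label and no contaminant -> kept; both -> ambiguous,
    discarded with a warning; only unknowns -> kept. Ids missing from
    ``annotations`` are treated as unknown and logged.
    """
    kept: set[str] = set()
    discarded: set[str] = set()
    status: dict[int, str] = {}
    for k, members in enumerate(clustering.clusters):
        kinds = set()
        for m in members:
            if m not in annotations:
                logger.info("id %s missing from annotations; treated as unknown", m)
            kinds.add(_classify_label(annotations.get(m, LABEL_UNKNOWN)))
        if "contaminant" in kinds and "member" in kinds:
            warnings.warn(
                f"cluster {k} mixes contaminant and superfamily labels; "
                f"discarding all {len(members)} members", RuntimeWarning)
            status[k] = "ambiguous"
            discarded |= members
        elif "contaminant" in kinds:
            status[k] = "discarded"
            discarded |= members
        else:  # member labels, or unknowns only
            status[k] = "kept"
            kept |= members
    return CurationResult(kept_ids=kept, discarded_ids=discarded,
                          cluster_status=status)


def filter_length(records: Sequence[SequenceRecord], min_length: int = 250,
                  ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Drop sequences shorter than ``min_length`` residues (strict: exactly
    min_length is kept)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in records if len(r) >= min_length]
    removed = [r for r in records if len(r) < min_length]
    return kept, removed


def write_curation(result: CurationResult, clustering: Clustering,
                   path: str | Path) -> Path:
    """TSV export: id, status, cluster_id, reason (the cluster verdict)."""
    path = Path(path)
    membership = clustering.membership()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "status", "cluster_id", "reason"])
        for sid in sorted(result.kept_ids | result.discarded_ids):
            k = membership.get(sid, -1)
            verdict = result.cluster_status.get(k, "unclustered")
            state = "kept" if sid in result.kept_ids else "discarded"
            writer.writerow([sid, state, k, verdict])
    return path
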