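"""End-to-end orchestration of the superfamily classification pipeline.

Stage order: profile search with both barrel profiles (permissive
reporting threshold) -> per-target merge keeping the higher-scoring
profile hit -> duplicate collapse -> all-vs-all alignment -> Markov
clustering at inflation 1.5 -> contaminant label propagation ->
contaminant removal -> 250 aa length filter -> Markov re-clustering at
inflation 1.3 (the final subfamily clusters) -> barrel/N-terminus
partition at the best hit's envelope start -> POTRA carving with
per-cluster consensus -> lipobox detection -> region similarity
networks -> taxonomic distribution matrices.

All numeric parameters live in :class:`PipelineConfig`; defaults are
the published ones. Given a fixed config (including seed) the pipeline
is deterministic and reruns are byte-identical.
"""

from __future__ import annotations

import csv
import logging
import time
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from . import curate as curate_mod
from . import domains as domains_mod
from . import network as network_mod
from .cluster import (Clustering, MclOptions, build_graph, mcl,
                      write_clustering, write_graph)
from .curate import CurationResult, filter_length, propagate_labels
from .domains import (DomainPartition, LipoboxCall, PotraSegment,
                      consensus_potra_set, detect_lipobox, extract_region,
                      scan_potras, split_domains)
from .io import (DuplicateGroup, SequenceRecord, TaxonRecord,
                 collapse_identical, read_aligned_fasta, read_fasta,
                 read_taxa, write_duplicate_groups, write_fasta)
from .pairwise import PairHit, all_vs_all, write_hits_m8
from .profiles import (Hit, build_profile, calibrate,
                       merge_hits, search, write_hits)
from .synth import read_annotations

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass
class PipelineConfig:
    """Every path and numeric parameter of the pipeline."""

    sequences: str = "sequences.fasta"
    seed_omp85: str = "seeds/barrel_omp85.afa"
    seed_tpsb: str = "seeds/barrel_tpsb.afa"
    seed_potra: str = "seeds/potra.afa"
    annotations: str = "annotations.tsv"
    taxa: str = "taxa.tsv"
    subfamilies: str = ""        # optional TSV id -> subfamily (or truth table)
    ftsq: str = ""               # optional FASTA of POTRA outgroup sequences
    outdir: str = "ompfam_out"

    # profile search
    inclusion_evalue_omp85: float = 1.0
    inclusion_evalue_tpsb: float = 0.1
    reporting_evalue: float = 10.0    # retention bound for below-cutoff hits
    calibration_n: int = 500
    calibration_length: int = 350
    profile_pseudocount: float = 8.0
    profile_gap_open: float = -4.0
    profile_gap_extend: float = -0.5

    # clustering / curation
    mcl_edge_cutoff: float = 1e-2
    inflation_initial: float = 1.5
    inflation_final: float = 1.3
    min_length: int = 250

    # domains
    min_nterm: int = 20
    potra_min_len: int = 25
    potra_max_len: int = 125
    potra_evalue: float = 0.1
    lipobox_window: tuple[int, int] = (15, 40)

    # networks
    network_identity: float = 0.80
    potra_identity: float = 0.50
    network_evalue: float = 1e-5
    potra_network_evalue: float = 1e-3
    network_min_columns: int = 100   # coverage floor for the 0.80 reductions
    potra_min_columns: int = 40      # floor for the POTRA 0.50 reduction

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lipobox_window" in data:
            data["lipobox_window"] = tuple(data["lipobox_window"])
        return cls(**data)


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    warnings: list[str] = field(default_factory=list)
    elapsed: float = 0.0


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[SequenceRecord]
    merged_hits: dict[str, Hit]
    groups: list[DuplicateGroup]
    representatives: list[SequenceRecord]
    pair_hits: list[PairHit]
    initial_clustering: Clustering
    curation: CurationResult
    final_records: list[SequenceRecord]
    final_clustering: Clustering
    cluster_labels: list[str]
    partitions: dict[str, DomainPartition]
    potras: dict[str, list[PotraSegment]]
    lipobox: dict[str, LipoboxCall]
    networks: dict[str, network_mod.AttributedNetwork]
    presence: Any
    copies: Any
    taxa: list[TaxonRecord]
    annotations: dict[str, dict[str, str]]
    reports: list[StageReport]

    def subfamily_of(self, seq_id: str) -> str:
        for label, members in zip(self.cluster_labels,
                                  self.final_clustering.clusters):
            if seq_id in members:
                return label
        return "unknown"


def _read_subfamily_map(path: str | Path) -> dict[str, str]:
    """id -> subfamily from a TSV with a 'subfamily' or 'template' column."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        col = ("subfamily" if "subfamily" in (reader.fieldnames or [])
               else "template")
        for row in reader:
            out[row["id"]] = row[col]
    return out


def _group_label(group: DuplicateGroup, labels: dict[str, str]) -> str:
    """Curation label of a duplicate group: a contaminant annotation on any
    member taints the group; otherwise any superfamily annotation keeps it."""
    member_labels = [labels.get(m, "unknown") for m in group.member_ids]
    for lab in member_labels:
        if lab.startswith(curate_mod.CONTAMINANT_PREFIX):
            return lab
    if curate_mod.LABEL_MEMBER in member_labels:
        return curate_mod.LABEL_MEMBER
    return curate_mod.LABEL_UNKNOWN


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.outdir``."""
    out = Path(config.outdir)
    for sub in ("search", "clusters", "curation", "domains", "networks",
                "distribution"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

            def report(self_inner, n_in: int, n_out: int,
                       warnings_: list[str] | None = None) -> None:
                reports.append(StageReport(
                    stage=name, n_in=n_in, n_out=n_out,
                    warnings=warnings_ or [],
                    elapsed=time.perf_counter() - self_inner.t0))
        return _Ctx()

    # ------------------------------------------------------------------ input
    with stage("read_input") as st:
        records = read_fasta(config.sequences)
        annotations = read_annotations(config.annotations)
        taxa = read_taxa(config.taxa)
        for rec in records:
            rec.taxon_id = annotations.get(rec.id, {}).get("taxon_id", "")
        st.report(len(records), len(records))

    # --------------------------------------------------------------- profiles
    with stage("build_profiles") as st:
        gap = dict(gap_open=config.profile_gap_open,
                   gap_extend=config.profile_gap_extend,
                   pseudocount_weight=config.profile_pseudocount)
        prof_omp85 = build_profile(read_aligned_fasta(config.seed_omp85),
                                   name="omp85", **gap)
        prof_tpsb = build_profile(read_aligned_fasta(config.seed_tpsb),
                                  name="tpsb", **gap)
        prof_potra = build_profile(read_aligned_fasta(config.seed_potra),
                                   name="potra", **gap)
        for k, prof in enumerate((prof_omp85, prof_tpsb, prof_potra)):
            calibrate(prof, n_random=config.calibration_n,
                      length=config.calibration_length,
                      seed=(config.seed * 3 + k) % (2**31))
        st.report(3, 3)

    # ----------------------------------------------------------------- search
    with stage("profile_search") as st:
        db = len(records)
        hits_omp85 = search(prof_omp85, records,
                            inclusion_evalue=config.reporting_evalue, db_size=db)
        hits_tpsb = search(prof_tpsb, records,
                           inclusion_evalue=config.reporting_evalue, db_size=db)
        merged = merge_hits(hits_omp85, hits_tpsb)
        write_hits(hits_omp85, out / "search" / "hits_omp85.tsv")
        write_hits(hits_tpsb, out / "search" / "hits_tpsb.tsv")
        write_hits(sorted(merged.values(), key=lambda h: h.target_id),
                   out / "search" / "hits_merged.tsv")
        retrieved = [r for r in records if r.id in merged]
        below = [
            f"omp85: {sum(1 for h in hits_omp85 if h.evalue > config.inclusion_evalue_omp85)}"
            f"/{len(hits_omp85)} retained hits below the inclusion threshold",
            f"tpsb: {sum(1 for h in hits_tpsb if h.evalue > config.inclusion_evalue_tpsb)}"
            f"/{len(hits_tpsb)} retained hits below the inclusion threshold",
        ]
        st.report(len(records), len(retrieved), below)

    # --------------------------------------------------------------- collapse
    with stage("collapse_identical") as st:
        groups, reps = collapse_identical(retrieved)
        write_duplicate_groups(groups, out / "duplicate_groups.tsv")
        st.report(len(retrieved), len(reps))

    # ------------------------------------------------------------- all-vs-all
    with stage("all_vs_all") as st:
        pair_hits = all_vs_all(reps, evalue_cutoff=config.mcl_edge_cutoff,
                               include_self=False)
        write_hits_m8(pair_hits, out / "search" / "all_vs_all.m8.tsv")
        st.report(len(reps), len(pair_hits))

    # -------------------------------------------------------- curation MCL
    with stage("mcl_initial") as st:
        graph = build_graph(pair_hits, evalue_cutoff=config.mcl_edge_cutoff,
                            nodes=[r.id for r in reps])
        write_graph(graph, out / "clusters" / "graph_initial.tsv")
        initial = mcl(graph, MclOptions(inflation=config.inflation_initial))
        write_clustering(initial, out / "clusters" / "mcl_initial.tsv")
        st.report(len(reps), len(initial.clusters))

    # ------------------------------------------------------------- curation
    with stage("propagate_labels") as st:
        raw_labels = {sid: meta.get("label", "unknown")
                      for sid, meta in annotations.items()}
        rep_labels = {g.representative_id: _group_label(g, raw_labels)
                      for g in groups}
        curation = propagate_labels(initial, rep_labels)
        curate_mod.write_curation(curation, initial,
                                  out / "curation" / "curation.tsv")
        kept = [r for r in reps if r.id in curation.kept_ids]
        st.report(len(reps), len(kept))

    # ---------------------------------------------------------- length filter
    with stage("filter_length") as st:
        final_records, removed = filter_length(kept, config.min_length)
        if not final_records:
            raise ValueError("no sequences left after length filter")
        write_fasta(final_records, out / "curation" / "curated.fasta")
        st.report(len(kept), len(final_records))

    # -------------------------------------------------------------- final MCL
    with stage("mcl_final") as st:
        final_ids = [r.id for r in final_records]
        graph_final = build_graph(pair_hits,
                                  evalue_cutoff=config.mcl_edge_cutoff,
                                  nodes=final_ids)
        final = mcl(graph_final, MclOptions(inflation=config.inflation_final))
        st.report(len(final_records), len(final.clusters))

    # -------------------------------------------------------- subfamily names
    with stage("label_clusters") as st:
        subfamily_map = (_read_subfamily_map(config.subfamilies)
                         if config.subfamilies else {})
        labels: list[str] = []
        for k, members in enumerate(final.clusters):
            named = [subfamily_map[m] for m in members if m in subfamily_map]
            labels.append(Counter(named).most_common(1)[0][0] if named
                          else f"cluster_{k}")
        final.labels = labels
        write_clustering(final, out / "clusters" / "mcl_final.tsv")
        st.report(len(final.clusters), len(final.clusters))

    # -------------------------------------------------------------- partition
    with stage("split_domains") as st:
        by_id = {r.id: r for r in final_records}
        partitions: dict[str, DomainPartition] = {}
        for sid in sorted(by_id):
            partitions[sid] = split_domains(by_id[sid], merged[sid],
                                            min_nterm=config.min_nterm)
        domains_mod.write_partitions(list(partitions.values()),
                                     out / "domains" / "partitions.tsv")
        barrel_records = [extract_region(by_id[sid], partitions[sid].barrel)
                          for sid in sorted(by_id)]
        nterm_records = [extract_region(by_id[sid], partitions[sid].nterm)
                         for sid in sorted(by_id)
                         if partitions[sid].nterm is not None]
        write_fasta(barrel_records, out / "domains" / "barrel.fasta")
        if nterm_records:
            write_fasta(nterm_records, out / "domains" / "nterm.fasta")
        st.report(len(final_records), len(barrel_records))

    # ------------------------------------------------------------ POTRA scan
    with stage("scan_potras") as st:
        nterm_by_id = {r.id: r for r in nterm_records}
        raw_segments: dict[str, list[PotraSegment]] = {}
        for sid in sorted(nterm_by_id):
            raw_segments[sid] = scan_potras(
                nterm_by_id[sid], prof_potra,
                min_len=config.potra_min_len, max_len=config.potra_max_len,
                evalue_threshold=config.potra_evalue)
        # one POTRA set per final cluster
        potras: dict[str, list[PotraSegment]] = {}
        for members in final.clusters:
            cluster_segs = {sid: raw_segments[sid] for sid in members
                            if sid in raw_segments}
            if cluster_segs:
                potras.update(consensus_potra_set(cluster_segs))
        domains_mod.write_potras(potras, out / "domains" / "potras.tsv")
        st.report(len(nterm_by_id),
                  sum(len(v) for v in potras.values()))

    # ---------------------------------------------------------------- lipobox
    with stage("detect_lipobox") as st:
        w0, w1 = config.lipobox_window
        lipo = {sid: detect_lipobox(by_id[sid], w0, w1)
                for sid in sorted(by_id)}
        domains_mod.write_lipobox(list(lipo.values()),
                                  out / "domains" / "lipobox.tsv")
        st.report(len(by_id), sum(c.positive for c in lipo.values()))

    # --------------------------------------------------------------- networks
    with stage("networks") as st:
        taxon_of = {sid: annotations.get(sid, {}).get("taxon_id", "")
                    for sid in by_id}
        phylum_of = {t.taxon_id: t.phylum for t in taxa}

        def attrs_for(sid: str, region: str, potra_index: str = "") -> dict:
            base = sid.split("/", 1)[0]
            return {"subfamily": res_subfamily.get(base, "unknown"),
                    "phylum": phylum_of.get(taxon_of.get(base, ""), "unknown"),
                    "region": region,
                    "potra_index": potra_index or "unknown"}

        res_subfamily = {m: labels[k]
                         for k, members in enumerate(final.clusters)
                         for m in members}
        networks: dict[str, network_mod.AttributedNetwork] = {}
        networks["full"] = network_mod.build_network(
            final_records, config.network_identity, config.network_evalue,
            {sid: attrs_for(sid, "full") for sid in by_id},
            precomputed_hits=pair_hits,
            min_columns=config.network_min_columns)
        networks["barrel"] = network_mod.build_network(
            barrel_records, config.network_identity, config.network_evalue,
            {r.id: attrs_for(r.id, "barrel") for r in barrel_records},
            min_columns=config.network_min_columns)
        if len(nterm_records) >= 2:
            networks["nterm"] = network_mod.build_network(
                nterm_records, config.network_identity, config.network_evalue,
                {r.id: attrs_for(r.id, "nterm") for r in nterm_records},
                min_columns=config.network_min_columns)
        potra_records = []
        potra_attrs = {}
        for sid in sorted(potras):
            for seg in potras[sid]:
                reg = extract_region(by_id[sid], (seg.start, seg.end),
                                     suffix=f"/P{seg.index}")
                potra_records.append(reg)
                potra_attrs[reg.id] = attrs_for(sid, "potra", f"P{seg.index}")
        if config.ftsq:
            for rec in read_fasta(config.ftsq):
                for seg in scan_potras(rec, prof_potra,
                                       min_len=config.potra_min_len,
                                       max_len=config.potra_max_len,
                                       evalue_threshold=config.potra_evalue):
                    reg = extract_region(rec, (seg.start, seg.end),
                                         suffix=f"/P{seg.index}")
                    potra_records.append(reg)
                    potra_attrs[reg.id] = {
                        "subfamily": "FtsQ_outgroup", "phylum": "unknown",
                        "region": "potra", "potra_index": f"P{seg.index}"}
        if len(potra_records) >= 2:
            write_fasta(potra_records, out / "domains" / "potra.fasta")
            networks["potra"] = network_mod.build_network(
                potra_records, config.potra_identity,
                config.potra_network_evalue, potra_attrs,
                min_columns=config.potra_min_columns)
        for name, net in networks.items():
            network_mod.write_network(net, out / "networks" / name)
        st.report(len(final_records), len(networks))

    # ------------------------------------------------------------ distribution
    with stage("distribution") as st:
        assignments = {sid: (res_subfamily[sid], taxon_of.get(sid, ""))
                       for sid in by_id}
        presence = network_mod.presence_matrix(assignments, taxa)
        copies = network_mod.copy_numbers(assignments, taxa)
        presence.to_csv(out / "distribution" / "presence_matrix.tsv", sep="\t",
                        float_format="%.2f")
        copies.to_csv(out / "distribution" / "copy_numbers.tsv", sep="\t")
        st.report(len(assignments), presence.size)

    with open(out / "stage_reports.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stage", "n_in", "n_out", "warnings"])
        for r in reports:
            writer.writerow([r.stage, r.n_in, r.n_out, ";".join(r.warnings)])

    return PipelineResult(
        config=config, records=records, merged_hits=merged, groups=groups,
        representatives=reps, pair_hits=pair_hits, initial_clustering=initial,
        curation=curation, final_records=final_records, final_clustering=final,
        cluster_labels=labels, partitions=partitions, potras=potras,
        lipobox=lipo, networks=networks, presence=presence, copies=copies,
        taxa=taxa, annotations=annotations, reports=reports)
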