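"""Synthetic Omp85/TpsB superfamily generator.

Emulates, at desk scale, the structure of the real superfamily: ten
domain architectures built around a conserved membrane-embedded barrel
domain (two divergent barrel sequence classes, Omp85-type and
TpsB-type, sharing roughly 40% identity), 0-5 tandem POTRA repeats
N-terminal to the barrel, accessory N-terminal domains (WD40-, patatin-
and metallopeptidase-like), a lipoprotein subfamily with an N-terminal
lipobox signal, contaminant families sharing only a short weakly
similar segment with the barrel, and a phylum-structured taxon table
with complete-proteome flags.

Generation is hierarchical: a shared domain consensus library (the
superfamily ancestor), per-subfamily consensus variants diverged from
it, and individual sequences diverged from their subfamily consensus.
Functionally invariant positions (the four lipobox residues; the
hydrophobic signal core at the subfamily level) are exempt from
substitution, mirroring the hard conservation of the lipobox cysteine
in real lipoproteins. Indels are confined to inter-domain linkers by
default so that ground-truth domain coordinates stay exact.

Every draw flows from a single integer seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (AMINO_ACIDS, BACKGROUND_FREQUENCIES, SequenceRecord,
                 TaxonRecord, write_fasta, write_taxa)

HYDROPHOBIC = "LIVF"  # signal h-region draws: strongly hydrophobic, Leu-rich
#: real-protein background composition, so pairwise and profile E-value
#: statistics (derived for real proteins) hold on generated sequences
_BG = np.array([BACKGROUND_FREQUENCIES[a] for a in AMINO_ACIDS])
_BG = _BG / _BG.sum()
#: lengths of the consensus domain library
DOMAIN_LENGTHS = {
    "barrel_omp85": 380,
    "barrel_tpsb": 300,
    "potra": 75,
    "wd40": 280,
    "patatin": 230,
    "metallo": 150,
    "signal": 20,
}
LINKER_LENGTH = 10
#: fraction of barrel_omp85 positions mutated to derive the TpsB-class barrel
TPSB_DIVERGENCE = 0.60
#: contaminant families share this much of the Omp85 barrel, this faintly
CONTAMINANT_SEGMENT_LEN = 60
CONTAMINANT_SEGMENT_DIVERGENCE = 0.60


@dataclass(frozen=True)
class ArchitectureTemplate:
    """One domain architecture of the superfamily."""

    name: str
    barrel_class: str          # omp85 | tpsb | none
    potra_count: int
    accessory_domain: str = "none"   # none | wd40 | patatin | metallo
    lipobox: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.potra_count <= 5):
            raise ValueError("potra_count must be in [0, 5]")
        if self.barrel_class not in ("omp85", "tpsb", "none"):
            raise ValueError(f"unknown barrel class {self.barrel_class!r}")
        if self.barrel_class == "none" and not (
                self.name.startswith("Contaminant") or self.name == "FtsQ_outgroup"):
            raise ValueError("barrel_class 'none' is reserved for contaminants "
                             "and the FtsQ outgroup")
        if self.accessory_domain not in ("none", "wd40", "patatin", "metallo"):
            raise ValueError(f"unknown accessory domain {self.accessory_domain!r}")
        if self.lipobox and self.potra_count < 1:
            raise ValueError("lipobox templates must carry at least one POTRA")


#: the ten bacterial subfamily architectures, plus the cyanobacterial BamA
#: variant and the FtsQ POTRA outgroup
TEMPLATES: dict[str, ArchitectureTemplate] = {t.name: t for t in [
    ArchitectureTemplate("BamA", "omp85", 5),
    ArchitectureTemplate("BamA_cyano", "omp85", 3),
    ArchitectureTemplate("TamA", "omp85", 3),
    ArchitectureTemplate("BamA_like", "omp85", 3),
    ArchitectureTemplate("Lipo", "omp85", 3, lipobox=True),
    ArchitectureTemplate("WD40", "omp85", 0, accessory_domain="wd40"),
    ArchitectureTemplate("Patatin", "omp85", 1, accessory_domain="patatin"),
    ArchitectureTemplate("Metallo", "omp85", 0, accessory_domain="metallo"),
    ArchitectureTemplate("noNterm", "omp85", 0),
    ArchitectureTemplate("FhaC", "tpsb", 2),
    ArchitectureTemplate("Hmw1B", "tpsb", 2),
    ArchitectureTemplate("FtsQ_outgroup", "none", 1),
]}

DEFAULT_TEMPLATE_COUNTS = {
    "BamA": 30, "TamA": 30, "BamA_like": 30, "Lipo": 30, "WD40": 30,
    "Patatin": 30, "Metallo": 30, "noNterm": 30, "FhaC": 30, "Hmw1B": 30,
}

DEFAULT_PHYLA = {
    "Proteobacteria": 5, "Bacteroidetes": 5, "Chlorobi": 5, "Cyanobacteria": 5,
}

#: which phyla carry which template; Lipo confined to the Bacteroidetes
DEFAULT_TEMPLATE_PHYLA = {
    "BamA": ["Proteobacteria", "Bacteroidetes", "Chlorobi", "Cyanobacteria"],
    "BamA_cyano": ["Cyanobacteria"],
    "TamA": ["Proteobacteria", "Cyanobacteria"],
    "BamA_like": ["Proteobacteria", "Chlorobi"],
    "Lipo": ["Bacteroidetes"],
    "WD40": ["Proteobacteria", "Chlorobi"],
    "Patatin": ["Proteobacteria"],
    "Metallo": ["Proteobacteria", "Cyanobacteria"],
    "noNterm": ["Chlorobi", "Cyanobacteria"],
    "FhaC": ["Proteobacteria"],
    "Hmw1B": ["Proteobacteria"],
}


@dataclass
class TruthRecord:
    """Ground-truth annotation for one generated sequence."""

    id: str
    template_name: str
    domain_coords: list[tuple[str, int, int]]
    taxon_id: str

    def __post_init__(self) -> None:
        prev_end = 0
        for kind, start, end in self.domain_coords:
            if start <= prev_end or end < start:
                raise ValueError(
                    f"truth coordinates for {self.id!r} are not sorted / "
                    f"non-overlapping: {self.domain_coords}")
            prev_end = end


@dataclass
class GeneratorConfig:
    template_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_COUNTS))
    divergence: float = 0.25
    indel_rate: float = 0.01
    # subfamilies are barely alignable to each other outside conserved
    # cores, as in the real superfamily: cross-subfamily pairs mostly do
    # not reach the 1e-2 all-vs-all cutoff, within-subfamily pairs always do
    family_divergence: float = 0.6
    # seed alignments span family-level diversity, like Pfam seeds
    seed_rows: int = 12
    seed_divergence: float = 0.45
    n_contaminant_families: int = 5
    contaminants_per_family: int = 10
    annotated_fraction: float = 0.5
    # contaminants stem from established, well-annotated families; the novel
    # superfamily members are the under-annotated ones
    contaminant_annotated_fraction: float = 0.9
    allow_domain_indels: bool = False
    phyla: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PHYLA))
    n_ftsq: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 0.9):
            raise ValueError("divergence must be in [0, 0.9)")
        for name, count in self.template_counts.items():
            if name not in TEMPLATES:
                raise ValueError(f"unknown template {name!r}")
            if count <= 0:
                raise ValueError(f"template {name!r} referenced with count {count}")


@dataclass
class Part:
    """One building block of an architecture consensus."""

    kind: str              # signal / wd40 / patatin / metallo / potra / barrel
                           # / linker / other
    residues: str
    frozen: frozenset[int] = frozenset()   # 0-based positions exempt from substitution
    #: positions restricted to hydrophobic substitutions (h-region selection)
    conservative: frozenset[int] = frozenset()
    is_linker: bool = False


def _random_string(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i]
                   for i in rng.choice(20, size=length, p=_BG))


def _mutate(residues: str, prob: float, rng: np.random.Generator,
            frozen: frozenset[int] = frozenset(),
            conservative: frozenset[int] = frozenset()) -> str:
    """Substitute each non-frozen position independently with probability
    ``prob``, always to a different residue drawn from the background.

    ``conservative`` positions substitute within the hydrophobic alphabet
    only (purifying selection on signal-peptide h-regions).
    """
    if prob <= 0.0:
        return residues
    out = list(residues)
    hit = rng.random(len(out)) < prob
    for i in np.flatnonzero(hit):
        if int(i) in frozen:
            continue
        repl = out[i]
        if int(i) in conservative:
            while repl == out[i]:
                repl = HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
        else:
            while repl == out[i]:
                repl = AMINO_ACIDS[rng.choice(20, p=_BG)]
        out[i] = repl
    return "".join(out)


def _mutate_exact(residues: str, prob: float, rng: np.random.Generator,
                  frozen: frozenset[int] = frozenset()) -> str:
    """Substitute an exact fraction ``prob`` of the non-frozen positions
    (chosen uniformly), to different background-drawn residues.

    Used for subfamily-consensus derivation: the exact count removes the
    binomial variance of per-site mutation, so every subfamily pair sits
    at the intended evolutionary distance instead of a spread around it.
    """
    if prob <= 0.0:
        return residues
    out = list(residues)
    mutable = [i for i in range(len(out)) if i not in frozen]
    k = int(round(prob * len(mutable)))
    for i in rng.permutation(len(mutable))[:k]:
        pos = mutable[int(i)]
        repl = out[pos]
        while repl == out[pos]:
            repl = AMINO_ACIDS[rng.choice(20, p=_BG)]
        out[pos] = repl
    return "".join(out)


def _scrub_nterm_cysteines(residues: str, upto: int = 45) -> str:
    """Remove cysteines from the first ``upto`` residues so spurious
    lipobox motifs cannot arise from the consensus itself."""
    head = residues[:upto].replace("C", "S")
    return head + residues[upto:]


def make_domain_library(seed: int) -> dict[str, str]:
    """The shared (ancestral) consensus for every domain kind.

    The TpsB-class barrel derives from the Omp85-class barrel with 60%
    of positions substituted (about 40% residual identity); the signal
    consensus is 20 aa ending in the lipobox L-A-G-C with a hydrophobic
    core before it. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    lib: dict[str, str] = {}
    for kind in ("barrel_omp85", "potra", "wd40", "patatin", "metallo"):
        lib[kind] = _scrub_nterm_cysteines(
            _random_string(rng, DOMAIN_LENGTHS[kind]))
    tpsb = _mutate(lib["barrel_omp85"][:DOMAIN_LENGTHS["barrel_tpsb"]],
                   TPSB_DIVERGENCE, rng)
    lib["barrel_tpsb"] = _scrub_nterm_cysteines(tpsb)
    core = "".join(HYDROPHOBIC[i] for i in rng.integers(0, len(HYDROPHOBIC), size=8))
    lib["signal"] = "M" + _random_string(rng, 7).replace("C", "S") + core + "LAGC"
    return lib


SIGNAL_MOTIF_FROZEN = frozenset(range(16, 20))   # the lipobox L-A-G-C
SIGNAL_FAMILY_FROZEN = frozenset(range(8, 20))   # hydrophobic core + lipobox
#: structural core of the POTRA fold, conserved across subfamilies — the
#: reason a single profile detects POTRA repeats superfamily-wide
POTRA_CORE_FROZEN = frozenset(range(0, DOMAIN_LENGTHS["potra"], 8))
#: membrane-embedded barrel core positions, conserved across subfamilies of
#: one barrel class (each class keeps its own core); profile anchor columns
BARREL_CORE_FROZEN = frozenset(range(0, DOMAIN_LENGTHS["barrel_omp85"], 10))


def _family_frozen(kind: str) -> frozenset[int]:
    """Positions of a domain kind exempt from subfamily-level divergence."""
    if kind == "potra":
        return POTRA_CORE_FROZEN
    if kind.startswith("barrel"):
        return frozenset(p for p in BARREL_CORE_FROZEN
                         if p < DOMAIN_LENGTHS[kind])
    if kind == "signal":
        return SIGNAL_FAMILY_FROZEN
    return frozenset()


def architecture_parts(template: ArchitectureTemplate, library: dict[str, str],
                       rng: np.random.Generator,
                       family_divergence: float = 0.0) -> list[Part]:
    """Subfamily-level consensus parts for one architecture.

    Domain order is fixed: optional signal, optional accessory domain,
    POTRA repeats, then the barrel, with a fresh random linker between
    consecutive domains. Each domain instance is independently diverged
    from the library consensus at ``family_divergence`` (each POTRA
    repeat gets its own variant, as tandem repeats drift apart).
    """
    parts: list[Part] = []

    def add_linker() -> None:
        if parts:
            parts.append(Part("linker", _random_string(rng, LINKER_LENGTH),
                              is_linker=True))

    def family_variant(kind: str, frozen: frozenset[int] = frozenset()) -> str:
        return _mutate_exact(library[kind], family_divergence, rng, frozen)

    if template.lipobox:
        parts.append(Part("signal", family_variant("signal", SIGNAL_FAMILY_FROZEN),
                          frozen=SIGNAL_MOTIF_FROZEN,
                          conservative=frozenset(range(8, 16))))
    if template.accessory_domain != "none":
        add_linker()
        parts.append(Part(template.accessory_domain,
                          family_variant(template.accessory_domain)))
    for _ in range(template.potra_count):
        add_linker()
        # the POTRA fold's core residues are conserved across subfamilies:
        # they are the anchor columns a single profile recognizes
        parts.append(Part("potra", family_variant("potra", POTRA_CORE_FROZEN)))
    if template.barrel_class != "none":
        add_linker()
        kind = f"barrel_{template.barrel_class}"
        parts.append(Part("barrel", family_variant(kind, _family_frozen(kind))))
    elif template.name == "FtsQ_outgroup":
        # FtsQ: a POTRA plus an unrelated periplasmic domain, no barrel
        add_linker()
        parts.append(Part("other", _random_string(rng, 150)))
    return parts


def sample_sequence(template: ArchitectureTemplate, parts: Sequence[Part],
                    divergence: float, indel_rate: float,
                    rng: np.random.Generator, seq_id: str = "seq",
                    taxon_id: str = "",
                    allow_domain_indels: bool = False,
                    ) -> tuple[SequenceRecord, TruthRecord]:
    """Draw one sequence from a subfamily consensus.

    Every non-frozen consensus position substitutes independently with
    probability ``divergence``. Indels (rate per site, half insertions,
    half deletions) are applied inside linkers only, unless
    ``allow_domain_indels`` is set; ground-truth coordinates track all
    shifts.
    """
    chunks: list[str] = []
    coords: list[tuple[str, int, int]] = []
    pos = 0
    for part in parts:
        mutated = _mutate(part.residues, divergence, rng, part.frozen,
                          part.conservative)
        if part.is_linker or allow_domain_indels:
            built: list[str] = []
            for ch in mutated:
                r = rng.random()
                if r < indel_rate / 2.0:
                    continue  # deletion
                built.append(ch)
                if r >= 1.0 - indel_rate / 2.0:
                    built.append(AMINO_ACIDS[rng.choice(20, p=_BG)])
            mutated = "".join(built)
        start = pos + 1
        pos += len(mutated)
        chunks.append(mutated)
        if not part.is_linker and mutated:
            coords.append((part.kind, start, pos))
    record = SequenceRecord(id=seq_id, residues="".join(chunks),
                            taxon_id=taxon_id)
    truth = TruthRecord(id=seq_id, template_name=template.name,
                        domain_coords=coords, taxon_id=taxon_id)
    return record, truth


def _contaminant_parts(library: dict[str, str], rng: np.random.Generator,
                       ) -> list[Part]:
    """Consensus for one contaminant family.

    A random protein of 280-420 aa carrying one 60-residue segment
    derived from the Omp85 barrel at ~35% identity. The segment is
    conserved within the family (it is the family's motif), so the
    permissive profile search can retrieve these proteins even though
    they fail subfamily-level clustering.
    """
    length = int(rng.integers(280, 421))
    residues = _random_string(rng, length)
    barrel = library["barrel_omp85"]
    seg_src = int(rng.integers(0, len(barrel) - CONTAMINANT_SEGMENT_LEN))
    segment = _mutate_exact(barrel[seg_src:seg_src + CONTAMINANT_SEGMENT_LEN],
                            CONTAMINANT_SEGMENT_DIVERGENCE, rng)
    insert_at = int(rng.integers(30, length - CONTAMINANT_SEGMENT_LEN - 10))
    residues = (residues[:insert_at] + segment
                + residues[insert_at + CONTAMINANT_SEGMENT_LEN:])
    frozen = frozenset(range(insert_at, insert_at + CONTAMINANT_SEGMENT_LEN))
    return [Part("other", _scrub_nterm_cysteines(residues), frozen=frozen)]


@dataclass
class GeneratedDataset:
    records: list[SequenceRecord]
    truth: dict[str, TruthRecord]
    annotations: dict[str, str]          # id -> omp85_like / contaminant:* / unknown
    taxa: list[TaxonRecord]
    library: dict[str, str]
    seed_alignments: dict[str, list[tuple[str, str]]]
    ftsq_records: list[SequenceRecord]

    def template_of(self, seq_id: str) -> str:
        return self.truth[seq_id].template_name


def _seed_alignment(library: dict[str, str], kind: str,
                    rng: np.random.Generator, n_rows: int = 12,
                    divergence: float = 0.40) -> list[tuple[str, str]]:
    """Ungapped seed alignment: family-diverse samples of one domain, so the
    derived profile generalizes across subfamilies the way Pfam profiles do.
    Invariant core positions stay fixed in every row, giving the profile the
    strong anchor columns real repeat profiles have."""
    frozen = _family_frozen(kind)
    return [(f"{kind}_seed{i + 1}",
             _mutate(library[kind], divergence, rng, frozen))
            for i in range(n_rows)]


def _make_taxa(phyla: dict[str, int]) -> list[TaxonRecord]:
    taxa: list[TaxonRecord] = []
    for phylum, n in phyla.items():
        for i in range(1, n + 1):
            taxa.append(TaxonRecord(
                taxon_id=f"t_{phylum}_{i}",
                name=f"{phylum} sp. {i}",
                phylum=phylum,
                complete_proteome=(i != n),  # last taxon per phylum incomplete
            ))
    return taxa


def generate(config: GeneratorConfig) -> GeneratedDataset:
    """Generate the full synthetic dataset in memory."""
    rng = np.random.default_rng(config.seed)
    library = make_domain_library(int(rng.integers(0, 2**31)))
    taxa = _make_taxa(config.phyla)
    taxa_by_phylum: dict[str, list[str]] = {}
    for t in taxa:
        taxa_by_phylum.setdefault(t.phylum, []).append(t.taxon_id)
    all_taxa = [t.taxon_id for t in taxa]

    records: list[SequenceRecord] = []
    truth: dict[str, TruthRecord] = {}
    annotations: dict[str, str] = {}

    for name in sorted(config.template_counts):
        template = TEMPLATES[name]
        count = config.template_counts[name]
        parts = architecture_parts(template, library, rng,
                                   config.family_divergence)
        phyla = DEFAULT_TEMPLATE_PHYLA.get(name, list(config.phyla))
        pool = [tid for p in phyla for tid in taxa_by_phylum.get(p, [])]
        for i in range(count):
            seq_id = f"{name}_{i + 1:03d}"
            taxon = pool[i % len(pool)] if pool else ""
            rec, tr = sample_sequence(
                template, parts, config.divergence, config.indel_rate, rng,
                seq_id=seq_id, taxon_id=taxon,
                allow_domain_indels=config.allow_domain_indels)
            records.append(rec)
            truth[seq_id] = tr
            annotations[seq_id] = ("omp85_like"
                                   if rng.random() < config.annotated_fraction
                                   else "unknown")

    for fam in range(1, config.n_contaminant_families + 1):
        fam_name = f"Contaminant_{fam}"
        template = ArchitectureTemplate(fam_name, "none", 0)
        parts = _contaminant_parts(library, rng)
        for i in range(config.contaminants_per_family):
            seq_id = f"Cont{fam}_{i + 1:03d}"
            taxon = all_taxa[(fam * 7 + i) % len(all_taxa)]
            rec, tr = sample_sequence(
                template, parts, config.divergence, config.indel_rate, rng,
                seq_id=seq_id, taxon_id=taxon)
            records.append(rec)
            truth[seq_id] = tr
            annotations[seq_id] = (
                f"contaminant:fam{fam}"
                if rng.random() < config.contaminant_annotated_fraction
                else "unknown")

    seeds = {kind: _seed_alignment(library, kind, rng,
                                   n_rows=config.seed_rows,
                                   divergence=config.seed_divergence)
             for kind in ("barrel_omp85", "barrel_tpsb", "potra")}

    ftsq: list[SequenceRecord] = []
    if config.n_ftsq > 0:
        template = TEMPLATES["FtsQ_outgroup"]
        parts = architecture_parts(template, library, rng,
                                   config.family_divergence)
        for i in range(config.n_ftsq):
            rec, tr = sample_sequence(
                template, parts, config.divergence, config.indel_rate, rng,
                seq_id=f"FtsQ_{i + 1:03d}")
            ftsq.append(rec)

    return GeneratedDataset(records=records, truth=truth,
                            annotations=annotations, taxa=taxa,
                            library=library, seed_alignments=seeds,
                            ftsq_records=ftsq)


def write_truth(truth: dict[str, TruthRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "template", "taxon_id", "domains"])
        for sid in sorted(truth):
            tr = truth[sid]
            dom = ";".join(f"{k}:{s}-{e}" for k, s, e in tr.domain_coords)
            writer.writerow([sid, tr.template_name, tr.taxon_id, dom])
    return path


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            coords = []
            if row["domains"]:
                for item in row["domains"].split(";"):
                    kind, span = item.split(":")
                    s, e = span.split("-")
                    coords.append((kind, int(s), int(e)))
            out[row["id"]] = TruthRecord(id=row["id"],
                                         template_name=row["template"],
                                         domain_coords=coords,
                                         taxon_id=row["taxon_id"])
    return out


def write_annotations(annotations: dict[str, str],
                      truth: dict[str, TruthRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label", "taxon_id"])
        for sid in sorted(annotations):
            taxon = truth[sid].taxon_id if sid in truth else ""
            writer.writerow([sid, annotations[sid], taxon])
    return path


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """id -> {label, taxon_id} from an annotation TSV."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["id"]] = {"label": row.get("label", "unknown"),
                              "taxon_id": row.get("taxon_id", "")}
    return out


def write_aligned_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n{row}\n")
    return path


def generate_dataset(config: GeneratorConfig, outdir: str | Path,
                     ) -> GeneratedDataset:
    """Generate and write the dataset: sequences.fasta, truth.tsv,
    annotations.tsv, taxa.tsv, ftsq.fasta and seeds/*.afa."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "seeds").mkdir(exist_ok=True)
    ds = generate(config)
    write_fasta(ds.records, outdir / "sequences.fasta")
    write_truth(ds.truth, outdir / "truth.tsv")
    write_annotations(ds.annotations, ds.truth, outdir / "annotations.tsv")
    write_taxa(ds.taxa, outdir / "taxa.tsv")
    for kind, rows in ds.seed_alignments.items():
        write_aligned_fasta(rows, outdir / "seeds" / f"{kind}.afa")
    if ds.ftsq_records:
        write_fasta(ds.ftsq_records, outdir / "ftsq.fasta")
    return ds
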