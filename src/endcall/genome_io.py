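"""Genome, annotation, TSS and 3'-end signal-track I/O.

All coordinates are 0-based half-open **internally**.  At the file
boundaries the each format's native convention is honoured: bedGraph is
0-based half-open, GFF3 is 1-based inclusive, and TSS / position tables
carry 1-based positions.  Conversions happen here and nowhere else.

Per-strand signal lives in separate bedGraph files; reverse-strand
values are stored as positive numbers.  The conventional suffixes are
``.fwd.bedgraph`` / ``.rev.bedgraph``.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

GENE_FEATURE_TYPES = ("mRNA", "tRNA", "rRNA", "sRNA")

#: Genes annotated as leader peptides (regulatory uORFs in 5' UTRs whose
#: stop codons must not disqualify a downstream 3' end).
LEADER_PEPTIDES = (
    "mgtL", "speFL", "hisL", "ivbL", "ilvL", "idlP", "leuL", "pheL",
    "pheM", "pyrL", "rhoL", "rseD", "thrL", "tnaC", "trpL", "uof",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BedGraphError(ValueError):
    """Malformed or out-of-bounds bedGraph content."""


class TableError(ValueError):
    """Malformed tabular (TSS / position) input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenomeSequence:
    """A single chromosome: name, sequence over {A,C,G,T,N}, circularity."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        allowed = set("ACGTN")
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(f"genome contains non-ACGTN characters: {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps on circular genomes.

        On linear genomes out-of-range coordinates raise IndexError.
        """
        L = len(self)
        if start >= end:
            return ""
        if 0 <= start and end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear genome of length {L}")
        idx = np.arange(start, end) % L
        # join via array indexing on the raw string
        s = self.sequence
        return "".join(s[i] for i in idx)

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence(self.name, reverse_complement(self.sequence), self.circular)


@dataclasses.dataclass(frozen=True)
class GenomicPosition:
    """A stranded single-nucleotide coordinate (0-based)."""

    chromosome: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclasses.dataclass
class SignalTrack:
    """Dense per-base non-negative 3'-end counts for one chromosome strand."""

    chromosome: str
    strand: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("signal counts must be non-negative")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return len(self.counts)


@dataclasses.dataclass
class GeneModel:
    """A stranded annotated gene (0-based half-open coordinates).

    For mRNAs ``cds_start``/``cds_end`` delimit the coding sequence
    (stop codon included); they are ``None`` for non-coding types.
    """

    chromosome: str
    start: int
    end: int
    strand: str
    feature_type: str
    name: str
    cds_start: int | None = None
    cds_end: int | None = None
    is_leader_peptide: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.name}: start must be < end")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.name}: partial CDS interval")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"gene {self.name}: CDS not contained in gene interval")

    @property
    def three_prime(self) -> int:
        """0-based coordinate of the 3'-terminal base of the feature."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def stop_codon_boundary(self) -> int | None:
        """0-based coordinate of the last base of the stop codon (mRNA only)."""
        if self.cds_start is None:
            return None
        return self.cds_end - 1 if self.strand == "+" else self.cds_start


class TSSSet:
    """Deduplicated collection of transcription start sites."""

    def __init__(self, positions: Iterable[GenomicPosition]):
        self.positions: list[GenomicPosition] = sorted(
            set(positions), key=lambda p: (p.chromosome, p.strand, p.position)
        )
        self._by_strand: dict[tuple[str, str], np.ndarray] = {}
        for p in self.positions:
            self._by_strand.setdefault((p.chromosome, p.strand), []).append(p.position)  # type: ignore[arg-type]
        self._by_strand = {
            k: np.asarray(sorted(v), dtype=int) for k, v in self._by_strand.items()
        }

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)

    def on(self, chromosome: str, strand: str) -> np.ndarray:
        """Sorted TSS coordinates on one chromosome strand."""
        return self._by_strand.get((chromosome, strand), np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read the first record of a FASTA file as a GenomeSequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        log.warning("%s holds %d records; using the first", path, len(records))
    rec = records[0]
    return GenomeSequence(rec.id, str(rec.seq), circular)


def write_genome(genome: GenomeSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph signal tracks
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str | Path, genome: GenomeSequence, strand: str) -> SignalTrack:
    counts = np.zeros(len(genome), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from None
            if value < 0:
                raise BedGraphError(f"{path}:{lineno}: negative signal value {value}")
            if start < 0 or end > len(genome) or start >= end:
                raise BedGraphError(
                    f"{path}:{lineno}: interval [{start},{end}) outside genome "
                    f"of length {len(genome)}"
                )
            counts[start:end] = value
    return SignalTrack(genome.name, strand, counts)


def read_signal_track(
    forward_file: str | Path, reverse_file: str | Path, genome: GenomeSequence
) -> tuple[SignalTrack, SignalTrack]:
    """Read a strand-separated bedGraph pair into dense per-base arrays.

    Positions absent from a file are zero.
    """
    fwd = _read_bedgraph(forward_file, genome, "+")
    rev = _read_bedgraph(reverse_file, genome, "-")
    return fwd, rev


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    """Write a run-length-compressed bedGraph; zero runs are omitted."""
    counts = track.counts
    with open(path, "w") as fh:
        if len(counts) == 0:
            return
        # run-length boundaries
        change = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(counts)]])
        for s, e in zip(starts, ends):
            v = counts[s]
            if v == 0:
                continue
            fh.write(f"{track.chromosome}\t{s}\t{e}\t{_fmt(v)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def track_pair_paths(prefix: str | Path) -> tuple[Path, Path]:
    """Conventional (.fwd.bedgraph, .rev.bedgraph) path pair for a prefix."""
    prefix = str(prefix)
    return Path(prefix + ".fwd.bedgraph"), Path(prefix + ".rev.bedgraph")


def write_track_pair(fwd: SignalTrack, rev: SignalTrack, prefix: str | Path) -> tuple[Path, Path]:
    fp, rp = track_pair_paths(prefix)
    write_signal_track(fwd, fp)
    write_signal_track(rev, rp)
    return fp, rp


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_annotation(
    gff_path: str | Path, leader_names: Sequence[str] = LEADER_PEPTIDES
) -> list[GeneModel]:
    """Read mRNA/tRNA/rRNA/sRNA features (GFF3, 1-based inclusive) as GeneModels.

    CDS children attach coding coordinates to their parent mRNA; a CDS
    without a parent mRNA is skipped with a warning.  Unknown feature
    types are ignored (logged).
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    leaders = set(leader_names)
    genes: list[GeneModel] = []
    known_ids: set[str] = set()
    for ftype in GENE_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get("Name", [feat.id])[0]
            cds_start = cds_end = None
            if ftype == "mRNA":
                cds = list(db.children(feat, featuretype="CDS"))
                if cds:
                    cds_start = min(c.start for c in cds) - 1
                    cds_end = max(c.end for c in cds)
            genes.append(
                GeneModel(
                    chromosome=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    feature_type=ftype,
                    name=name,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    is_leader_peptide=name in leaders,
                )
            )
            known_ids.add(feat.id)
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            log.warning("CDS %s has no parent mRNA; skipped", cds.id)
    for feat in db.all_features():
        if feat.featuretype not in GENE_FEATURE_TYPES + ("CDS",):
            log.info("ignoring feature type %r (%s)", feat.featuretype, feat.id)
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end, g.strand))
    return genes


def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as GFF3 (1-based inclusive), CDS as mRNA children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = f"gene{i:04d}"
            fh.write(
                f"{g.chromosome}\tendcall\t{g.feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid};Name={g.name}\n"
            )
            if g.cds_start is not None:
                fh.write(
                    f"{g.chromosome}\tendcall\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                    f"{g.strand}\t0\tID={gid}.cds;Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# TSS / position tables
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> TSSSet:
    """Read a TSS TSV (header chrom/pos/strand, 1-based positions)."""
    return TSSSet(read_position_table(path))


def read_position_table(path: str | Path) -> list[GenomicPosition]:
    """Read a generic stranded position TSV (chrom<TAB>pos<TAB>strand, 1-based)."""
    out: list[GenomicPosition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom, pos_s, strand = fields[0], fields[1], fields[2]
            if lineno == 1 and not pos_s.lstrip("-").isdigit():
                continue  # header row
            if strand not in STRANDS:
                raise TableError(f"{path}:{lineno}: bad strand symbol {strand!r}")
            try:
                pos = int(pos_s)
            except ValueError:
                raise TableError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            out.append(GenomicPosition(chrom, pos - 1, strand))
    return out


def write_position_table(positions: Iterable[GenomicPosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\n")
        for p in positions:
            fh.write(f"{p.chromosome}\t{p.position + 1}\t{p.strand}\n")
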