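"""Synthetic bacterial 3'-end sequencing data with planted ground truth.

The generator emulates the data-generating biology behind stranded
single-nucleotide 3'-end count tracks: a random genome carrying
non-overlapping genes on both strands, each transcribed from a TSS
through a chain of planted terminators.  Term-seq replicate tracks
place sharp (+/-1 nt jitter) 3'-end read pileups at the planted sites
with replicate-correlated lognormal intensities over Poisson
background plus replicate-specific spurious peaks.  DirectRNA-seq
tracks (+/- bicyclomycin) are built transcript by transcript:
initiation at the TSS, termination at each planted site with
probability (1 - f) untreated or (1 - f_bcm) BCM-treated, and read 3'
ends deposited uniformly along each transcript's extent — so a
rho-type site (f < f_bcm) shows BCM-dependent readthrough while an
intrinsic site (f = f_bcm) does not.  Optionally a C-rich 150-nt
element (Rut-like) is planted on the sense strand upstream of each
rho site.

All randomness flows from a single numpy Generator seeded from the
config: the same config yields byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    GeneModel,
    GenomeSequence,
    SignalTrack,
    TSSSet,
    GenomicPosition,
    write_annotation,
    write_genome,
    write_position_table,
    write_track_pair,
)

log = logging.getLogger(__name__)

NUCS = np.frombuffer(b"ACGT", dtype="S1")

# sense-strand base probabilities inside a planted C-rich (Rut-like) element
C_RICH_PROBS = (0.225, 0.45, 0.10, 0.225)  # A, C, G, T


@dataclasses.dataclass
class TerminatorSpec:
    """One planted terminator.

    ``kind``: intrinsic (f == f_bcm), rho (f < f_bcm: BCM-sensitive), or
    processed (a processing site: a Term-seq 3' end with no
    transcription termination at all).
    ``location``: gene_end / utr5 / internal; ``offset`` is interpreted
    per location — nt downstream of the stop codon (gene_end), nt
    upstream of the start codon (utr5), or fraction into the CDS
    (internal).
    """

    kind: str
    location: str
    gene_index: int
    offset: float
    f: float = 0.05
    f_bcm: float = 0.05
    mean_end_reads: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("intrinsic", "rho", "processed"):
            raise ValueError(f"unknown terminator kind {self.kind!r}")
        if self.location not in ("gene_end", "utr5", "internal"):
            raise ValueError(f"unknown location {self.location!r}")
        if self.kind == "rho" and self.f > self.f_bcm:
            raise ValueError("rho terminator requires f <= f_bcm")
        if self.kind == "intrinsic" and self.f != self.f_bcm:
            raise ValueError("intrinsic terminator requires f == f_bcm")


def default_terminator_specs(n_genes: int = 20) -> list[TerminatorSpec]:
    """The default planting plan: 30 sites over 20 genes, 8 rho-type.

    Every gene gets a gene-end terminator (rho for genes 0, 5, 10, 15);
    genes 1, 4, 7, 11, 16 get an extra 5'UTR site (rho for 1 and 11);
    genes 2, 8, 13, 17, 19 get an extra ORF-internal site (rho for 2
    and 13).  Rho sites use f = 0.1, f_bcm = 0.8; intrinsic sites
    f = f_bcm = 0.05.
    """
    rho_gene_end = {0, 5, 10, 15}
    utr5_genes = {1: "rho", 4: "intrinsic", 7: "intrinsic", 11: "rho", 16: "intrinsic"}
    internal_genes = {2: "rho", 8: "intrinsic", 13: "rho", 17: "intrinsic", 19: "intrinsic"}
    specs: list[TerminatorSpec] = []
    for i in range(n_genes):
        kind = "rho" if i in rho_gene_end else "intrinsic"
        f, fb = (0.1, 0.8) if kind == "rho" else (0.05, 0.05)
        specs.append(TerminatorSpec(kind, "gene_end", i, 30, f, fb))
    for i, kind in utr5_genes.items():
        if i >= n_genes:
            continue
        f, fb = (0.1, 0.8) if kind == "rho" else (0.05, 0.05)
        specs.append(TerminatorSpec(kind, "utr5", i, 60, f, fb))
    for i, kind in internal_genes.items():
        if i >= n_genes:
            continue
        f, fb = (0.1, 0.8) if kind == "rho" else (0.05, 0.05)
        specs.append(TerminatorSpec(kind, "internal", i, 0.5, f, fb))
    return specs


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic scenario (defaults = the
    desk-scale scenario used throughout the test suite)."""

    genome_length: int = 100_000
    circular: bool = True
    n_genes: int = 20
    terminator_specs: list[TerminatorSpec] | None = None
    c_rich_upstream: bool = True
    background_rate: float = 0.01       # Term-seq/DirectRNA Poisson background per nt per strand
    replicate_correlation: float = 0.9  # shared fraction of lognormal site-intensity variance
    noise_peak_rate: float = 5e-5       # spurious replicate-specific peaks per nt per strand
    seed: int = 42
    # secondary knobs
    # DirectRNA reads are independent molecules drawn shallowly from a large
    # transcript population: per-molecule noise must not masquerade as
    # read-level signal, so the population is big and the per-molecule
    # sequencing rate small (their product, ~6 reads/nt of covered genome,
    # sets the effective depth)
    mean_transcripts_per_gene: float = 30000.0
    reads_per_nt: float = 2e-4          # sequenced 3' ends per nt of each molecule's extent
    site_log_sd: float = 0.5            # lognormal sd of Term-seq site intensities
    jitter_probs: tuple[float, float, float] = (0.15, 0.7, 0.15)  # -1 / 0 / +1 nt
    smear_prob: float = 0.0             # geometric 3'->5' exonuclease smear (off: sharp ends)
    smear_step: float = 0.2
    chromosome: str = "simchr"

    def __post_init__(self) -> None:
        if self.terminator_specs is None:
            self.terminator_specs = default_terminator_specs(self.n_genes)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["terminator_specs"] = [dataclasses.asdict(s) for s in self.terminator_specs]
        d["jitter_probs"] = list(self.jitter_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        specs = d.pop("terminator_specs", None)
        if specs is not None:
            d["terminator_specs"] = [TerminatorSpec(**s) for s in specs]
        if "jitter_probs" in d:
            d["jitter_probs"] = tuple(d["jitter_probs"])
        return cls(**d)


@dataclasses.dataclass
class _Gene:
    index: int
    strand: str
    tss: int            # genome coordinate of the TSS
    utr5_len: int
    cds_len: int
    runoff_t: int       # transcript coordinate where readthrough transcripts stop
    terminators: list[tuple[int, TerminatorSpec]]  # (transcript coord, spec), ordered

    def to_genome(self, t: int, L: int) -> int:
        g = self.tss + t if self.strand == "+" else self.tss - t
        return g % L

    @property
    def cds_interval(self) -> tuple[int, int]:
        # 0-based half-open genome coordinates of the CDS
        if self.strand == "+":
            return self.tss + self.utr5_len, self.tss + self.utr5_len + self.cds_len
        return (self.tss - self.utr5_len - self.cds_len + 1, self.tss - self.utr5_len + 1)


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    tss: TSSSet
    termseq: list[tuple[SignalTrack, SignalTrack]]
    direct_untreated: tuple[SignalTrack, SignalTrack]
    direct_bcm: tuple[SignalTrack, SignalTrack]
    truth: pd.DataFrame
    stats: dict
    paths: dict[str, Path] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

_RUNOFF = 900       # nt a readthrough transcript travels past the gene-end site
_GENE_MARGIN = 30   # gene-end terminator offset default scale


def _lay_out_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    specs_by_gene: dict[int, list[TerminatorSpec]] = {}
    for s in cfg.terminator_specs:
        specs_by_gene.setdefault(s.gene_index, []).append(s)
    genes: list[_Gene] = []
    cursor = int(rng.integers(500, 1500))
    for i in range(cfg.n_genes):
        u = int(rng.integers(90, 141))
        # CDS >= 930 nt keeps a 5'UTR site and the gene-end terminator
        # separated by more than w + 200: the windowed Rho statistic smears
        # up to w nt around a true site, and planted sites must not sit in
        # each other's ambiguity zone
        c = 3 * int(rng.integers(310, 601))
        strand = "+" if rng.random() < 0.5 else "-"
        total = u + c + _GENE_MARGIN + _RUNOFF
        if cursor + total > cfg.genome_length - 500:
            raise ValueError(
                f"gene placement infeasible at gene {i}: genome too small; "
                "reduce n_genes or increase genome_length"
            )
        tss = cursor if strand == "+" else cursor + total - 1
        terms: list[tuple[int, TerminatorSpec]] = []
        for spec in specs_by_gene.get(i, []):
            if spec.location == "gene_end":
                t = u + c - 1 + int(spec.offset)
            elif spec.location == "utr5":
                t = u - int(spec.offset)
                if t < 1:
                    raise ValueError(f"gene {i}: utr5 offset {spec.offset} exceeds UTR length {u}")
            else:  # internal
                # keep the site within w - 50 of the gene-end terminator so a
                # BCM-readthrough step never falls in the suppression-escape
                # band (w, w + 200] of another planted site
                t = u + max(int(spec.offset * c), c - 721)
            terms.append((t, spec))
        terms.sort(key=lambda x: x[0])
        genes.append(_Gene(i, strand, tss, u, c, u + c - 1 + _GENE_MARGIN + _RUNOFF, terms))
        cursor += total + int(rng.integers(1200, 1801))
    return genes


def _expected_class(spec: TerminatorSpec) -> str:
    return {"gene_end": "primary", "utr5": "orphan", "internal": "internal"}[spec.location]


# ---------------------------------------------------------------------------
# Main entry
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate the full synthetic dataset; optionally write it to disk.

    Deterministic for a fixed config (seed included): two runs produce
    byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    chrom = cfg.chromosome

    genes = _lay_out_genes(cfg, rng)

    # --- genome sequence -------------------------------------------------
    base_idx = rng.integers(0, 4, size=L)
    site_rows = []
    for g in genes:
        for t, spec in g.terminators:
            pos = g.to_genome(t, L)
            site_rows.append((g, t, spec, pos))
            if cfg.c_rich_upstream and spec.kind == "rho":
                elem = rng.choice(4, size=150, p=C_RICH_PROBS)
                for k in range(150):
                    # transcript coordinate t - 150 + k, on the sense strand
                    gp = g.to_genome(t - 150 + k, L)
                    if g.strand == "+":
                        base_idx[gp] = elem[k]
                    else:
                        base_idx[gp] = 3 - elem[k]  # complement: A<->T, C<->G
    sequence = NUCS[base_idx].tobytes().decode()
    genome = GenomeSequence(chrom, sequence, cfg.circular)

    # --- annotation and TSS ----------------------------------------------
    gene_models: list[GeneModel] = []
    for g in genes:
        cs, ce = g.cds_interval
        gene_models.append(
            GeneModel(chrom, cs, ce, g.strand, "mRNA", f"gene{g.index:03d}",
                      cds_start=cs, cds_end=ce)
        )
    tss = TSSSet(GenomicPosition(chrom, g.tss, g.strand) for g in genes)

    # --- Term-seq replicate tracks ---------------------------------------
    n_rep = 2
    termseq_arr = [
        {"+": np.zeros(L), "-": np.zeros(L)} for _ in range(n_rep)
    ]
    sigma = cfg.site_log_sd
    rho_c = cfg.replicate_correlation
    truth_records = []
    stats: dict = {"termseq_site_reads": 0, "termseq_background": 0,
                   "termseq_noise_peaks": 0, "termseq_noise_reads": 0,
                   "direct_reads": {}}
    jit = np.array([-1, 0, 1])
    for g, t, spec, pos in site_rows:
        lam0 = spec.mean_end_reads * max(1e-3, 1 - spec.f)
        z_site = rng.normal()
        rep_reads = []
        for r in range(n_rep):
            z_rep = rng.normal()
            lam = lam0 * np.exp(
                sigma * (np.sqrt(rho_c) * z_site + np.sqrt(1 - rho_c) * z_rep)
                - sigma**2 / 2
            )
            n = int(rng.poisson(lam))
            offs = rng.choice(jit, size=n, p=list(cfg.jitter_probs))
            if cfg.smear_prob > 0:
                smear = rng.random(n) < cfg.smear_prob
                shift = rng.geometric(cfg.smear_step, size=n)
                sgn = 1 if g.strand == "-" else -1  # upstream in genome coords
                offs = offs + np.where(smear, sgn * shift, 0)
            np.add.at(termseq_arr[r][g.strand], (pos + offs) % L, 1.0)
            rep_reads.append(n)
            stats["termseq_site_reads"] += n
        truth_records.append(
            {
                "chrom": chrom, "position": pos, "strand": g.strand,
                "type": spec.kind, "location": spec.location,
                "f": spec.f, "f_bcm": spec.f_bcm,
                "expected_class": _expected_class(spec),
                "gene": f"gene{g.index:03d}",
                "reads_rep1": rep_reads[0], "reads_rep2": rep_reads[1],
            }
        )
    for r in range(n_rep):
        for strand in ("+", "-"):
            bg = rng.poisson(cfg.background_rate, size=L).astype(float)
            termseq_arr[r][strand] += bg
            stats["termseq_background"] += int(bg.sum())
            n_noise = rng.poisson(cfg.noise_peak_rate * L)
            npos = rng.integers(0, L, size=n_noise)
            nreads = rng.poisson(15, size=n_noise) + 1
            np.add.at(termseq_arr[r][strand], npos, nreads.astype(float))
            stats["termseq_noise_peaks"] += int(n_noise)
            stats["termseq_noise_reads"] += int(nreads.sum())

    # --- DirectRNA-seq +/- BCM -------------------------------------------
    direct_arr = {
        sample: {"+": np.zeros(L), "-": np.zeros(L)} for sample in ("untreated", "bcm")
    }
    crossing: dict[tuple[str, int, str], list[int]] = {}
    for sample in ("untreated", "bcm"):
        total_reads = 0
        for g in genes:
            n_tx = int(rng.poisson(cfg.mean_transcripts_per_gene))
            remaining = n_tx
            stops: list[tuple[int, int]] = []  # (transcript stop coord, count)
            for t, spec in g.terminators:
                if remaining == 0:
                    break
                f_eff = spec.f if sample == "untreated" else spec.f_bcm
                if spec.kind == "processed":
                    f_eff = 1.0  # processing sites do not terminate transcription
                pos = g.to_genome(t, L)
                through = int(rng.binomial(remaining, f_eff))
                crossing.setdefault((sample, pos, g.strand), [0, 0])
                crossing[(sample, pos, g.strand)][0] += through
                crossing[(sample, pos, g.strand)][1] += remaining
                if remaining - through:
                    stops.append((t, remaining - through))
                remaining = through
            if remaining:
                stops.append((g.runoff_t, remaining))
            for t_stop, m in stops:
                n_reads = int(rng.poisson(m * cfg.reads_per_nt * (t_stop + 1)))
                ts = rng.integers(0, t_stop + 1, size=n_reads)
                gp = (g.tss + ts) % L if g.strand == "+" else (g.tss - ts) % L
                np.add.at(direct_arr[sample][g.strand], gp, 1.0)
                total_reads += n_reads
        for strand in ("+", "-"):
            bg = rng.poisson(cfg.background_rate, size=L).astype(float)
            direct_arr[sample][strand] += bg
            total_reads += int(bg.sum())
        stats["direct_reads"][sample] = total_reads

    truth = pd.DataFrame(truth_records)
    unt_thr, unt_reach, bcm_thr, bcm_reach = [], [], [], []
    for rec in truth_records:
        key_u = ("untreated", rec["position"], rec["strand"])
        key_b = ("bcm", rec["position"], rec["strand"])
        u = crossing.get(key_u, [0, 0])
        b = crossing.get(key_b, [0, 0])
        unt_thr.append(u[0]); unt_reach.append(u[1])
        bcm_thr.append(b[0]); bcm_reach.append(b[1])
    truth["unt_through"] = unt_thr
    truth["unt_reaching"] = unt_reach
    truth["bcm_through"] = bcm_thr
    truth["bcm_reaching"] = bcm_reach
    truth = truth.sort_values(["position", "strand"]).reset_index(drop=True)

    def _pair(arrs) -> tuple[SignalTrack, SignalTrack]:
        return (SignalTrack(chrom, "+", arrs["+"]), SignalTrack(chrom, "-", arrs["-"]))

    result = SimResult(
        config=cfg,
        genome=genome,
        genes=gene_models,
        tss=tss,
        termseq=[_pair(termseq_arr[r]) for r in range(n_rep)],
        direct_untreated=_pair(direct_arr["untreated"]),
        direct_bcm=_pair(direct_arr["bcm"]),
        truth=truth,
        stats=stats,
    )
    if outdir is not None:
        result.paths = _write(result, Path(outdir))
    return result


def _write(res: SimResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    write_genome(res.genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    write_annotation(res.genes, paths["annotation"])
    paths["tss"] = outdir / "tss.tsv"
    write_position_table(res.tss, paths["tss"])
    for r, pair in enumerate(res.termseq, start=1):
        f, rv = write_track_pair(*pair, outdir / f"termseq_rep{r}")
        paths[f"termseq_rep{r}_fwd"], paths[f"termseq_rep{r}_rev"] = f, rv
    for name, pair in (("untreated", res.direct_untreated), ("bcm", res.direct_bcm)):
        f, rv = write_track_pair(*pair, outdir / f"directrna_{name}")
        paths[f"direct_{name}_fwd"], paths[f"direct_{name}_rev"] = f, rv
    paths["truth"] = outdir / "ground_truth.tsv"
    truth = res.truth.copy()
    truth["position"] = truth["position"] + 1  # 1-based on disk
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "config.yaml"
    res.config.to_yaml(paths["config"])
    return paths
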