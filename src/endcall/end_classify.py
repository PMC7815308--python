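"""Positional classification of 3' ends and 5'UTR/ORF-internal selection.

A 3' end is labeled relative to annotated genes (mRNA ORF, tRNA, rRNA,
sRNA): *primary* on the same strand within 50 bp downstream of a gene's
3' end; *antisense* on the opposite strand within 50 bp of the gene's
start and end coordinates; *internal* on the same strand inside the
gene (excluding the gene's 3'-terminal coordinate); *orphan* when none
applies.  Labels are not exclusive — an end may be, e.g., primary for
one gene and internal to the next — except orphan, which stands alone.

The 5'UTR/ORF-internal selection extracts ends lying between 200 bp
upstream of a start codon and the stop codon, then removes ends that
likely belong to the upstream gene: an end whose first upstream
feature (TSS or mRNA stop codon, same strand) is a stop codon is
eliminated unless a TSS lies within 200 nt upstream or the stop codon
belongs to an annotated leader peptide; an end with a TSS 20 nt or
less upstream is eliminated as well.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

from .end_peaks import ConsensusEnd
from .genome_io import GeneModel, TSSSet

log = logging.getLogger(__name__)

CLASS_LABELS = ("primary", "antisense", "internal", "orphan")

KEEP = "keep"
ELIMINATE = "eliminate"

RULES = (
    "no_candidate_gene",
    "upstream_is_tss",
    "stop_rescued_by_tss_200",
    "stop_rescued_by_leader",
    "eliminated_upstream_stop",
    "eliminated_tss_within_20",
)


@dataclasses.dataclass
class EndAnnotation:
    end: ConsensusEnd
    labels: tuple[str, ...]
    genes: dict[str, list[str]]
    dominant: bool = False  # highest-scoring primary end of its gene


@dataclasses.dataclass
class UtrSelectionResult:
    end: ConsensusEnd
    decision: str  # keep / eliminate
    rule: str
    gene: str | None = None  # candidate gene whose 5'UTR/ORF window holds the end


def classify_end(
    end: ConsensusEnd, genes: Sequence[GeneModel], flank: int = 50
) -> EndAnnotation:
    """Attach all applicable positional class labels to one end."""
    labels: list[str] = []
    assoc: dict[str, list[str]] = {}
    pos = end.position
    for g in genes:
        if g.chromosome != end.chromosome:
            continue
        if end.strand == g.strand:
            # primary: within (g3, g3 + flank] strand-oriented
            if g.strand == "+":
                is_primary = g.end <= pos <= g.end - 1 + flank
            else:
                is_primary = g.start - flank <= pos <= g.start - 1
            if is_primary:
                labels.append("primary")
                assoc.setdefault("primary", []).append(g.name)
            # internal: inside the gene, excluding the 3'-terminal base
            if g.start <= pos < g.end and pos != g.three_prime:
                labels.append("internal")
                assoc.setdefault("internal", []).append(g.name)
        else:
            if g.start - flank <= pos < g.end + flank:
                labels.append("antisense")
                assoc.setdefault("antisense", []).append(g.name)
    if not labels:
        labels = ["orphan"]
    # dedupe, fixed order
    ordered = tuple(l for l in CLASS_LABELS if l in labels)
    return EndAnnotation(end=end, labels=ordered, genes=assoc)


def classify_ends(
    ends: Sequence[ConsensusEnd], genes: Sequence[GeneModel], flank: int = 50
) -> list[EndAnnotation]:
    """Classify many ends and flag, per gene, the dominant primary end
    (the highest-scoring 3' end within the gene's downstream window)."""
    anns = [classify_end(e, genes, flank) for e in ends]
    best: dict[str, EndAnnotation] = {}
    for ann in anns:
        for gname in ann.genes.get("primary", []):
            cur = best.get(gname)
            if cur is None or ann.end.score > cur.end.score:
                best[gname] = ann
    for ann in best.values():
        ann.dominant = True
    return anns


# ---------------------------------------------------------------------------
# 5'UTR / ORF-internal selection
# ---------------------------------------------------------------------------

def _upstream_distance(end_pos: int, feat_pos: int, strand: str) -> int:
    """Strand-oriented distance of a feature strictly upstream of the end
    (positive); <= 0 means at or downstream of the end."""
    return end_pos - feat_pos if strand == "+" else feat_pos - end_pos


def select_utr_internal(
    ends: Sequence[ConsensusEnd],
    genes: Sequence[GeneModel],
    tss: TSSSet,
    upstream_window: int = 200,
    tss_exclusion: int = 20,
) -> list[UtrSelectionResult]:
    """Apply the 5'UTR/ORF-internal selection algorithm to each end.

    Per end: (1) it is a candidate iff a same-strand mRNA exists whose
    strand-oriented window [start codon - upstream_window, stop codon]
    contains it; (2) the nearest strictly-upstream same-strand feature
    among TSSs and mRNA stop-codon 3' boundaries is found (equidistant
    ties go to the TSS); (3) a stop codon there eliminates the end
    unless a TSS lies <= upstream_window nt upstream or the stop
    belongs to a leader peptide; (4) independently, a TSS 1..
    ``tss_exclusion`` nt upstream eliminates the end.
    """
    mrnas = [g for g in genes if g.feature_type == "mRNA"]
    coding = []
    for g in mrnas:
        if g.cds_start is None:
            log.warning("mRNA %s has no CDS; skipped in UTR selection", g.name)
            continue
        coding.append(g)

    out: list[UtrSelectionResult] = []
    for end in ends:
        pos = end.position
        candidate_gene: str | None = None
        for g in coding:
            if g.chromosome != end.chromosome or g.strand != end.strand:
                continue
            if g.strand == "+":
                inside = g.cds_start - upstream_window <= pos < g.cds_end
            else:
                inside = g.cds_start <= pos < g.cds_end + upstream_window
            if inside:
                candidate_gene = g.name
                break
        if candidate_gene is None:
            out.append(UtrSelectionResult(end, ELIMINATE, "no_candidate_gene"))
            continue

        tss_dists = [
            d
            for t in tss.on(end.chromosome, end.strand)
            if (d := _upstream_distance(pos, int(t), end.strand)) >= 1
        ]
        nearest_tss = min(tss_dists) if tss_dists else None

        nearest_stop: tuple[int, GeneModel] | None = None
        for g in coding:
            if g.chromosome != end.chromosome or g.strand != end.strand:
                continue
            d = _upstream_distance(pos, g.stop_codon_boundary, end.strand)
            if d >= 1 and (nearest_stop is None or d < nearest_stop[0]):
                nearest_stop = (d, g)

        if nearest_tss is not None and nearest_tss <= tss_exclusion:
            out.append(
                UtrSelectionResult(end, ELIMINATE, "eliminated_tss_within_20", candidate_gene)
            )
            continue

        # first upstream feature; equidistant tie -> TSS wins (keep path)
        if nearest_stop is None or (nearest_tss is not None and nearest_tss <= nearest_stop[0]):
            out.append(UtrSelectionResult(end, KEEP, "upstream_is_tss", candidate_gene))
            continue

        stop_gene = nearest_stop[1]
        if nearest_tss is not None and nearest_tss <= upstream_window:
            out.append(
                UtrSelectionResult(end, KEEP, "stop_rescued_by_tss_200", candidate_gene)
            )
        elif stop_gene.is_leader_peptide:
            out.append(
                UtrSelectionResult(end, KEEP, "stop_rescued_by_leader", candidate_gene)
            )
        else:
            out.append(
                UtrSelectionResult(end, ELIMINATE, "eliminated_upstream_stop", candidate_gene)
            )
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_classification_tsv(
    annotations: Sequence[EndAnnotation],
    selections: Sequence[UtrSelectionResult] | None,
    path: str,
    rho_points=None,
) -> None:
    """TSV report: 1-based position, labels, genes, dominant flag,
    UTR-selection decision/rule, Rho score columns, and a column
    reserved for an externally supplied intrinsic-terminator score."""
    sel_by_end = {}
    if selections:
        sel_by_end = {id(s.end): s for s in selections}
    rho_by_pos = {}
    if rho_points:
        rho_by_pos = {
            (p.position.chromosome, p.position.position, p.position.strand): p
            for p in rho_points
        }
    with open(path, "w") as fh:
        fh.write(
            "chrom\tposition\tstrand\tlabels\tgenes\tdominant\tdecision\trule\t"
            "rho_score\tsignificance_score\tintrinsic_terminator_score\n"
        )
        for ann in annotations:
            e = ann.end
            sel = sel_by_end.get(id(e))
            rp = rho_by_pos.get((e.chromosome, e.position, e.strand))
            genes = ";".join(
                f"{lab}:{','.join(gs)}" for lab, gs in sorted(ann.genes.items())
            )
            fh.write(
                "\t".join(
                    [
                        e.chromosome,
                        str(e.position + 1),
                        e.strand,
                        ",".join(ann.labels),
                        genes or ".",
                        "1" if ann.dominant else "0",
                        sel.decision if sel else ".",
                        sel.rule if sel else ".",
                        f"{rp.rho_score:.4g}" if rp else ".",
                        f"{rp.p_value:.4g}" if rp else ".",
                        ".",  # intrinsic terminator score: externally supplied
                    ]
                )
                + "\n"
            )
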