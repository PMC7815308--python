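"""Hand-built classification / UTR-selection truth table.

One case per class or selection-rule branch, mirrored on both strands.
Coordinates are 0-based; each case carries its own minimal annotation
so the expected outcome can be verified by eye against the rules.
"""
from __future__ import annotations

import dataclasses

from endcall.end_peaks import ConsensusEnd
from endcall.genome_io import GeneModel, GenomicPosition, TSSSet

CHROM = "chr"


def _mrna(start, end, strand, name, leader=False):
    return GeneModel(CHROM, start, end, strand, "mRNA", name,
                     cds_start=start, cds_end=end, is_leader_peptide=leader)


def _end(pos, strand, score=10.0):
    return ConsensusEnd(CHROM, strand, pos, score, 0.01)


@dataclasses.dataclass
class Case:
    name: str
    end: ConsensusEnd
    genes: list
    tss: TSSSet
    expected_labels: tuple | None = None      # classify_end
    expected_decision: str | None = None      # select_utr_internal
    expected_rule: str | None = None


def _tss(*pos_strand):
    return TSSSet(GenomicPosition(CHROM, p, s) for p, s in pos_strand)


def classification_cases() -> list[Case]:
    """Positional class assignments, both strands."""
    fwd_gene = _mrna(1000, 2000, "+", "geneF")
    rev_gene = _mrna(3000, 4000, "-", "geneR")
    genes = [fwd_gene, rev_gene]
    empty = _tss()
    return [
        Case("primary_fwd", _end(2030, "+"), genes, empty, ("primary",)),
        Case("primary_rev", _end(2960, "-"), genes, empty, ("primary",)),
        Case("internal_fwd", _end(1500, "+"), genes, empty, ("internal",)),
        Case("internal_rev", _end(3500, "-"), genes, empty, ("internal",)),
        Case("antisense_fwd_gene", _end(1500, "-"), genes, empty, ("antisense",)),
        Case("antisense_rev_gene", _end(3500, "+"), genes, empty, ("antisense",)),
        Case("antisense_flank", _end(960, "-"), genes, empty, ("antisense",)),
        Case("orphan_fwd", _end(2500, "+"), genes, empty, ("orphan",)),
        Case("orphan_rev", _end(2500, "-"), genes, empty, ("orphan",)),
        # an end may satisfy two class predicates at once
        Case(
            "primary_and_internal",
            _end(2030, "+"),
            genes + [_mrna(2010, 2500, "+", "geneG")],
            empty,
            ("primary", "internal"),
        ),
        Case(
            "primary_and_antisense",
            _end(2030, "+"),
            genes + [_mrna(1900, 2500, "-", "geneH")],
            empty,
            ("primary", "antisense"),
        ),
    ]


def utr_selection_cases() -> list[Case]:
    """5'UTR / ORF-internal selection rules, both strands.

    Forward target gene: CDS [1000, 2000); candidate window [800, 2000).
    Reverse target gene: CDS [3000, 4000); candidate window [3000, 4200).
    """
    tf = _mrna(1000, 2000, "+", "targetF")
    tr = _mrna(3000, 4000, "-", "targetR")

    cases = []
    # --- no candidate gene
    cases.append(Case("no_candidate_fwd", _end(700, "+"), [tf], _tss((650, "+")),
                      None, "eliminate", "no_candidate_gene"))
    cases.append(Case("no_candidate_rev", _end(4300, "-"), [tr], _tss((4350, "-")),
                      None, "eliminate", "no_candidate_gene"))
    # --- first upstream feature is a TSS -> keep
    cases.append(Case("upstream_tss_fwd", _end(900, "+"),
                      [tf, _mrna(200, 500, "+", "upF")], _tss((850, "+")),
                      None, "keep", "upstream_is_tss"))
    cases.append(Case("upstream_tss_rev", _end(4100, "-"),
                      [tr, _mrna(4500, 4800, "-", "upR")], _tss((4150, "-")),
                      None, "keep", "upstream_is_tss"))
    # --- nearest is a stop codon but a TSS lies <= 200 nt upstream
    cases.append(Case("stop_tss200_fwd", _end(900, "+"),
                      [tf, _mrna(600, 871, "+", "upF")], _tss((720, "+")),
                      None, "keep", "stop_rescued_by_tss_200"))
    cases.append(Case("stop_tss200_rev", _end(4100, "-"),
                      [tr, _mrna(4129, 4400, "-", "upR")], _tss((4280, "-")),
                      None, "keep", "stop_rescued_by_tss_200"))
    # --- nearest is the stop codon of a leader peptide
    cases.append(Case("stop_leader_fwd", _end(900, "+"),
                      [tf, _mrna(600, 871, "+", "mgtL", leader=True)], _tss((400, "+")),
                      None, "keep", "stop_rescued_by_leader"))
    cases.append(Case("stop_leader_rev", _end(4100, "-"),
                      [tr, _mrna(4129, 4400, "-", "mgtL", leader=True)], _tss((4600, "-")),
                      None, "keep", "stop_rescued_by_leader"))
    # --- nearest is a plain stop codon, no rescue
    cases.append(Case("stop_elim_fwd", _end(900, "+"),
                      [tf, _mrna(300, 601, "+", "upF")], _tss((400, "+")),
                      None, "eliminate", "eliminated_upstream_stop"))
    cases.append(Case("stop_elim_rev", _end(4100, "-"),
                      [tr, _mrna(4399, 4700, "-", "upR")], _tss((4600, "-")),
                      None, "eliminate", "eliminated_upstream_stop"))
    # --- a TSS 20 nt or less upstream eliminates regardless
    cases.append(Case("tss20_fwd", _end(900, "+"),
                      [tf], _tss((885, "+")),
                      None, "eliminate", "eliminated_tss_within_20"))
    cases.append(Case("tss20_rev", _end(4100, "-"),
                      [tr], _tss((4115, "-")),
                      None, "eliminate", "eliminated_tss_within_20"))
    return cases
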