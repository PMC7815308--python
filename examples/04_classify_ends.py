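"""Classify 3' ends against the annotation and select 5'UTR/ORF-internal ends.

Positional classes: primary (within 50 bp downstream of a gene's 3'
end, same strand), antisense (opposite strand within 50 bp of the
gene), internal (inside the gene), orphan (none). The UTR selection
then keeps ends between 200 bp upstream of a start codon and the stop
codon, removing those that belong to the upstream gene.
"""
from collections import Counter

from endcall import SimConfig, call_ends, classify_ends, select_utr_internal, simulate

res = simulate(SimConfig())
ends, _ = call_ends(res.termseq)
annotations = classify_ends(ends, res.genes)
selections = select_utr_internal(ends, res.genes, res.tss)

label_counts = Counter(l for a in annotations for l in a.labels)
print("class distribution:", dict(label_counts))
rule_counts = Counter(s.rule for s in selections)
print("UTR-selection rules:", dict(rule_counts))
kept = [s for s in selections if s.decision == "keep"]
print(f"\n5'UTR / ORF-internal candidate ends kept: {len(kept)}")
for s in kept[:5]:
    print(f"  {s.end.position + 1}{s.end.strand}  gene={s.gene}  rule={s.rule}")
print("\n'primary' ends mark terminators of their upstream gene; 'orphan' "
      "and 'internal' kept ends are candidates for premature termination "
      "within 5' UTRs or coding sequences.")
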