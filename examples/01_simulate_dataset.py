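"""Generate a synthetic Term-seq / DirectRNA-seq dataset with planted truth.

Builds the default desk-scale scenario — a 100-kb circular genome with
20 genes and 30 planted transcription terminators (8 Rho-dependent) —
and writes every file the pipeline consumes: genome FASTA, GFF3
annotation, TSS table, two Term-seq replicate bedGraph pairs, and
untreated/+BCM DirectRNA bedGraph pairs.
"""
from endcall import SimConfig, simulate

res = simulate(SimConfig(), outdir="scratch/example_sim")

print(f"genome: {len(res.genome):,} nt ({res.genome.name})")
print(f"genes: {len(res.genes)}, TSSs: {len(res.tss)}")
print(f"planted 3' ends: {len(res.truth)} "
      f"({(res.truth.type == 'rho').sum()} rho-type)")
print(res.truth[["position", "strand", "type", "location", "f", "f_bcm"]].head())
print("\nfiles written:")
for name, path in sorted(res.paths.items()):
    print(f"  {name}: {path}")
print("\nEach truth row is one planted terminator: 'f' is the fraction of "
      "transcripts reading through it untreated, 'f_bcm' after Rho inhibition; "
      "they differ only at rho-type sites.")
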