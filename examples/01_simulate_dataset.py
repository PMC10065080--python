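"""Generate a small synthetic rescue-assay dataset and inspect its design.

The generator emulates a four-condition genetic-rescue experiment
(wild type + empty vector, enhancer-knockout + empty, knockout + wild-type
factor, knockout + pathogenic variant; 4 replicates each): NB counts with
designed per-gene regulatory categories, TSS-linked accessibility peaks,
and peak DNA with planted GATA/E-box/ETS/EBF motifs.
"""

from gatarescue import simulate

cfg = simulate.SimConfig(n_genes=2000, seed=1)
annotation = simulate.simulate_annotation(cfg)
truth = simulate.simulate_truth(cfg)
counts = simulate.simulate_counts(cfg, truth, annotation)
peaks, sequences, truth = simulate.simulate_peaks_and_sequences(cfg, truth, annotation)

print("true regulatory classes (counts of genes):")
print(truth.genes["category"].value_counts().to_string())
print(f"\ncount table: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"median library {int(counts.sum().median()):,} reads")
print(f"peaks: {len(peaks)}; peak sequences: {len(sequences)}; "
      f"planted motif instances: {len(truth.motifs)}")
print("\nA 'shared' gene is regulated by both the wild-type factor and the "
      "variant; 'ectopic' genes respond only to the variant; the truth table "
      "records each gene's true log2 fold change per contrast.")
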