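"""Scan peak sequences for GATA-family motif grammars.

Single motifs use IUPAC consensus scanning on both strands (WGATAR: W=A/T,
R=A/G). Composite elements are an E-box (CANNTG) and a WGATAR separated by a
6-14 bp spacer on the same strand; double-WGATAR elements are two
non-overlapping WGATARs with at most a 5 bp gap.
"""

from gatarescue import motifs, simulate

# a constructed enhancer-like sequence: E-box, 8 bp spacer, GATA site,
# then a double GATA a bit further on
seq = "CAGCTG" + "GTCGTCGA" + "TGATAA" + "CCGC" + "AGATAAG" + "TGATAA"
print("single WGATAR hits:", [(h.start, h.strand) for h in motifs.scan_iupac(seq, motifs.WGATAR)])
print("composite elements:", [(h.left_start, h.right_start, h.spacer)
                              for h in motifs.scan_composite(seq)])
print("double WGATAR:", [(h.left_start, h.right_start, h.spacer)
                         for h in motifs.scan_double(seq)])

# class-level enrichment on synthetic peak sequences
cfg = simulate.SimConfig(n_genes=3000, seed=4)
annotation = simulate.simulate_annotation(cfg)
truth = simulate.simulate_truth(cfg)
_, sequences, truth = simulate.simulate_peaks_and_sequences(cfg, truth, annotation)
shifted = truth.peaks[(truth.peaks["shift_rescue"] != 0)]
by_class = {
    side: {pid: sequences[pid] for pid in grp["peak_id"]}
    for side, grp in shifted.groupby("side") if side != "neutral"
}
stats_df, tests_df = motifs.peak_set_motif_stats(by_class)
print("\nfraction of peaks with at least one hit, by class:")
print(stats_df.pivot(index="motif", columns="class", values="frac_with_hit")
      .round(3).to_string())
wg = tests_df[tests_df["motif"] == "WGATAR"].iloc[0]
print(f"\nWGATAR activated vs repressed: proportion test p = {wg['proportion_p']:.2e}")
print("The GATA consensus is enriched in accessibility peaks at "
      "factor-activated loci relative to repressed loci.")
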