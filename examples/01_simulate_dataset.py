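"""Generate a small two-tissue synthetic dataset and look at its truth.

The generator plants mesoderm (ME) and dorsal-ectoderm (DEE) enhancers
whose flanking H3K27ac is 3-fold higher in the matching tissue, plus a
large pool of non-differential candidates.
"""
from enhancerdiff.synthetic import small_test_config, generate

ds = generate(small_test_config(seed=0))

print(f"genome: {sum(ds.chrom_sizes.values()):,} bp, {len(ds.genes)} genes")
print(ds.truth["class"].value_counts().to_string())
print(f"candidate peaks emitted: {len(ds.candidate_peaks)}")
reads = ds.simulate_chip_sample("H3K27ac", "mesoderm", 1)
print(f"one H3K27ac replicate: {len(reads):,} aligned reads")
planted = (ds.truth["ME_motif_pos"] >= 0).sum()
print(f"ME motif planted in {planted} candidate cores")
# The class counts are the ground truth every later stage is scored
# against; reads follow the bimodal-flank geometry around each summit.
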