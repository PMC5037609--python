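"""Scan PWMs over enhancer cores and test motif enrichment.

Motif hits come from a log-likelihood-ratio scan against a genome-wide
background model, with exact DP hit p-values; enrichment compares motif
presence in differential vs non-differential cores.
"""
from enhancerdiff import motifs as mt
from enhancerdiff.synthetic import small_test_config, generate, core_sequences

ds = generate(small_test_config(seed=0))
truth = ds.truth
test = truth[truth["class"] != "nondiff"]
ctrl = truth[truth["class"] == "nondiff"]

bg = mt.build_background(list(ds.genome.values()), order=0)
seqs = {}
for label, grp in (("enh", test), ("ctl", ctrl)):
    for i, s in enumerate(core_sequences(ds, grp["summit"].tolist())):
        seqs[f"{label}{i}"] = s
hits = mt.scan_regions(ds.motifs, seqs, bg, p_threshold=1e-4)
pres = mt.presence_matrix(hits, list(seqs))
res = mt.enrichment_test(
    pres.loc[[k for k in seqs if k.startswith("enh")]],
    pres.loc[[k for k in seqs if k.startswith("ctl")]],
)
enriched = sorted((r for r in res if r.direction == "enriched"), key=lambda r: r.p)
for r in enriched[:4]:
    print(f"{r.motif_id:10s} {r.test_with}/{r.test_total} vs "
          f"{r.control_with}/{r.control_total}  p={r.p:.2e} q={r.q:.2e}")
# The planted class motifs lead this table by p-value; decoys hover near
# the null. At this small demo scale (40 test cores) significance is
# modest — the default 5-Mb conditions separate them by many orders of
# magnitude.
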