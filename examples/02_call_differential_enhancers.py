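"""Call tissue-specific enhancers by differential H3K27ac.

Counts H3K27ac fragments in 1-kb windows around candidate summits,
fits the NB model, and calls ME/DEE at q < 0.01; then scores the calls
against the planted truth.
"""
from enhancerdiff.pipeline import Pipeline, inputs_from_synthetic, recovery_metrics
from enhancerdiff.synthetic import small_test_config, generate

ds = generate(small_test_config(seed=0))
pipe = Pipeline(inputs_from_synthetic(ds, with_tf_tracks=False))
pipe.run(["candidates", "counts", "differential"])

res = pipe.results["differential"]
print(res["call"].value_counts().to_string())
m = recovery_metrics(ds, pipe.results["candidates"], res)
print(f"sensitivity {m['sensitivity']:.2f}  FDR {m['fdr']:.3f} "
      f"({int(m['n_called'])} calls / {int(m['n_true'])} planted)")
# Sensitivity is the fraction of planted differential enhancers called
# with the correct tissue; FDR the fraction of calls that are wrong.
top = res[res["q"] < 0.01].sort_values("q").head(3)
print(top[["baseMean", "log2fc", "q", "call"]].round(3).to_string())
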