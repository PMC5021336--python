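"""Generate a synthetic methylome and summarise it the way a WGBS study would.

Builds a 100 kb genome, draws bisulfite counts at every cytosine (depth 30,
0.5% conversion failure), then prints the weighted methylation percentage
per sequence context and the conversion rate estimated from a simulated
chloroplast.  The context percentages should sit near the generator
baselines (CG 28%, CHG 10%, CHH 3%) and the conversion rate near
100 * (1 - 0.005) = 99.5%.
"""

import methylite as ml

cfg = ml.SimConfig(seed=1, chrom_lengths={"Chr1": 100_000}, depth=30.0,
                   conversion_failure=0.005)
reference = ml.generate_reference(cfg)
truth, _ = ml.plant_dmrs(reference, n_dmrs=0, seed=2)
sample = ml.simulate_counts(truth, cfg, seed=3, sample_id="wt_shoot")

summary = ml.context_summary(sample)
print("weighted methylation per context (percent of pooled reads):")
for context, row in summary.iterrows():
    print(f"  {context:>5}: {row['percent']:6.2f}%  ({row['n_sites']} sites with >=4x)")

chloroplast = ml.simulate_chloroplast(20_000, cfg, seed=4)
rate = ml.conversion_rate(chloroplast, "ChrC")
print(f"bisulfite conversion rate from chloroplast: {rate:.2f}%")
print("(every methylated call on the unmethylated chloroplast is a "
      "conversion failure, so this estimates 100*(1-f))")
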