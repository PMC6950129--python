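"""Monte-Carlo uncertainty intervals for a real case-study sample.

Propagates the instrument's measurement error (multiplicative ratio
noise, relative s.d. 0.05%) through the four-source solve for soil
sample N-1000 and prints 95% percentile intervals per source.
"""

import pbsource as pb

sources, samples = pb.load_case_study_inputs()
sample = next(s for s in samples if s.id == "N-1000")

mc = pb.monte_carlo_uncertainty(
    sources, sample, pb.NoiseModel(relative_sd=0.0005, seed=1), replicates=1000
)

print(f"sample {sample.id}: central estimate with 95% intervals")
for name, c, lo, hi in zip(mc.source_names, mc.central, mc.lower, mc.upper):
    print(f"  {name:30s} {100 * c:8.2f}%  [{100 * lo:7.2f}%, {100 * hi:7.2f}%]")
print(
    "\nThe central estimate is the apportionment of the measured ratios; "
    "the intervals show how far plausible measurement error alone can move "
    "each contribution rate."
)
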