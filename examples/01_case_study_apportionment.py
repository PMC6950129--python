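"""Apportion the bundled Guanzhong soil samples among four end-members.

Loads the bundled measurement table (32 soil samples around a lead and
zinc smelter plus four end-member fingerprints), solves the exactly
determined four-source mass-balance system for every sample, and prints
the contribution rates.  Negative rates flag samples influenced by
sources beyond the four modeled ones.
"""

import pbsource as pb

report = pb.case_study()

print(f"{'sample':10s} " + " ".join(f"{n[:12]:>12s}" for n in report.batch.source_names))
for result in report.batch.results:
    flag = "  <- negative fraction" if result.has_negative else ""
    cells = " ".join(f"{100 * f:11.2f}%" for f in result.fractions)
    print(f"{result.sample_id:10s} {cells}{flag}")

mean = report.batch.mean_valid_fractions
print(
    f"\nmean over {len(report.batch.valid_results)} valid samples: "
    + ", ".join(
        f"{n}: {100 * f:.2f}%" for n, f in zip(report.batch.source_names, mean)
    )
)
print(
    "Each row gives the share of that sample's total lead attributed to "
    "each end-member; rows sum to 100%."
)
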