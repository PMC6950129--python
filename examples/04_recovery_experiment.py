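"""Parameter recovery under instrument noise.

Simulates the full measurement chain: draw true fractions on the
simplex, mix three end-members, add multiplicative ratio noise at the
two endpoints of the instrument's quoted precision range (relative s.d.
0.02% and 0.09%), and re-estimate.  The table shows how measurement
error propagates into the recovered fractions.
"""

import pbsource as pb

for sd in (0.0, 0.0002, 0.0009):
    report = pb.recovery_experiment(
        n=3, noise=pb.NoiseModel(relative_sd=sd), replicates=300, seed=42
    )
    rmse = ", ".join(f"{v:.4f}" for v in report.rmse)
    print(
        f"relative sd {sd:.4%}: per-source RMSE = [{rmse}], "
        f"max |error| = {report.max_abs_error:.2e}"
    )

print(
    "\nZero noise recovers the fractions to solver precision.  At the "
    "instrument's error level the fraction RMSE reaches several percentage "
    "points: end-member abundance vectors differ from each other by only a "
    "few percent, so small ratio errors are strongly amplified in the "
    "inversion."
)
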