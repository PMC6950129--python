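"""Why ratio balance is not mass balance.

Mixes three synthetic end-members with known fractions by the physical
(mass-balance) forward model, then apportions the mixture with both the
mass-balance solver and the classical three-source ratio-balance model.
The mass-balance solver recovers the truth to machine precision; the
ratio-balance fractions deviate because isotope ratios do not mix
linearly under mass conservation.
"""

import pbsource as pb

sources = pb.generate_sources(3, seed=11)
truth = [0.4, 0.4, 0.2]
comparison = pb.compare_models(sources, truth)

print(f"{'source':8s} {'true':>8s} {'mass-bal':>10s} {'ratio-bal':>10s} {'dev':>8s}")
for i, name in enumerate(sources.names):
    print(
        f"{name:8s} {100 * truth[i]:7.2f}% "
        f"{100 * comparison.mass_balance.fractions[i]:9.2f}% "
        f"{100 * comparison.gobeil_fractions[i]:9.2f}% "
        f"{100 * comparison.deviation[i]:+7.2f}pp"
    )
print(f"\nmax |deviation| = {100 * comparison.max_abs_deviation:.2f} pp")
print(
    "The deviation is systematic, not numerical: it grows with the spread "
    "of the sources' 206Pb/207Pb abundances (see docs/methods.md)."
)
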