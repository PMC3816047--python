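"""Evaluate a fixed-ratio drug combination against the additive null.

In a fixed-ratio (ray) design both drugs are dosed at complementary
fractions of their own IC50. Under Loewe additivity every such mixture
is one IC50-equivalent, so 50% inhibition is expected; observations
above the null indicate synergy.
"""

from camvessel import MixtureDesign, additive_null, evaluate_mixture

# observed in-vivo inhibitions along the artesunate:captopril ray,
# including the 83% peak at the 40:60 mixture
design = MixtureDesign(
    ratios=((1.0, 0.0), (0.6, 0.4), (0.5, 0.5), (0.4, 0.6), (0.0, 1.0)),
    observed_inhibition_pct=(50.0, 71.0, 76.0, 83.0, 51.0),
)

result = evaluate_mixture(design, tolerance_pct=5.0)
print(f"additive null: {additive_null((0.5, 0.5)):.0f}% inhibition at every ratio")
print(f"{'f_art':>6} {'f_cap':>6} {'observed':>9} {'delta':>7}  verdict")
for v in result.verdicts:
    print(f"{v.ratio[0]:6.1f} {v.ratio[1]:6.1f} {v.observed_pct:8.0f}% {v.delta_pct:+6.0f}%  {v.verdict}")
print()
print(f"strongest interaction at ratio {result.max_delta_ratio}: "
      f"{result.max_delta_pct:+.0f} points above the additive expectation")
print("Deltas beyond the +/-5-point tolerance are called synergistic or")
print("antagonistic; single drugs at their own IC50 sit on the null.")
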