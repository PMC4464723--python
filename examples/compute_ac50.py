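"""The AC50 threshold-sensitivity statistic on a hand-checkable curve.

AC50 = the largest log10 dilution factor at which the piecewise-linear
response still reaches half the stimulation-control activation.
"""

from batkit import DoseResponseCurve, PEANUT_SERIES, ac50, ac50_to_concentration

# positive control at 60 % -> threshold T = 30 %; the response crosses 30 %
# between d=4 (40 %) and d=5 (20 %): AC50 = 4 + (40-30)/(40-20) = 4.5
curve = DoseResponseCurve(
    subject_id="demo", allergen="peanut",
    d=[2, 3, 4, 5, 6], activation=[55, 48, 40, 20, 5],
    positive_control_activation=60.0,
)
result = ac50(curve)
print(f"AC50 = {result.value:.2f} log10 dilution units ({result.status.value})")
print(f"threshold used: {result.threshold_used:.0f} % CD63+")

conc = ac50_to_concentration(result.value, PEANUT_SERIES)
print("\nequivalent peanut protein concentrations (ng/ml):")
for convention, ng_ml in conc.items():
    print(f"  {convention:28s} {ng_ml:10.2f}")
# Higher AC50 = reactivity at lower allergen concentration = more sensitive
# subject. The concentration readings depend on the dilution-coordinate
# convention, so all are reported.
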