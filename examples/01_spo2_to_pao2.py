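"""Convert pulse-oximetry readings to estimated arterial oxygen tension.

Two estimators are available: a piecewise-linear bedside rule (4 mmHg per
percentage point down to 90%, then 1.5 mmHg per point to 80%, then half the
SpO2 value) and a Hill-equation inversion of the oxyhemoglobin dissociation
curve. Both take SpO2 in percent and return PaO2 in mmHg.
"""

from sofa_oxi import estimate_pao2_hill, estimate_pao2_piecewise

print(f"{'SpO2 (%)':>9} {'piecewise (mmHg)':>17} {'Hill (mmHg)':>12}")
for spo2 in (100, 96, 93, 90, 85, 80, 75):
    print(
        f"{spo2:>9} {estimate_pao2_piecewise(spo2):>17.1f} "
        f"{estimate_pao2_hill(spo2):>12.1f}"
    )

# The piecewise rule pins 90% -> 60 mmHg and 80% -> 45 mmHg exactly; the
# Hill inversion follows the sigmoid dissociation curve, staying finite
# (~146 mmHg) even at 100% saturation.
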