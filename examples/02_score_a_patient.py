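"""Score one patient's respiratory SOFA under all seven strategies.

The patient below is hypoxemic on 2 L/min nasal cannula and never had an
arterial blood gas drawn: PaO2 is missing, which is exactly the situation
the estimation methods address.
"""

from sofa_oxi import (
    Method,
    OxygenDelivery,
    OxygenDevice,
    PatientRecord,
    respiratory_sofa,
    total_sofa,
)

patient = PatientRecord(
    spo2=89.0,
    pao2=None,  # no blood gas drawn
    delivery=OxygenDelivery(OxygenDevice.NASAL_CANNULA, flow_lpm=2),
    platelets=140.0,
    bilirubin=1.4,
    map_mmhg=68.0,
    gcs=14,
    creatinine=1.3,
)

print("method  respiratory  total")
for method in Method:
    breakdown = total_sofa(patient, method)
    print(f"{method.value:>6}  {breakdown.respiratory:>11}  {breakdown.total:>5}")

# The conventional method imputes a normal PaO2 (100 mmHg) and scores the
# PF ratio, underestimating this patient's hypoxemia; the SpO2-based
# methods recover it from the oximetry reading (89% on oxygen).
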