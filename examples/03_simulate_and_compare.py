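"""Simulate an ED infection cohort and compare all seven scoring methods.

Generates a synthetic cohort (latent severity drives gas exchange, oxygen
therapy, PaO2 missingness and mortality), scores every patient under the
seven respiratory-SOFA strategies, and tabulates AUROC for in-hospital
mortality with paired DeLong tests against the conventional method.
"""

from sofa_oxi import compare_methods, default_config, generate_cohort

cohort = generate_cohort(default_config(n=15000))
records = cohort.records

mortality = sum(r.died_in_hospital for r in records) / len(records)
missing = sum(r.pao2 is None for r in records) / len(records)
print(f"n={len(records)}, mortality {mortality:.1%}, missing PaO2 {missing:.1%}\n")

report = compare_methods(records)
for score_type in ("respiratory", "total"):
    rows = report[report["score_type"] == score_type]
    print(f"{score_type} SOFA score, AUROC for in-hospital mortality:")
    for _, r in rows.iterrows():
        p = "" if r.method == "CONV" else f"  p vs CONV = {r.p_vs_conventional:.3f}"
        print(
            f"  {r.method:>4}: {r.auc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}){p}"
        )
    print()

# Methods A, C, E replace ALL PaO2 values with SpO2-based information and
# match or exceed the conventional method's discrimination — the missing
# blood gases are not missing at random, and a worst-in-24h SpO2 carries
# information a single imputed-normal PaO2 cannot.
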