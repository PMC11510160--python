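"""Baseline 4β-OHC across genotype and disease virtual populations.

CYP3A4*22 carriers express less hepatic CYP3A4 (retrograde-derived means of
100.86 and 51.27 pmol/mg vs 137 for wild type), and rheumatoid arthritis
suppresses CYP3A4 to 82.07 pmol/mg; because 4β-OHC formation is essentially
proportional to CYP3A activity, population mean baselines shift accordingly.
"""

from oxypbpk import default_config, make_template, run_trial_set
from oxypbpk.trials import TrialDesign

config = default_config()

populations = {
    "wild type (*1/*1)": make_template("caucasian_healthy", genotype="*1/*1"),
    "CYP3A4*1/*22": make_template("caucasian_healthy", genotype="*1/*22"),
    "CYP3A4*22/*22": make_template("caucasian_healthy", genotype="*22/*22"),
    "rheumatoid arthritis": make_template("caucasian_healthy", disease="RA"),
}

means = {}
for label, template in populations.items():
    design = TrialDesign(template=template, n_trials=10, n_subjects_per_trial=20, seed=2024)
    summary = run_trial_set(design, config)
    means[label] = summary.mean_css_metabolite_ng_ml
    print(
        f"{label:22s} CYP3A4 mean {template.abundances['CYP3A4'].mean:7.2f} pmol/mg -> "
        f"4b-OHC {summary.mean_css_metabolite_ng_ml:5.1f} ng/mL "
        f"(P5-P95 {summary.p5_css_metabolite_ng_ml:.1f}-{summary.p95_css_metabolite_ng_ml:.1f})"
    )

wt = means["wild type (*1/*1)"]
print()
for label in ("CYP3A4*1/*22", "CYP3A4*22/*22", "rheumatoid arthritis"):
    print(f"{label:22s} {means[label] / wt:.2f}-fold of wild type")
print("\nThe fold-ratios track the CYP3A4 abundance ratios because the")
print("metabolite's formation is linear in CYP3A activity at baseline.")
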