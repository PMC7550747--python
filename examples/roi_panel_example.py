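"""Compare one synthetic patient's ROI panel against age-matched controls.

Builds a cohort of 20 controls plus one patient whose left caudate volume is
implanted 4 control SDs below normal, then runs the full single-case panel:
age-window matching, TIV normalization, z-score + Crawford-Howell t per
biomarker, and Benjamini-Hochberg FDR across the panel.
"""

from casemap import SimulationConfig, compare_roi_panel, simulate_cohort

key = ("Left-Caudate", "volume_mm3")
config = SimulationConfig(
    seed=7, n_controls=20, n_patients=1, age_range=(45.0, 55.0),
    implants_roi={("pat000", key): -4.0},
)
metas, records = simulate_cohort(config)
panel = list(config.roi_panel)[:12]
subject = [r for r in records if r.subject_id == "pat000"]
controls = [r for r in records if r.subject_id.startswith("ctrl")]
age = next(m.age for m in metas if m.subject_id == "pat000")

results = compare_roi_panel(subject, controls, metas, panel, age)

print(f"patient pat000, age {age:.1f}, vs {results[0].n} age-matched controls")
print(f"{'biomarker':<38}{'z':>8}{'t':>8}{'p':>9}{'p-adj':>9}  flag")
for r in results:
    name = f"{r.biomarker_key[0]} ({r.biomarker_key[1]})"
    flag = r.direction.upper() if r.significant else ""
    print(f"{name:<38}{r.z:>8.2f}{r.t:>8.2f}{r.p:>9.4f}{r.p_adj:>9.4f}  {flag}")
print("\nA significant BELOW flag means the patient's value falls outside the")
print("normative range after correcting for the number of regions tested.")
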