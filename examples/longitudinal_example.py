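"""Annualized atrophy rates, group comparison, and disease-burden correlation.

Simulates 2-scan follow-ups (18 months apart) for 12 patients and 12
controls, estimates per-subject annualized rates, compares the groups with a
pooled t-test, and correlates a synthetic affected-voxel count with the
Huntington's disease burden score Age x (CAG - 35.5).
"""

import numpy as np

from casemap import (
    SimulationConfig,
    annualized_rate,
    disease_burden,
    group_rate_test,
    partial_correlation,
    pearson_r,
    simulate_cohort,
    simulate_longitudinal,
)

rng = np.random.default_rng(9)
config = SimulationConfig(seed=9, n_controls=12, n_patients=12)
metas, _ = simulate_cohort(config)

true_rates = {}
for m in metas:
    base = -150.0 if m.group == "patient" else -20.0
    true_rates[m.subject_id] = base + float(rng.normal(0, 15))

series = simulate_longitudinal(config, true_rates, n_sessions=2,
                               interval_months=18.0, noise_sd=20.0)
rates = {s.subject_id: annualized_rate(s) for s in series}
pat = [rates[m.subject_id] for m in metas if m.group == "patient"]
ctl = [rates[m.subject_id] for m in metas if m.group == "control"]
t, df, p = group_rate_test(pat, ctl)
print(f"mean annualized rate: patients {np.mean(pat):.1f}, controls {np.mean(ctl):.1f} mm^3/yr")
print(f"pooled two-sample t({df}) = {t:.2f}, two-tailed p = {p:.2g}")

# affected-voxel counts rising with disease burden, plus independent noise
patients = [m for m in metas if m.group == "patient"]
burden = np.array([disease_burden(m.age, m.cag) for m in patients])
voxels = 50.0 + 2.0 * burden + rng.normal(0, 150, len(patients))
scores = -0.01 * voxels + rng.normal(0, 2, len(patients))
r, p = pearson_r(voxels, burden)
print(f"\naffected voxels vs disease burden: r = {r:.2f}, p = {p:.2g}")
r_z, p_z = partial_correlation(voxels, scores, burden)
print(f"voxels vs clinical score controlling for burden: r = {r_z:.2f}, p = {p_z:.2g}")
print("\nA negative rate is tissue loss per year; the burden correlation links")
print("voxel-level atrophy to the CAG/age progression index.")
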