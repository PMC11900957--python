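"""Method-agreement statistics on a simulated pre/post surgery cohort.

Simulates 40 eyes with mild-to-severe ptosis, "operates" on them by
reducing droop to ~0.5 mm, measures every image twice with the pipeline
(the automated method) and once from the ground-truth masks' pixel
counts (standing in for a careful manual reading), then assembles the
full agreement/outcome report: pre/post means, paired t, repeated-run
and cross-method ICC, Bland–Altman limits, and severity-stratified
improvement rates.
"""

import numpy as np
import pandas as pd

from cermetrics import cohort_report, generate_eye, measure_eye
from cermetrics.synthetic import spec_for_droop

rng = np.random.default_rng(0)
rows = []
for i in range(40):
    droop_pre = rng.uniform(0.5, 8.0)
    droop_post = rng.uniform(0.0, 1.0)  # surgical correction
    for timepoint, droop in (("pre", droop_pre), ("post", droop_post)):
        image, truth = generate_eye(spec_for_droop(droop))
        measured = measure_eye(image).cer_percent
        for method, cer in (("ai", measured), ("manual", truth.true_cer_percent)):
            rows.append((f"eye{i:02d}", timepoint, method, cer, droop_pre))

long_df = pd.DataFrame(rows, columns=["eye_id", "timepoint", "method", "cer", "droop_mm"])
report = cohort_report(long_df, severity_method="ai")

pd.set_option("display.float_format", lambda v: f"{v:.3f}")
print("=== pre/post summary per method (paired t) ===")
print(report.summary.to_string(index=False))
print("\n=== cross-method agreement (ICC, Bland–Altman) ===")
print(report.agreement.to_string(index=False))
print("\n=== severity-stratified improvement ===")
print(report.severity.to_string(index=False))
# ICC near 1 and a bias well inside ±1 CER point mean the automated
# measurement is interchangeable with the manual pixel-count reading;
# the improvement rate is larger for moderate-to-severe eyes because
# they start from a lower preoperative CER.
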