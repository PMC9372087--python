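"""Full three-section evaluation over a synthetic cohort.

Generates a 12-case phantom cohort with the calibrated contour-error
profile, scores contour geometry, recomputes dose-volume indices for
both contour sets against each fixed plan, runs the paired statistics,
and prints the summary report. Writing the CSV bundle to disk is one
extra call (report.save(outdir)).
"""

import contoureval as ce

cases = ce.generate_cohort(n=12, seed=42)
report = ce.evaluate_cohort(cases)
print(report.summary_markdown())
print("Rows: geometry", len(report.geometry), "| paired DVI", len(report.dvi),
      "| correlations", len(report.table3))
print("A significant Wilcoxon P flags a systematic manual-vs-auto dose shift;")
print("Bland-Altman limits show the spread of per-case differences.")
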