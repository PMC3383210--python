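"""Run the full QSAR pipeline on a synthetic study-regime dataset.

Generates a 31-compound, 439-descriptor matrix with six planted descriptors
on a three-factor latent structure, then runs the complete analysis:
degenerate-column cleaning, the |r| >= 0.3 activity-correlation prefilter,
OPS variable selection over all three informative vectors, a 3-LV PLS fit,
the internal validation battery (LOO, leave-N-out, y-randomization), an
HCA-guided train/test split with external validation, and outlier
diagnostics.  Every statistic lands in one JSON-ready report.
"""

import json

from opspls import PipelineConfig, run_pipeline
from opspls.synthetic import paperlike

SEED = 11

truth = paperlike(SEED)
report = run_pipeline(PipelineConfig(
    synthetic_seed=SEED, seed=SEED, n_components=3,
    ops_lv_range=[1, 2, 3], ops_window=6,
))

sel = report["selection"]
recovered = sorted(set(sel["descriptors"]) & set(truth.true_names))
print(f"planted descriptors : {', '.join(truth.true_names)}")
print(f"selected descriptors: {', '.join(sel['descriptors'])}")
print(f"recovered {len(recovered)} of {len(truth.true_names)} "
      f"(vector: {sel['vector_kind']}, {sel['n_lv']} latent variables)\n")

cal, cv = report["calibration"], report["cross_validation"]
print(f"R2 = {cal['r2']:.3f}  SEC = {cal['sec']:.3f}  "
      f"F = {cal['f_value']:.1f} (crit {cal['f_crit']:.3f})")
print(f"Q2(LOO) = {cv['q2_loo']:.3f}  SEV = {cv['sev']:.3f}  "
      f"PRESS = {cv['press']:.3f} < SSy = {cv['ssy']:.3f}")
print(f"mean Q2(LNO) = {report['lno']['overall_mean']:.3f}")
print(f"y-randomization intercepts: R2-line {report['y_randomization']['intercept_r2']:.3f} "
      f"(< 0.3), Q2-line {report['y_randomization']['intercept_q2']:.3f} (< 0.05)")
ext = report["external"]
print(f"external: R2pred = {ext['r2pred']:.3f}  SEP = {ext['sep']:.3f}  "
      f"k = {ext['k']:.3f}  k' = {ext['kprime']:.3f}")
print(f"\nflags: {json.dumps(report['flags'], indent=2)}")
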