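"""Recompute the published statistics from the packaged tables.

Loads the 31-compound activity table and the 5-compound observed/predicted
external-validation table that ship with the package, recomputes every
desk-scale statistic (activity conversions, response sums of squares, the
external-validation battery, and the derived statistics of both printed
model blocks) and prints the comparison.
"""

from opspls import external_metrics, load_activity_table, load_observed_predicted
from opspls.workflow import reproduce_paper

activity = load_activity_table("table1")
obs_pred = load_observed_predicted("table2")
training = activity.drop(obs_pred.ids)

print(f"data set: {len(activity)} compounds, "
      f"pIC50 range {activity.pic50.min():.3f}..{activity.pic50.max():.3f}")
print(f"training mean pIC50 (n={len(training)}): {training.pic50.mean():.4f}\n")

metrics = external_metrics(
    obs_pred.observed, obs_pred.predicted, float(training.pic50.mean())
)
print("external validation of the packaged test set:")
print(f"  R2pred = {metrics.r2pred:.4f}   (> 0.5 required)")
print(f"  SEP    = {metrics.sep:.4f}   (standard error of prediction)")
print(f"  k      = {metrics.k:.4f},  k' = {metrics.kprime:.4f}   (0.85..1.15)")
print(f"  |R2_0 - R'2_0| = {metrics.abs_diff:.4f}   (< 0.3)")
print(f"  all criteria pass: {metrics.all_pass}\n")

result = reproduce_paper()
width = max(len(t["name"]) for t in result["targets"])
for t in result["targets"]:
    status = "ok  " if t["ok"] else "FAIL"
    print(f"  {status} {t['name']:<{width}} computed={t['computed']:<9.4f} "
          f"reference={t['reference']:.4f}")
print(f"\nall {len(result['targets'])} reference targets reproduced: {result['all_ok']}")
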