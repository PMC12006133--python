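"""Scoring a module assignment with internal and external clustering metrics.

Internal indices (SI, CHI, DBI) need no ground truth; external indices
(AMI, ARI) compare against the planted labels available for synthetic data.
"""

import wgchna as w

dataset = w.generate(w.default_scenario())
result = w.run_pipeline(dataset.expression)

internal = w.internal_metrics(result.tom.tom, result.assignment.labels)
print("internal metrics on TOM-row features (grey genes excluded):")
print(f"  silhouette (SI, higher better):        {internal.si:.4f}")
print(f"  Calinski-Harabasz (CHI, higher better): {internal.chi:.4f}")
print(f"  Davies-Bouldin (DBI, lower better):     {internal.dbi:.4f}")

external = w.external_metrics(result.assignment.labels, dataset.truth)
print("\nexternal metrics against planted truth:")
print(f"  adjusted Rand index (ARI):        {external.ari:.4f}")
print(f"  adjusted mutual information (AMI): {external.ami:.4f}")
print("both are corrected for chance: 0 is random agreement, 1 is perfect.")
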