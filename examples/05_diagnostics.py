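"""Posterior certainty, severity profiles and feature detection for a fit.

Fits the planted class count on a synthetic cohort, then produces the
evaluation reports a modeller would inspect before promoting a solution:
certainty of membership, the normalised severity profile, detected
features (variable groups with >=30% spread), and subgroup-size checks.
"""

import lcasub as L

spec = L.compact_cohort_spec(n=800, seed=9)
data, codebook, truth = L.generate_cohort(spec)
fit = L.fit_with_restarts(data, codebook, 3, n_restarts=5, base_seed=1,
                          tol=1e-7).retained

summ = L.posterior_summary(fit.posteriors)
print(f"median max posterior: {summ.median_max_posterior:.3f} "
      f"(IQR {summ.iqr_max_posterior[0]:.3f}-{summ.iqr_max_posterior[1]:.3f})")
print(f"patients with max posterior < 0.70: {summ.n_below_070}")
print(f"patients sharing membership (> 1/3 for 2+ classes): {summ.n_multi_033}")

profile = L.normalized_profile(fit, codebook)
features = L.detect_features(profile)
print(f"\nprofile: {profile.scores.shape[0]} variables x {profile.K} classes, "
      f"{len(features)} feature group(s) with >=30% spread")
for g in features[:3]:
    print(f"  {g.classification:12s} spread>={g.spread:.2f}  members: "
          f"{g.members[:4]}{'...' if len(g.members) > 4 else ''}")

report = L.subgroup_size_check(fit, codebook)
for k, (share, status) in enumerate(zip(report.shares, report.status), start=1):
    print(f"class {k}: {share:.1%} of cohort -> {status}")
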