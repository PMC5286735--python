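"""Two-stage subgrouping: per-domain LCAs, then an LCA on the memberships.

Stage one fits one latent class model inside each health domain and
assigns every patient to their modal domain category; stage two searches
class counts on the six resulting categorical variables. Because modal
assignment discards the certainty of the first-stage memberships, the
second stage typically shows equal or lower posterior certainty than a
single-stage fit on the raw variables.
"""

import lcasub as L

spec = L.compact_cohort_spec(n=800, seed=5)
data, codebook, truth = L.generate_cohort(spec)

result = L.run_two_stage(
    data, codebook,
    domain_Ks={d.name: d.n_categories for d in spec.domains},
    K_max=5, base_seed=2, n_restarts=5, tol=1e-7)

print("second-stage BIC table (6 categorical variables):")
for K, b in result.second_stage.bic_table.items():
    marker = " <- starting model" if K == result.second_stage.starting_K else ""
    print(f"  K={K}: {b:10.2f}{marker}")

K = result.second_stage.starting_K
two = result.second_stage.retained(K)
single = L.fit_em(data, codebook, K, seed=2, tol=1e-7)
s2 = L.posterior_summary(two.posteriors)
s1 = L.posterior_summary(single.posteriors)
print(f"median max posterior: single-stage {s1.median_max_posterior:.3f}, "
      f"two-stage {s2.median_max_posterior:.3f}")
print("(two-stage certainty can only match or trail the single stage: the "
      "first-stage assignment certainty was discarded)")
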