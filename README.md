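# lcasub

Latent class subgrouping of multi-domain questionnaire data.

Patients with complex conditions such as non-specific low back pain differ
widely in their baseline presentation across several health domains
(activity, contextual factors, pain, participation, physical impairment,
psychology). `lcasub` is a toolkit for identifying statistically
homogeneous patient subgroups from such data with latent class analysis
(LCA), for researchers in epidemiology and clinical biostatistics who work
with mixed questionnaire and examination variables.

## The model

A K-class finite mixture with local independence. Patient *i* with
responses *y<sub>i1</sub> … y<sub>iJ</sub>* has likelihood

&nbsp;&nbsp;&nbsp;&nbsp;P(y<sub>i</sub>) = Σ<sub>k</sub> π<sub>k</sub> Π<sub>j observed</sub> f<sub>j</sub>(y<sub>ij</sub> | k)

where π<sub>k</sub> are class weights, f<sub>j</sub>(· | k) is a
multinomial with class-conditional probabilities θ<sub>jkc</sub> for
nominal/ordinal indicators and a normal with class mean μ<sub>jk</sub> and
(by default pooled) variance σ²<sub>j</sub> for continuous indicators.
Missing entries are skipped in the product (ignorable missingness; nothing
is imputed). Estimation is by EM; model size is judged by
BIC = −2·log L + p·ln n.

Beyond the estimator, the package implements the full subgrouping
methodology:

- **Model search** — class counts K = 1..12, ten seeded restarts per K
  retained by a *BIC-consistency* rule (the recurring rounded BIC value
  wins over a lone lower one), and a *starting model* chosen by walking up
  K while BIC keeps dropping by ≥ 1% per added class.
- **Two-stage pipeline** — one LCA per health domain, modal assignment of
  each patient to a domain category, then a second LCA over the six
  resulting categorical variables (fewer parameters, at the price of
  discarding first-stage certainty).
- **Diagnostics** — posterior-certainty summaries, severity-oriented
  profile matrices, feature detection (≥ 30% spread rule), qualitative vs
  quantitative profile differences, subgroup-size checks, and a flagged
  cross-tabulation for comparing two solutions (with adjusted Rand index).
- **Synthetic cohorts** — a generator emulating the six-domain,
  112-variable, n = 928 study design with planted class structure, so every
  stage can be validated against a known truth.

## Worked example

Comparing two subgroup solutions via the membership cross-tabulation
(`examples/04_compare_solutions.py`):

```
grand total: 928 patients
single-stage subgroup sizes: [192, 154, 136, 132, 130, 109, 75] (smallest 75)
two-stage subgroup sizes: [219, 161, 127, 113, 71, 69, 74, 45, 49] (largest 219)
prevalence of TS 1: 24%  prevalence of SS 2: 17%
SS 3 share in its largest cell: 0.831 (nearly a subset of TS 1)
adjusted Rand index between the solutions: 0.206
greedy one-to-one matched agreement: 35.8%
```

Each of the 7×9 cells is flagged: `a` largest in its row, `b` largest in
its column, `c` over 10% of its row, `d` over 10% of its column only. The
reading: the two solutions capture a similar structure (every subgroup of
one solution concentrates in a few subgroups of the other; one single-stage
subgroup is nearly a subset of a two-stage subgroup), yet assign many
individual patients differently (ARI 0.21).

The other example scripts cover cohort simulation, the single-stage search
(BIC table, starting model, loadings), the two-stage pipeline and the
fit diagnostics; each runs in seconds and prints what the numbers mean.
A thin CLI wraps the same stages:
`lcasub simulate|preprocess|search|two-stage|compare --help`.

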