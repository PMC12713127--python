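# spatiodyn

Spatiotemporal dynamics of resting-state brain networks: quasi-periodic
pattern (QPP) detection, complex principal component analysis (cPCA),
template-integrity metrics, and nonparametric cohort comparison — for
intrinsic connectivity network (ICN) time courses.

The package is aimed at researchers studying how large-scale brain
dynamics degrade across disease stages (e.g. along the Alzheimer's
continuum) using network time courses extracted from resting-state fMRI
(here: 105 ICNs in 14 subdomains and 7 functional domains, TR = 3 s).
Because such cohort data are access-controlled, `spatiodyn` includes a
first-class synthetic generator with planted ground truth, so every stage
of the pipeline is testable end to end.

## What it computes

**QPP** — the dominant recurrent spatiotemporal pattern. An iterative
sliding-template algorithm correlates an `N × W` template (window 24 s,
`W = 8` frames) against every window of the series (flattened `N·W`
Pearson correlation), keeps suprathreshold local maxima, and replaces the
template by the mean of the matched segments until the correlation trace
stabilises.

**cPCA** — per ICN β, the analytic signal
`Z_β(t) = I(β,t) + iℋ(I(β,t))` is formed via the Hilbert transform, the
complex correlation matrix `R_ij = (1/T) Σ_t Z_i(t) Z̄_j(t)` is
eigendecomposed, and the leading complex loading `u₁` yields amplitude
(`|u₁|`) and phase-delay (`arg u₁`) maps plus component time courses
`a_k(t) = u_kᴴ Z(t)`.

**Integrity** — cohort templates `Q_i` are compared through ICN-pair
correlation matrices `C_ii = corr(Q_i, Q_i)` and `C_ij = corr(Q_i, Q_j)`,
and the delta `ΔC_ij = C_ii − C_ij` against a reference cohort; cPCA
engagement indices are `l = |u₁|` averaged per domain.

**Statistics** — per functional domain, the within-domain ICN-pair values
of each cohort form one group; Kruskal–Wallis at α = 0.05 with Dunn's
post hoc (Bonferroni) where the omnibus is significant.

See `docs/methods.md` for conventions, assumptions and limitations.

## Worked example

Plant a domain-coherent 24 s pattern into two synthetic cohorts — in the
comparison cohort the paralimbic (PL) networks participate at half
amplitude — then detect each cohort's QPP and compare within-domain
template correlations:

```python
from spatiodyn.experiments import attenuation_experiment

run = attenuation_experiment(seed=7)
print(run.comparison.domain_table)
print("significant:", list(run.comparison.significant_domains))
print("mean delta, perturbed:", round(run.mean_delta_perturbed, 3))
print("mean delta, others:   ", round(run.mean_delta_other, 3))
```

```
domain         H     p_kw group_sizes  significant
    CB  5.555660 0.018421    (78, 78)         True
    VI  2.881771 0.089587    (66, 66)        False
    PL 20.778423 0.000005    (55, 55)         True
    SC  0.913138 0.339283  (153, 153)        False
    SM  0.696140 0.404084    (91, 91)        False
    HC  0.366480 0.544929  (210, 210)        False
    TN  3.464734 0.062691  (120, 120)        False
significant: ['CB', 'PL']
mean delta, perturbed: 0.075
mean delta, others:    -0.003
```

The attenuated PL domain is flagged decisively (H = 20.8 over its 55 ICN
pairs, p ≈ 5e-6) and carries the large positive integrity delta, while the
unperturbed domains sit near delta 0. An occasional borderline flag in
another domain (here CB at p = 0.018) reflects the mild anticonservatism
of treating ICN pairs as independent observations — see the statistics
section of the methods note. Across 20 seeds the perturbed domain is
flagged in 18 and has the largest delta in 19.

The same stages are scriptable from the shell:

```sh
spatiodyn generate --out cohort.tsv --seed 4 --n-timepoints 800
spatiodyn detect-qpp cohort.tsv --out qpp/ --seed 1
spatiodyn cpca cohort.tsv --out cpca/
spatiodyn run-all --config pipeline.yaml --out results/
```

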