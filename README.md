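# matriline

Tools for asking whether clutch **sex-ratio variation is maternally
inherited** — the signature of manipulation by maternally transmitted
endosymbiont bacteria such as *Wolbachia* — and, if so, which manipulative
mechanism (male killing vs feminization) is at work.

The package grew out of the analysis of breeding pedigrees of the dwarf
spider *Oedothorax gibbosus*, whose females produce strongly female-biased
clutches, but it applies to any species where dams are bred over multiple
generations and the sex of their adult offspring is recorded.

## The model

Let `Y_i ∈ {0,1}` be the sex of adult offspring `i` (male = 1) and `d(i)`
its dam. Then

    Y_i ~ Bernoulli(π_d),    logit(π_d) = μ + x_d'β + m_{mat(d)} + e_d

with

* `μ` — population average logit sex ratio;
* `m` — the **maternally inherited** effect, constant along a matriline
  (a mother's effect equals her daughters': `m_i = m_{d(i)}`), with
  `m ~ N(0, σ²_m)`;
* `e_d` — a dam-level residual effect, `e ~ N(0, σ²_e)`, capturing
  sex-ratio variation *not* transmitted to daughters;
* `β` — optional fixed effects (infection status, antibiotic treatment).

Priors are vague normals on `μ` and `β` and Gamma(0.1, 0.1) on the
precisions `1/σ²_m`, `1/σ²_e`. The posterior is explored by
Metropolis-within-Gibbs (conjugate Gamma updates for the precisions,
element-wise random-walk updates for all effects simultaneously), by
default with 2 chains of 12,000 iterations and 2,000 burn-in. A large
`σ²_m` relative to `σ²_e` is the pedigree's evidence that the sex-ratio
trait is transmitted from mother to daughter.

Around the model the package provides:

* a forward-time **pedigree simulator** with matriline-inherited effects,
  maternal endosymbiont transmission, and male-killing / feminization
  mechanisms (`simulate_pedigree`);
* **downstream statistics**: clutch-size weighted Pearson correlation,
  Fisher's exact prevalence comparisons, the expected-infected-male
  accounting with its exact binomial test, a Bayesian group contrast of
  sex ratio by infection status, and a brood-size diagnostic that
  separates male killing (infected broods halved) from feminization
  (broods untouched);
* a dense-grid **quadrature oracle** for validating the sampler on tiny
  problems, and a `matriline` command-line interface
  (`simulate` / `fit` / `stats` / `diagnose`).

## Worked example

```python
import matriline as ml

params = ml.SimulationParams(n_founders=50, n_generations=2, seed=11)
pedigree, truth = ml.simulate_pedigree(params)      # σ²_m=0.64, σ²_e=0.27
records = ml.aggregate_dams(pedigree)               # one binomial record/dam
results = ml.MaternalSexRatioModel(records).fit(ml.McmcConfig(seed=1))
print(results.summary())
```

prints

```
                mean         sd       q2.5      q97.5       psrf
parameter
mu           -0.3708     0.1187    -0.6014    -0.1325     1.0018
tau_m         2.7010     0.9027     1.4098     4.8937     1.0035
tau_e         3.6813     1.1668     2.0418     6.5608     1.0186
sigma2_m      0.4091     0.1296     0.2043     0.7093     1.0032
sigma2_e      0.2965     0.0860     0.1524     0.4898     1.0159
```

Read this as: the mean logit sex ratio is about −0.37 (expit(−0.37) ≈ 0.41,
a female excess), and at this small scale (50 matrilines, 150 dams) the
maternally inherited variance `sigma2_m` is estimated at 0.41 with 95%
credibility interval [0.20, 0.71] — covering the generating value 0.64 is
only reached reliably at larger pedigree sizes; see the study-scale
experiment below. `psrf` near 1 indicates the two chains agree. The
`e`-level variance `sigma2_e` ≈ 0.30 matches its generating value 0.27.

The infected-male accounting used in the field study is one call:

```python
ml.expected_male_infection(ml.PrevalenceScenario(0.45, 0.36, 0.5))
# -> (0.162, 0.275, 0.3707...)   i.e. 37% of males expected infected
```

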