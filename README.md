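# magblup

Microbiome-assisted multi-trait genomic evaluation of longitudinal
beef-cattle growth.

Rumen microbial gene abundances (KEGG orthologs, "MG") are partly under
host genomic control and genomically correlated with growth. `magblup`
implements the full analysis that exploits this: from weekly body
weights, SNP genotypes and MG count tables it derives longitudinal
average daily gains (ADG), a genomic relationship matrix, compositional
microbial traits, Bayesian estimates of heritabilities and host-genomic
correlations, a data-driven subset of informative microbial traits, and
finally genomic breeding values (GEBV) under three breeding strategies —
direct (growth phenotypes only), microbiome-driven (microbial phenotypes
only) and combined. It is aimed at quantitative geneticists and
microbiome researchers who want a tested, reproducible pipeline plus a
synthetic-herd generator for validating every stage by parameter
recovery.

## The model

Growth is summarised as four ADG traits, the OLS slopes (kg/day) of
weight on day over four consecutive 5-point windows of a 17-point weekly
series (consecutive windows share their boundary weighing).

All genetic inference uses the multi-trait genomic animal model

    y = Xb + Zu + e,    u ~ N(0, G ⊗ K),    e ~ N(0, R ⊗ I)

with K the VanRaden method-2 GRM, `G`/`R` the genomic and residual
(co)variance matrices, flat priors on b and scaled-inverse-χ² /
inverse-Wishart priors on the variances with scale
S0 = var(Y)·(df0 + t + 1)·R², R² = 0.5. The model is fitted by Gibbs
sampling with a one-time eigendecomposition of K (exact, makes
thousands of univariate/bivariate scans cheap) and data augmentation for
missing phenotypes — which is also how genotyped-but-unphenotyped sires
and the microbiome-driven strategy (all ADG records missing) enter.

Microbial counts are treated compositionally: core filtering (present in
≥ 70% of samples), geometric Bayesian-multiplicative zero replacement,
and an additive log-ratio (alr) transform whose reference gene is chosen
to preserve the full log-ratio geometry (Procrustes correlation with the
clr configuration) while having minimal log-abundance variance.

GEBV accuracy per animal follows from the posterior sd of its breeding
value, `sqrt(1 − sd_i²/(g_ii σu²))`, and the predicted response to
selecting the top 10% (intensity 1.755) is the posterior of
mean(selected) − mean(all).

## Worked example

```python
from magblup import SimulationConfig, simulate_dataset, adg_table, selection_intensity
from magblup.gblup import GBLUP, McmcSettings, design_matrix
from magblup.params import estimate_adg_parameters

cfg = SimulationConfig(n_animals=400, n_sires_extra=30, n_snps=2000, n_mg=10, seed=0)
data = simulate_dataset(cfg)

adg = adg_table(data.weights)              # 400 animals x ADG_1..ADG_4
grm = data.grm.loc[adg.index, adg.index]
X = design_matrix(data.truth.fixed_level)

res = estimate_adg_parameters(adg, grm, X, mcmc=McmcSettings(n_iter=3000, burn_in=1000, thin=5, seed=0))
s = res["h2"]["ADG_1"]
print(f"h2(ADG_1) median {s.median:.2f}  HPD95% [{s.hpd95_low:.2f}, {s.hpd95_high:.2f}]")
print(f"selection intensity at 10%: {selection_intensity(0.10):.3f}")
```

Output:

```
h2(ADG_1) median 0.43  HPD95% [0.21, 0.60]
selection intensity at 10%: 1.755
```

The median sits above the generating value (0.31) because at 400 animals
the likelihood is diffuse and the default priors pull heritabilities
toward 0.5 — the HPD interval covers the truth. `docs/methods.md`
discusses this information limit.

The same pipeline runs from the shell on TSV inputs (or a simulated
bundle) with checkpointed stages:

```bash
magblup run --config run.yaml          # simulate → adg → grm → compose →
                                       # scans → select → assemble → evaluate
magblup report --outdir magblup_run    # strategy comparison JSON
```

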