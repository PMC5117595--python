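# pedvc — pedigree variance-components analysis

`pedvc` is a toolkit for family-based quantitative genetics of the kind
used in community health surveys: given pedigrees, phenotypes and a few
candidate-gene genotypes, it estimates how much trait variation is
familial (heritability), how much of that is shared between traits
(genetic correlation), and how much individual measured variants
contribute (measured-genotype association). It was built around the
analysis of albuminuria (urinary albumin:creatinine ratio, UACR), blood
pressure and fasting plasma glucose in small multi-generation pedigrees,
and ships a forward simulator that generates study-shaped synthetic data
so the whole pipeline can be exercised and validated end to end without
access to field data.

## The model

For a trait vector **y** over n pedigree members,

    y = Xβ + g + e,     g ~ N(0, A σ²_A),     e ~ N(0, I σ²_E)

where **A** is the additive (numerator) relationship matrix computed from
the pedigree by the tabular method (a_ij is twice the kinship coefficient;
the diagonal is 1 + F_i), X holds fixed covariates (age, sex, weight,
coded genotypes, ...), and heritability is h² = σ²_A / (σ²_A + σ²_E).
Variance parameters are estimated by REML (ML optional). For T traits the
genetic effects have covariance A ⊗ G and the residuals I ⊗ E; genetic and
environmental correlations r_G, r_E are the correlation forms of G and E.
A coded genotype (carrier indicator or allele count) entered as a fixed
effect gives the measured-genotype test, and its Hardy–Weinberg variance
c(1−c)β² (carrier) or 2p(1−p)β² (additive) expressed as a share of σ²_A
quantifies how much of the genetic variance the locus explains.

Model fitting is exposed as scikit-learn-style estimators
(`UnivariateVarianceComponents`, `MultivariateVarianceComponents`,
`MeasuredGenotypeAssociation` — `fit`, `get_params`, trailing-underscore
fitted attributes), with thin functional wrappers (`fit_univariate`,
`fit_multivariate`, `measured_genotype_association`).

Around the core model the package provides: LINKAGE/PED pedigree I/O with
validation, gene-dropping genotype simulation, the transmission
disequilibrium test (TDT), Hardy–Weinberg tests and allele frequencies,
albuminuria categories (micro 3.4–33 g/mol, macro > 33 g/mol), MDRD eGFR,
relative risks with log-scale Wald intervals, and pairwise-complete
correlation matrices.

## Worked example

```python
import pedvc

study = pedvc.generate_study_like_dataset(seed=1)
rm = pedvc.additive_relationship(study.pedigree)

df = study.phenotypes.data.copy()
for locus, risk, scheme in (("ACE", "D", "carrier"), ("TP53", "P", "additive")):
    coding = pedvc.GenotypeCoding(locus, risk, scheme)
    df[coding.column] = pedvc.code_genotype(study.genotypes, coding).reindex(df.index)

fixed = ("age", "sex", "weight", "ACE_D_carrier", "TP53_P_additive")
fit = pedvc.fit_univariate(df, rm, "logACR", fixed)
null = pedvc.fit_univariate(df, rm, "logACR", fixed, va_zero=True)
lrt = pedvc.lrt_heritability(fit, null)

res = pedvc.measured_genotype_association(
    df, rm, study.genotypes, pedvc.GenotypeCoding("ACE", "D", "carrier"),
    trait="logACR", fixed_effects=("age", "sex", "weight", "TP53_P_additive"),
)
```

prints (via the obvious f-strings):

```
pedigree members: 706, phenotyped: 327
h2(logACR) = 0.449 (SE 0.122), V_A = 0.285, V_E = 0.349, n = 327
LRT for h2 > 0: statistic = 13.00, p = 1.56e-04
ACE D carrier effect on logACR: 0.412 (SE 0.133, Wald p = 0.0020); 8.1% of V_A
fold change on raw UACR: 2.58x
r_G(logACR, dBP) = 0.533, r_E = 0.316
```

Reading this: in one simulated replicate of ~700 pedigree members with 327
phenotyped, log10 UACR is significantly heritable (ĥ² = 0.45 against a
generating value of 0.55 — single replicates scatter; the mean over many
replicates recovers the truth), carrying the ACE risk allele raises log10
UACR by 0.41 (≈ 2.6-fold on the raw scale), and that locus accounts for
about 8% of the additive genetic variance. The genetic correlation between
log UACR and diastolic blood pressure is substantially larger than the
environmental one, i.e. their association in this replicate is mostly
familial/genetic.

The same pipeline is available from the shell:

```sh
pedvc simulate --seed 1 --out run/
pedvc kinship --ped run/study.ped --out run/kin
pedvc fit --ped run/study.ped --pheno run/phenotypes.csv \
      --traits logACR,dBP --fixed age,sex,weight --out run/fit
pedvc assoc --ped run/study.ped --pheno run/phenotypes.csv \
      --loci 'ACE:D,I:D;TP53:P,R:P' --locus ACE --risk-allele D \
      --scheme carrier --trait logACR --fixed age,sex,weight --out run/assoc
```

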