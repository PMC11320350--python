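# protclock

A mortality-trained **proteomic aging clock**: train a biological-age
predictor from a plasma protein expression matrix plus survival outcomes,
convert each person's mortality risk into a *proteomic age* in years, and
validate the resulting age deviation against death and incident-disease
outcomes under competing risks.

Second-generation biological-age clocks are trained on mortality rather
than chronological age, so that a person's clock age reflects their risk
state, not just their birth date.  `protclock` implements that construction
end-to-end for proteomics-scale data (thousands of NPX-like continuous
protein values per participant) and ships a synthetic-cohort generator with
known ground truth, so every stage of the pipeline can be verified by
parameter-recovery and null-case tests — the kind of data the design targets
(large biobank cohorts) is access-restricted, the statistical machinery is
not.

## The model

1. **Protein selection.** An L1-penalized Cox model (coordinate descent on
   the Breslow partial likelihood, glmnet's `1/n` λ-scaling, λ by 10-fold
   cross-validated partial-likelihood deviance) is trained on all-cause
   mortality using chronological age plus all proteins; the proteins with
   non-zero coefficients are carried forward.

2. **Paired Gompertz models.** On the same training rows two Gompertz
   proportional-hazards models are fitted by maximum likelihood:

   - *full*: h(t|x) = exp(b₀ + a·t + β_age·age + Σⱼ βⱼ xⱼ)
   - *age-only*: h(t|age) = exp(b₀⁰ + a⁰·t + β⁰_age·age)

   with t in years since baseline and a the Gompertz shape (exponential
   rise of adult mortality with follow-up time).

3. **Risk matching.** A participant's k-year cumulative mortality risk
   under the full model, M = 1 − exp(−e^{b₀+xβ}(e^{ak}−1)/a), is mapped to
   the chronological age A at which the age-only model reaches the same
   risk:

   A = [ log( −log(1−M) · a⁰ / (e^{a⁰k}−1) ) − b₀⁰ ] / β⁰_age

   A is the proteomic age; A minus chronological age is the **age
   deviation** (positive = accelerated aging).  The default horizon is
   k = 10 years.

Validation uses Cox regression for mortality and Fine–Gray
subdistribution-hazard models (Geskus IPCW weighting) for incident diseases
with death as a competing event, across nested covariate-adjustment tiers
with Benjamini–Hochberg FDR; discrimination is compared by Harrell's C.
Proteins associated with age deviation feed a hypergeometric gene-set
enrichment against a protein-coding background (default 20,260 genes).

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(4,000 participants × 200 proteins, 12 causal, ~14% mortality over 13
years, two incident diseases) and write their tables under
`results/study/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_train_clock.py
python analysis/04_validate.py
python analysis/05_enrichment.py
```

Output (abridged):

```
cohort: 4000 participants, 570 deaths (14.2%) over 13 years
removed 3 proteins above 50% missingness: ['PROT0001', 'PROT0002', 'PROT0003']
lambda 0.00900 (5-fold CV) selected age + 57 proteins; 12/12 ground-truth causal recovered
test set: mean proteomic age 47.9 y (chronological 54.2 y), deviation SD 12.43 y
Spearman r(proteomic age, chronological age) = 0.648
mortality HR per year of deviation (age-adjusted): 1.062 [1.048, 1.076]
Harrell's C (mortality): age=0.700, proteomic_age=0.759
top set: CAUSAL_MORTALITY_SET (overlap 12/12, Bonferroni p = 3.25e-36)
```

Reading it: the clock recovers every planted causal protein; each extra
year of proteomic age deviation raises mortality hazard by ~6% after
adjusting for chronological age; the clock discriminates deaths better
than chronological age alone (C 0.76 vs 0.70); and the genes behind the
deviation-associated proteins light up exactly the planted mortality set.

The same pipeline is available as a CLI (`protclock simulate`, `protclock
train`, `protclock score`, `protclock run --config cfg.yaml`) for use on
your own tab-delimited cohort and matrix files.

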