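# fairaudit

Gender-bias auditing and mitigation for phone-based mental-health
classifiers.

Mobile-sensing studies predict a participant's mental-health level (high/low,
from a Mental Health Inventory–style score) out of phone-usage summaries —
call volume, contact diversity, tie strength, temporal rhythms. These models
are typically built on small cohorts (tens of participants) in which women
are under-represented both overall and among high-score labels, and in which
phone-use patterns differ by gender. `fairaudit` is a tested pipeline for
asking, on such data: *does the classifier perform differently for men and
women, and can a preprocessing repair fix that without giving up accuracy?*

It is aimed at researchers auditing small tabular health-classification
studies who need the full loop — cohort in, audit out, mitigation compared —
reproducible from a single seed.

## What it computes

For a binary protected attribute S with privileged level *m* (men) and
unprivileged level *w* (women), and pooled out-of-fold predictions ŷ of the
binary label y, the audit reports:

- **Δaccuracy** = Acc<sub>m</sub> − Acc<sub>w</sub> (percentage points)
- **ΔTPR** = TPR<sub>m</sub> − TPR<sub>w</sub> (equal opportunity) and
  **ΔFPR** = FPR<sub>m</sub> − FPR<sub>w</sub>
- **SPD** = P(ŷ=1 | S=m) − P(ŷ=1 | S=w)
- **DI** = P(ŷ=1 | S=w) / P(ŷ=1 | S=m), flagged *biased* when DI < 0.8
  (the four-fifths rule)
- **BER** = (err<sub>m</sub> + err<sub>w</sub>) / 2 — the group-balanced
  error rate, which (unlike overall error) refuses to hide a sacrificed
  small group: 90 privileged rows all right plus 10 unprivileged rows all
  wrong gives overall error 0.10 but BER 0.50.

The evaluation engine is the one used in small-cohort sensing studies:
median imputation → standardization → SMOTE on the training folds only →
PCA (top 5 components) → classifier (logistic regression, SVM, random
forest with 100 trees / depth 6, k-NN, or MLP), inside stratified 5-fold
cross-validation repeated for many shuffled iterations, with Welch t tests
on the group comparison.

Mitigation is a from-scratch **disparate impact remover**: per feature and
per group, a value at within-group percentile *p* is moved toward the
cross-group median quantile at *p*,

x ↦ (1 − λ) · x + λ · q̄(F<sub>g</sub>(x)),

so at λ=1 a woman at her group's 80th percentile and a man at his group's
80th percentile become indistinguishable on that feature, while within-group
ranks are preserved for every repair amount λ ∈ [0, 1]. The repair is
fitted inside each training fold and applied to the held-out fold; the
classifier itself is never modified.

Because the real study cohorts are private, the package ships a synthetic
cohort generator with the same statistical shape (n≈55, ~38% women,
gender-shifted feature distributions, noisy monotone feature→score link,
controllable *negative legacy* = deficit of high-score labels in the
minority group). It is first-class, tested code: every downstream claim is
demonstrated on cohorts it generates.

## Worked example

Audit a biased synthetic cohort of 55 participants with the random-forest
model, then repeat with full repair and compare:

```bash
fairaudit generate --n 55 --seed 1 -o cohort.csv
fairaudit audit --cohort cohort.csv --model random_forest --iterations 20 --seed 1 -o baseline.json
fairaudit audit --cohort cohort.csv --model random_forest --iterations 20 --repair-lambda 1.0 --seed 1 -o repaired.json
fairaudit compare baseline.json repaired.json
```

The baseline audit prints:

```
                           metric      observed  ideal
               Delta accuracy (%)  10.23 (6.30)    0.0
     Delta true positive rate (%) 37.78 (10.63)    0.0
    Delta false positive rate (%)  16.78 (6.97)    0.0
Statistical parity difference (%)  26.42 (6.44)    0.0
                 Disparate impact 0.553 (0.097)    1.0
              Balanced error rate 0.235 (0.037)    0.0
```

Accuracy is 78.3% overall, but the model favours men: it hands them 26
percentage points more positive predictions (SPD), and women receive
positive predictions at barely half the male rate (DI 0.553, well under the
0.8 bias threshold). After λ=1 repair the comparison ends with:

```
          metric  before_mean  before_sd  after_mean  after_sd  difference     t_stat      p_value
  delta_accuracy    10.232733   6.299917    5.908408  8.076386    4.324324   1.840230 7.401919e-02
       delta_tpr    37.777778  10.628404    6.111111 10.526275   31.666667   9.227470 3.039976e-11
       delta_fpr    16.783626   6.973791   -5.847953  9.168427   22.631579   8.563796 3.720191e-10
             spd    26.418919   6.444831   -0.743243  5.642625   27.162162  13.821873 2.911392e-16
disparate_impact     0.552973   0.096957    1.017484  0.109773    0.464511 -13.824544 2.779072e-16
             ber     0.234947   0.036573    0.206569  0.028699    0.028378   2.660821 1.157373e-02
overall accuracy: 78.27% -> 80.36% (cost -2.09 pp)
```

Disparate impact moves from 0.553 to 1.017 and statistical parity from
+26.4 to −0.7 points (both p < .001); on this cohort the repair *gains* 2.1
points of overall accuracy, because aligning the gendered feature
distributions also removes a systematic misreading of the minority group.

The same workflow is available as a library (`generate_cohort`,
`median_split_label`, `run_audit`, `compare_before_after`, ...); see the
docstrings and `docs/methods.md`.

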