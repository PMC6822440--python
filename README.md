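# crowdaffect

Tools for judging whether crowdsourced emotion labels on pictures are
reliable enough to use — and how many ratings per picture a campaign
needs to collect.

Affect annotation campaigns collect valence, arousal and dominance
ratings on the 9-point SAM (Self-Assessment Manikin) scale, typically
30–50 crowd ratings per picture, and ask three questions:

1. **Reliability** — if the campaign were repeated with only *k*
   ratings per picture, would the per-picture mean ratings agree across
   repetitions? How small can *k* be?
2. **Quality** — do aggregated crowd means agree with gold labels from
   controlled lab studies (IAPS-style normative values)?
3. **Structure** — are per-picture rating distributions unimodal, or do
   subgroups of raters hold opposite opinions that persist across
   thematically related pictures?

`crowdaffect` implements the full analysis pipeline plus a synthetic
campaign generator with the statistical structure such data exhibits,
so every stage is testable end to end without access to proprietary
crowd data.

## Statistics at the core

**Intraclass correlation, two-way random effects, single measurement.**
From the two-way ANOVA mean squares of an items × raters matrix
(MSR rows, MSC columns, MSE residual; n items, k raters):

    ICC_consistency = (MSR − MSE) / (MSR + (k−1)·MSE)
    ICC_agreement   = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

Consistency ignores additive rater shifts; absolute agreement
penalizes them. Estimates ≥ .75 are labelled *excellent*, ≥ .4 *fair*.

**Reliability curves.** Simulated runs draw k ratings per picture
without replacement from the pool (30 runs per k, k = 1…15); the
ICC_consistency of the pictures × runs grid of run means, as a function
of k, yields the minimum-ratings recommendation (first k reaching .75).
Under the additive homoscedastic model the curve has the closed form
σ_p² / (σ_p² + σ_w²/k), used as a testing oracle.

**Dip test for unimodality.** Hartigan's dip — the minimum sup-norm
distance between the empirical CDF and the class of unimodal
(convex-then-concave) CDFs — computed with the classical greatest
convex minorant / least concave majorant interval-shrinking algorithm,
with Monte-Carlo p-values from uniform null samples and an optional
jitter policy for the heavily tied 9-point scale.

**Opinion transfer.** Ratings are binarized about the neutral value 5;
for pairs of multimodal pictures, the counts of raters staying below
(0-0), staying above (1-1), switching sides, or excluded (neutral
rating) quantify whether diverging opinions persist across themes.

## Worked example

```python
import crowdaffect as ca

cfg = ca.GeneratorConfig(seed=42)          # 60 pictures, 2 populations
table, truth, gold = ca.generate(cfg)

pool = ca.pivot_matrix(table, "valence", "specialized")
curve = ca.reliability_curve(pool, ca.SimConfig(seed=1, n_dispersion=5))
print(curve.table.head(4).round(3))
print("min ratings for ICC >= .75:", ca.min_ratings(curve, 0.75))

frac, calls = ca.modality_summary(table, "valence", "specialized", seed=2)
print(f"unimodal fraction (valence): {frac:.2f}")

crowd = ca.aggregate_crowd(pool, k=8, seed=3)
print(f"ICC agreement vs gold (k=8):",
      f"{ca.agreement_with_gold(crowd, gold, 'valence').estimate:.3f}")
```

prints

```
 k    icc  icc_sd  n_runs
 1  0.666   0.008      30
 2  0.809   0.009      30
 3  0.869   0.008      30
 4  0.902   0.004      30
min ratings for ICC >= .75: 2
unimodal fraction (valence): 0.75
ICC agreement vs gold (k=8): 0.967
```

Read: a single rating per picture already correlates decently across
runs (ICC .67) because this campaign's pictures span the valence scale
widely; two ratings push the across-run consistency past the
"excellent" threshold. Three quarters of the pictures have unimodal
valence distributions (the generator planted 25% divisive pictures),
and crowd means from 8-rating runs agree almost perfectly with the
gold labels (ICC_agreement .97).

The same pipeline runs from the shell:

```
crowdaffect simulate --seed 7 --out sim
crowdaffect analyze --ratings sim/ratings.csv --gold sim/gold.csv --seed 7 --out report
```

`report/report.json` consolidates reliability recommendations,
modality fractions, SD profiles, opinion-transfer summaries and
agreement results per dimension × population; outputs are
byte-identical for a fixed seed.

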