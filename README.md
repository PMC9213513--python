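# mbondecode

Analysis pipeline for learning-induced plasticity at *Drosophila*
mushroom-body output neuron (MBON) postsynapses: calcium-trace
quantification, paired pre/post statistics, pseudo-population SVM decoding
of conditioned-odor identity, and choice-assay learning indices — with a
synthetic-data generator that emulates the compartment-specific response
structure of the γ-lobe MBONs (γ1–γ5), so the whole pipeline runs and is
tested without any external recordings.

## The problem

During aversive olfactory conditioning a fly learns that one odor (CS+)
predicts electric shock while another (CS−) does not. The mushroom-body
γ-lobe is divided into five compartments, each read out by its own MBON.
Because each animal can be imaged in only one MBON type, population
activity must be assembled *across* animals: a pseudo-population vector
holds one animal's response per MBON type. The pipeline asks (1) where
training changes the odor drive onto MBON dendrites, (2) whether those
changes suffice to decode which odor was punished, and (3) which
compartment carries that information.

## The core quantities

* ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean fluorescence over the 2 s before
  odor onset; the response measure is AUC = ∫₀⁵ ΔF/F₀ dt (trapezoid, 5 s
  after onset), normalized per group × odor by the mean pre-training AUC.
* Paired pre/post comparisons use a two-sided Wilcoxon signed-rank test
  (exact p by sign-assignment enumeration for n ≤ 15, tie-corrected z).
* Decoding: per model, one animal per MBON type is held out as the CS+/CS−
  test pair; 1000 bootstrap drawings from the remaining 45 samples build
  2000 training vectors for a linear SVM (C = 1, z-scaled features); model
  accuracy ∈ {0, 50, 100}%. 100 models give a mean accuracy and a
  signed-rank test against the 50% chance level. Controls: pre-training
  labels, random A/B relabeling for odor-only/shock-only; plus
  leave-one-MBON-out ablation.
* Behavior: lane preference index PI = (N_CS+ − N_CS−)/N, learning index =
  mean PI of two reciprocally trained lanes; groups compared by one-way
  ANOVA + Tukey and Bonferroni-corrected one-sample t-tests.

## Worked example

Either run the numbered drivers (`analysis/01_simulate.py` …
`05_behavior.py`) or the CLI:

```sh
mbondecode simulate --seed 1 --out results
mbondecode quantify --traces results/traces.csv --out results/aucs.csv
mbondecode plasticity --aucs results/aucs.csv
mbondecode decode --aucs results/aucs.csv --seed 1 --out results
mbondecode behavior --lanes results/behavior_lanes.csv --out results
mbondecode report --dir results
```

`simulate` writes 900 traces (3 protocols × 5 MBON types × 10 flies × 3
odors × 2 phases). `plasticity` prints one row per stratum, e.g. (seed 1):

```
mbon_type   protocol      cs_role  n         z        p direction
       g1     paired       CSplus 10 -2.803060 0.001953  decrease
       g1     paired      CSminus 10  0.050965 1.000000  decrease
       g3     paired       CSplus 10 -2.803060 0.001953  decrease
...
pooled shock-only gamma1 test: n=20, z=3.397, p=0.0006806, direction=increase
```

— the CS+-specific suppression is confined to γ1, γ2–γ4 adapt to all
odors, and the γ1 potentiation after shock alone is significant only when
both trained odors are pooled. `decode` prints nine condition summaries
(seed 1):

```
  condition  n_models  mean_accuracy  chance_test_p
    trained       100           62.0       5.3e-04
pretraining       100           66.0       1.4e-06
  odor_only       100           63.0       1.6e-03
 shock_only       100           69.5       2.5e-08
    excl_g1       100           56.5       6.3e-02
    ...
```

A single run's mean accuracy carries a ~±10-point dataset-level
fluctuation (all 100 models share one 50-animal dataset — at this seed
even the controls land high); averaged over replicate experiments the
trained decoder sits near 70–75%, every control near 50%, and among the
ablations only removing γ1 returns accuracy to chance. See
`docs/methods.md` for the generator's assumptions and the statistical
properties of these estimates.

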