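# biosol — predicting drug solubility in biorelevant intestinal media

`biosol` models the apparent solubility (S_app, log10 molar) of lipophilic
drugs in fasted-state simulated intestinal fluid (FaSSIF) and aspirated
human intestinal fluid (HIF). Intestinal solubility governs oral drug
absorption, but HIF is scarce and expensive, and even FaSSIF measurements
require synthesized compound. The package is aimed at pharmaceutical
profiling and QSPR practitioners who want transparent, latent-variable
models that run on calculated molecular descriptors — optionally sharpened
with cheap experimental measurements such as buffer solubility.

It ships a curated 86-compound dataset of log S_app in blank phosphate
buffer pH 6.5 (PhB), FaSSIF and HIF together with molecular weight,
logD(pH 6.5), polar surface area, rotatable bonds, melting point and
train/test labels (see `docs/table1_curation.md` for how the table was
curated), plus a seeded synthetic-data generator so that the whole pipeline
is testable without proprietary descriptor software.

## The model

The core regression is PLS1 (projection to latent structures) fitted by
NIPALS. For a centered descriptor matrix **X** (n x p) and response **y**,
components a = 1..A are extracted as

    w_a ∝ X_a' y,   t_a = X_a w_a,   p_a = X_a' t_a / t_a't_a,
    q_a = y' t_a / t_a't_a,          X_{a+1} = X_a − t_a p_a'

with prediction through the closed-form coefficients
**B** = **W**(**P**'**W**)⁻¹**q**. Model quality is tracked by the grouped
cross-validated Q² = 1 − PRESS/SS (7 groups, venetian-blind assignment),
and descriptor influence by VIP, whose squares average to 1.

The model-building protocol mirrors standard chemometric practice:

1. descriptors are blinded, signed-cube-root transformed, screened for
   gross non-normality, and autoscaled;
2. compounds are sorted by response and every third one is assigned to the
   test set; training-set outliers flagged by PCA (Hotelling T² or DModX at
   the 95% limit) are relocated to the test set;
3. all but the 100 highest-VIP descriptors are discarded, then greedy
   backward elimination removes any descriptor whose exclusion leaves Q²
   equal or improved, until no further removal is possible;
4. measured properties (PhB solubility, melting point, logD) can be
   appended as extra descriptors and are kept only if Q² improves;
5. two models' predictions can be combined as an unweighted consensus
   average, whose RMSE provably never exceeds the root-mean of the two
   models' squared RMSEs.

Everything is exposed both as scikit-learn-style estimators
(`NipalsPLS`, `PCAModel`, `DescriptorPreprocessor`, `VipGreedyPLS`) that
compose with sklearn pipelines, and as a CLI (`biosol`).

## Worked example

Summaries and inter-medium correlations of the bundled dataset:

```text
$ biosol data summarize --medium fassif
medium=fassif n=86 min=-5.44 max=-2.14 median=-3.73 fold_range=2e+03
$ biosol data summarize --medium hif
medium=hif n=48 min=-6.06 max=-2.02 median=-4.00 fold_range=1.1e+04
$ biosol correlate --a phb --b fassif
phb,fassif,all,n=63,r2=0.588
phb,fassif,logd_lt3,n=29,r2=0.962
phb,fassif,logd_3to4,n=16,r2=0.715
phb,fassif,logd_gt4,n=18,r2=0.163
```

Solubility spans roughly 2000-fold in FaSSIF and 11,000-fold in HIF.
Buffer and FaSSIF solubility correlate well for mildly lipophilic
compounds (r² 0.96 below logD 3) but poorly for the most lipophilic ones
(r² 0.16 above logD 4) — the lipid aggregates in FaSSIF solubilize
lipophilic drugs far beyond their buffer solubility, which is exactly why
a dedicated FaSSIF/HIF model is needed.

A full model-building run on synthetic descriptors (the bundled dataset
has no public descriptor matrix):

```python
from biosol.workflow import RunConfig, run_workflow

cfg = RunConfig(outdir="runs/demo", seed=1,
                synthetic={"n": 86, "p": 120, "k": 2,
                           "n_informative": 5, "noise_sd": 0.3},
                augmentation=["phb_solubility"])
run_dir = run_workflow(cfg)
```

which writes `summary.yaml` reporting, for this seed: 32 descriptors
retained, Q² = 0.93, RMSE_tr = 0.13, RMSE_te = 0.87 (n_train = 55,
n_test = 31 after one outlier relocation), and an augmentation block
showing that adding buffer solubility raises Q² from 0.87 to 0.90 on the
augmentation-complete training subset, so it is retained.

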