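# Methods

This note documents the estimation and testing conventions implemented in
`pupiltask`.

## Data model and preprocessing

All signals live on a common 20 samples/s grid. Epochs are half-open
intervals `[start, end)` in seconds; a bin belongs to an epoch iff its left
edge lies inside it. Reference stimuli are 0.75 s (15 bins) with 0.7 s
inter-stimulus gaps.

The pupil trace is shifted forward by 750 ms (held at its first value) to
account for the delayed relationship between pupil size and neural activity,
then normalized by the raw session maximum to give the regressor `p(t)`; the
engagement regressor `b(t)` is 1 during active-behavior blocks. The
large/small-pupil split is a median split over per-presentation means of the
lagged pupil (ties labeled small).

Reference presentations from active miss and false-alarm trials, and any
presentation overlapping a target, are excluded from model fitting. The
spontaneous rate `s0` is the mean rate over pre-trial silence (0.35 s before
trial onset) and inter-stimulus gaps (skipping 0.2 s after each stimulus
offset to avoid offset responses), pooled over included trials. The stimulus
PSTH `r0(t)` is the included-presentation mean response per stimulus minus
`s0`, so the state-independent ("null") prediction is `s0 + r0(t)`.

## Behavior

A lick 0.1–1.5 s after target onset is a hit; a lick before that window is a
false alarm; no lick with a target presented is a miss; each completed,
un-licked reference presentation contributes one correct rejection. Hit rate
HR = hits/(hits+misses) and false-alarm rate FAR = FAs/(FAs+CRs) are exact
ratios; sensitivity d′ = z(HR) − z(FAR) after clipping both rates to
[1/(2n), 1 − 1/(2n)] (n = the relevant trial count) so perfect rates stay
finite.

## State-dependent model

The full model per unit is

```
r(t) = s0 · F_d[d0 + dp·p(t) + db·b(t)] + r0(t) · F_g[g0 + gp·p(t) + gb·b(t)]
```

with six free coefficients. `F_d` and `F_g` share a fixed
difference-of-exponentials (Gompertz) sigmoid
`F(x) = B + (1−B)·exp(e − exp(−k(x−x0)))` with `e = exp(−k(1−x0))`; the
default shape (B = 0, k = 1, saturation 2) places `x0` so that `F(1) = 1`
exactly in floating point, which makes the neutral parameter point
(`d0 = g0 = 1`, all state coefficients 0) reduce the model bitwise to
`s0 + r0(t)`. An identity mode exists for optimizer diagnostics.

Partial models shuffle one regressor in time and the null model shuffles
both. Shuffling permutes per-trial blocks of the flattened signal among trial
slots of equal length, preserving within-trial autocorrelation and the
per-trial value multiset; the same seeded permutations are reused across the
model variants of a unit so variants differ only in which alignment is
destroyed.

Fitting uses 20-fold cross-validation with trial-interleaved fold assignment
(consecutive trials land in consecutive folds; no trial is split). Within
each fold, `r0` and `s0` are re-estimated from the training trials only, and
the coefficients minimize training MSE by bounded L-BFGS-B (analytic
gradient, neutral starting point, random restarts on non-convergence). The
concatenated held-out predictions cover every included bin exactly once;
prediction accuracy is the squared Pearson correlation r² between prediction
and observation. Unique variance is `r²_full − r²_partial` (signed; small
negative values are evidence of overfitting and are preserved).

Significance per unit uses a jackknife over the folds: leave-one-fold-out
estimates of the difference in prediction correlation feed a t statistic with
the (n−1)-inflated jackknife standard error and n−1 degrees of freedom. A
unit is state-modulated if full beats null (p < 0.05), and is then classified
`task_only` / `pupil_only` / `both` by which unique contribution is
significant, or `ambiguous_state` if neither is individually significant.

## Modulation indices

MI = (r_α − r_β)/(r_α + r_β), with rates averaged over the 0.75 s stimulus
windows of the presentations in each condition, computed from model
predictions rectified at zero. Pairs: active/passive (AP, active first),
large/small pupil (LS, large first), and pre/post-behavior passive blocks
(P1P2, fitted on passive data with block identity replacing the engagement
regressor). The component unique to one variable subtracts the partial-model
MI, e.g. task-unique MI_AP = MI_AP(full) − MI_AP(pupil-only); the identity
`unique = full − partial` is exact by construction. For population summaries,
each unit's (partial, unique) pair is multiplied by the sign of its mean so
magnitude comparisons are direction-agnostic, and the reduction is
`1 − mean(unique)/mean(partial)`.

## Population statistics

The hierarchical bootstrap resamples recording sites with replacement and
then units within each sampled site; two-sided p-values are
`2·min(frac ≤ 0, frac ≥ 0)` over the bootstrap distribution, floored at
1/n_iter and reported as "< floor" when no crossing occurs. The test is
calibrated under its intended nested null (site-level random effects with a
zero grand mean); with strictly IID data it is conservative by construction,
because site resampling adds variance that the data do not contain.

The overlap of task- and pupil-modulated populations is tested by permuting
one significance-flag vector and counting permutations whose joint count
reaches the observed one; for 8 or fewer units all permutations are
enumerated, making the p-value exact.

## Synthetic sessions

Sessions follow a passive–active–passive block design. Trials hold 2–5
reference noises under a flat hazard (constant continuation probability 2/3,
capped at 5) so the target time is unpredictable, followed by a target and a
response window. Outcomes are drawn from the configured hit rate (per
target) and false-alarm rate (per reference); a false alarm truncates the
trial at the lick.

Pupil is a block-dependent baseline (larger when active) plus zero-mean
Ornstein–Uhlenbeck noise and a gamma-shaped trial-onset dilation transient
(peak ~1 s, larger when engaged). Spike rates follow the state model with
known coefficients and Poisson count noise at 20 Hz bins (Gaussian and
noise-free options exist for diagnostics).

Identifiability: the analysis estimates `r0` as the session-average evoked
response, which absorbs any mean state modulation. The generator therefore
fixes the offsets `d0`, `g0` so the mean DC and gain terms over included
reference bins equal one; the stored true PSTH then coincides with the
average response and the state coefficients (dp, db, gp, gb) are recoverable.
Ground truth stores the generating parameters, the noiseless rate, and
analytic modulation indices computed from the noiseless rates.

All epoch times are integer bins divided by the bin rate, so the text
container round-trips exactly, and every generated session passes the same
structural validation as loaded data.

## Auditory tuning

STRFs are estimated by reverse correlation: lag-wise cross-correlation of the
mean-subtracted rate with each mean-subtracted spectrogram channel,
normalized by channel variance (valid for near-white ripple stimuli;
zero-variance channels yield zero weights with a warning). Best frequency is
the center of mass, on the log-frequency axis, of the positive part of the
STRF's first left singular vector (sign-aligned so its largest-magnitude
coefficient is positive). Response reliability is a split-half SNR: trials
are randomly halved, the two half-PSTHs correlated, Spearman–Brown corrected,
averaged over splits and floored at zero.

## Reproducibility

Every stochastic step (generation, shuffles, fold restarts, bootstraps,
permutations) is driven by explicit integer seeds, and result tables are
written with a fixed float format, so a fixed seed reproduces every output
byte for byte.

## Known limitations

- With pupil strongly correlated to engagement (as in the default
  generator), the shuffle-based decomposition attributes genuinely shared
  variance to whichever regressor remains intact; unique contributions are
  then conservative and the task-only MI reduction has a nonzero floor. The
  acceptance tests therefore probe attribution specificity at the study
  design and the sharp limits under controlled dissociation sweeps.
- Bootstrap standard errors for the six model coefficients come from
  presentation resampling with PSTH re-estimation; coefficients on the DC
  path of low-rate units are weakly identified and carry honest, large SEs.
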