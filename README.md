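# qt1pipe

Cortical quantitative-T1 (qT1) mapping and group statistics for
case-control MRI studies, with a fully synthetic phantom/cohort generator
so the whole chain is testable without scanner data.

Quantitative T1 is a per-voxel tissue property (ms) estimated from spoiled
gradient-echo (SPGR) acquisitions; elevated cortical qT1 is commonly read
as reduced myelination. This package implements the analysis chain of a
small schizophrenia-spectrum (SSD) vs healthy-control (HC) study that
compared two acquisition protocols — a single-echo SPGR (flip angles
3°/14°, TE = 4.948 ms) and a multi-echo fast SPGR (3°/24°, five echoes
TE = 3.36 + 4.42·k ms, TR = 28.5 ms) — and asked which is more sensitive
to group differences and covariates. It is aimed at quantitative-MRI
methodologists and psychiatric-neuroimaging analysts who want the fitting
and statistics pipeline as reusable, tested code.

## Model core

Steady-state SPGR signal at flip angle α and repetition time TR:

    S(α) = M0 · sin(α) · (1 − E1) / (1 − cos(α) · E1),   E1 = exp(−TR/T1)

with echo-time decay `exp(−TE/T2*)` for multi-echo readouts. Two
acquisitions at flip angles α₁, α₂ give the classic two-point VFA/DESPOT1
solve via the linearization y = E1·x + M0(1−E1) with y = S/sin α,
x = S/tan α. Transmit-field inhomogeneity is handled by the double-angle
method (DAM): from FSE images at nominal 60°/120°,

    κ = arccos(S₁₂₀ / (2 S₆₀)) / 60°

scales every nominal flip angle voxel-wise (α′ = κα) before fitting.
Regional statistics follow the study design: per-ROI OLS of mean qT1 on a
group indicator adjusting for age and sex, Cohen's d from the group
t-statistic (d = t·√(1/n₁+1/n₂), SE(d) = √((n₁+n₂)/(n₁n₂) + d²/2(n₁+n₂))),
Benjamini-Hochberg FDR applied separately per hemisphere, within-patient
covariate models (age, sex, chlorpromazine-equivalent dose), and
inter-protocol Pearson correlation per ROI.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (tables under `results/`, volumes under `scratch/`):

```sh
python analysis/01_simulate_cohort.py --seed 1   # cohort + ground truth
python analysis/02_fit_t1_maps.py     --seed 1   # B1 map, VFA fits, ROI means
python analysis/03_group_stats.py                # group GLM + covariates
python analysis/04_protocol_reliability.py       # correlation, SD, noise MC
python analysis/05_effect_size_table.py          # reference-table arithmetic
```

`05_effect_size_table.py` recomputes every effect size of the reference
regional table from its printed mean differences and standard errors
(n = 14 patients, 7 controls) and ends with:

```
max |d deviation| at printed precision: 0.000
max |SE(d) deviation|: 0.000
effect sizes range from 0.59 (left medialorbitofrontal) to 1.59 (right cuneus)
```

i.e. the printed Cohen's d and SE(d) values are exactly the two-group
conversion of the printed differences, and the extreme effect sizes land
in the expected parcels. `04_protocol_reliability.py` prints the
noise-propagation comparison; on the default settings:

```
Monte-Carlo noise propagation at matched total signal: ME fit noisier than
SE in 100% of replicates (median SD 1.81 vs 0.87 ms)
```

meaning that at an equal total signal budget and equal per-image noise,
the multi-echo protocol's echo averaging under T2* decay roughly doubles
the standard deviation of fitted regional T1 — the mechanistic reading of
why the multi-echo dataset shows larger variability.

## Layout

- `src/qt1pipe/relaxometry.py` — signal models and closed-form inverses
- `src/qt1pipe/phantom.py` — phantom, acquisition simulator, cohort generator
- `src/qt1pipe/b1map.py` — DAM B1 map, masked smoothing, resampling
- `src/qt1pipe/t1fit.py` — echo averaging, volume fitting, QC
- `src/qt1pipe/roistats.py` — ROI means, GLM, effect sizes, FDR, reliability
- `src/qt1pipe/reliability.py` — protocol noise-propagation Monte Carlo
- `src/qt1pipe/experiments.py` — the validation experiments
- `src/qt1pipe/pipeline.py`, `io.py` — config-driven end-to-end runs, NIfTI/CSV I/O
- `docs/methods.md` — model assumptions, defaults, and design choices
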