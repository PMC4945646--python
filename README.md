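# physioad

**Multimodal physiological feature extraction and staged classification of
TV-commercial effectiveness.**

`physioad` is for researchers in affective computing / neuromarketing who
want a tested, reusable implementation of a classic paradigm: subjects watch
a ~30-minute documentary with three embedded blocks of three commercials
while EEG (30 channels @ 256 Hz), single-lead ECG, skin conductance (GSR)
and respiration are recorded; features extracted per (subject, ad) instance
feed a classifier protocol that labels each commercial **positive / neutral
/ negative** in effectiveness and finally predicts one held-out, unlabeled
spot.  Since no public recordings exist for this design, the package ships a
synthetic-session generator with class-conditional physiology and
ground-truth event ledgers, so the whole chain is reproducible and testable
end to end.

## What it computes

* **EEG** — Global Field Power over the 12 frontal electrodes in six bands
  (δ 1–3, θ 4–7, α 8–12, β 13–24, β-ext 25–40, γ 25–100 Hz), using the
  pairwise form
  `GFP = √(ΣᵢΣⱼ(uᵢ−uⱼ)²/Nₑ)`,
  its baseline **Zscore** `(GFP − mean GFP_B)/σ(GFP_B)` against the 2-min
  documentary stretch preceding each ad block, Welch band power per frontal
  electrode (128-sample windows, 50% overlap), supra-threshold Zscore peak
  counts and the **interest index** `II = PN_brand / PN_total`, plus
  group-level memorization and pleasantness (right−left frontal asymmetry)
  curves.  Per-instance vectors: 18 + 72 + 8 = **98 features**.
* **HRV** — Pan-Tompkins R detection, an artifact-screened RR tachogram and
  the canonical **56-feature battery**: 11 time-domain metrics, 14 spectral
  metrics each under a Welch and a Lomb-Scargle estimator (ULF/VLF/LF/HF),
  14 time-frequency metrics (windowed Welch, averaged) and Poincaré SD1/SD2
  with Sample Entropy.
* **GSR / respiration** — **10** skin-conductance and **6** breathing
  statistics from morphologically smoothed traces (sudomotor peak counts and
  rates, rises, ranges; breathing rate and inter-breath intervals).
* **Evaluation** — dataset variants (GSR 10, RSP 6, HRV 56, EEG 18/72/8/98,
  combinations 66/74/164 columns), SMOTE balancing, z-standardisation,
  stratified 10-fold cross-validation of Weka-style cascades (Random Forest,
  one-vs-all / bagging / AdaBoost combinations, wrapper attribute
  selection), a three-round winners protocol (advance at ≥75% macro
  accuracy) and majority-vote prediction of the unlabeled ad.

Preprocessing follows the paradigm's prescriptions: EEG 0.5–40 Hz zero-phase
band-pass with kurtosis channel/epoch QC, spatial interpolation and
ICA-based blink removal; ECG linear-phase 0.5 Hz high-pass, 50 Hz notch,
65 Hz low-pass; morphological opening/closing for GSR and respiration.

## Worked example

Fourteen synthetic subjects with strong class effects on the sudomotor event
rate and the slow heart-rate drift; GSR+HRV features; selection and the
one-vs-all AdaBoost/Random-Forest cascade:

```python
import physioad as pa
from physioad import evaluation as ev
from physioad.session import SessionConfig
from physioad.pipeline import extract_cohort_features

cohort = pa.generate_cohort(14, pa.ClassEffects.strong(), seed=7,
                            session_config=SessionConfig.compact(),
                            drop=pa.DropModel.none(), modalities=("ecg", "gsr"))
tables = extract_cohort_features(cohort, signals=("gsr", "hrv"), seed=0)
raw = ev.assemble("GSR+HRV", tables, cohort.ad_labels)     # 112 x 66
prep, imp, sc = ev.prepare_table(raw, seed=0)              # impute, SMOTE, z-scale
print(ev.cross_validate(prep, "RF", k=10, seed=0).summary())
sel = ev.wrapper_select(prep, "RF", seed=0)
print(ev.cross_validate(prep.select(sel), "MCC+AB+RF", k=10, seed=0).summary())
```

prints

```
RF             negative: 100.00  neutral:  91.07  positive:  94.64  average:  95.24
MCC+AB+RF      negative: 100.00  neutral:  96.43  positive:  98.21  average:  98.21
```

The per-class numbers are class recall (%) aggregated over ten stratified
folds and *average* is their macro mean.  The wrapper picked two slow-HRV
features (`t_minRR`, `fw_aULF`) — exactly the channels the `strong()` preset
loads with class signal.  Training the final cascade and predicting the
held-out unlabeled ad (generated with positive-class physiology) yields a
unanimous `positive` majority vote.

A command-line front end covers the same ground:

```bash
physioad simulate -n 5 -s 1 --compact --out scratch/cohort
physioad classify -n 10 --variant GSR+HRV --cascade RF --effects strong -s 1
physioad protocol -n 20 -s 1 --signals gsr,hrv,rsp --report protocol.json
```

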