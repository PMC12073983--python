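# hfoarea

Automated delineation of the interictal **high-frequency-oscillation (HFO)
area** from intracranial EEG, and the multicentre diagnostic statistics of
its value for predicting postsurgical seizure outcome in drug-resistant focal
epilepsy.

## The problem

Epilepsy surgery aims to remove the epileptogenic zone. Interictal HFOs —
brief 80–500 Hz oscillations in iEEG — are a candidate biomarker of
epileptogenic tissue that does not require recording seizures. This package
implements the full analysis chain a multicentre validation study of that
biomarker needs:

1. **Preprocessing** — polyphase downsampling to 2000 Hz, within-electrode
   bipolar montage, centre-marked exclusions, 5-minute non-REM epochs.
2. **Detection** — ripples (80–240 Hz) and fast ripples (250–490 Hz) found by
   a per-channel robust envelope threshold (median + 3 scaled-MAD of the
   Hilbert envelope) and validated by an in-band spectral-peak criterion that
   rejects transient artefacts; an **HFO** is a ripple co-occurring with a
   fast ripple. Rates are events per effective minute.
3. **HFO area** — per epoch, channels whose rate exceeds the 95th percentile
   of the cross-channel rate distribution are candidates; channels that are
   candidates in ≥50% of their analysable epochs form the HFO area. If no
   channel reaches 50% the patient is *inconclusive* and no prediction is
   made.
4. **Outcome prediction** — a patient is classified by whether the HFO area
   was completely resected (crHFO-area) and by the ILAE outcome:
   TP (incomplete resection, recurrent seizures), TN (complete, seizure-free),
   FP (incomplete, seizure-free), FN (complete, recurrent).
5. **Cohort statistics** — PPV/NPV/sensitivity/specificity/accuracy with
   exact Clopper–Pearson CIs; a paired relative-NPV test (delta-method
   variance of log NPV₁ − log NPV₂); DerSimonian–Laird random-effects pooling
   of per-centre proportions and odds ratios with Q/I²; a bivariate
   random-effects SROC model with AUC; Wilcoxon rank-sum rate comparisons;
   and an OLS model of prediction correctness on quantized clinical
   covariates with Benjamini–Hochberg FDR.

A synthetic-data module generates iEEG with known injected events (1/f
background, flat-top sinusoidal bursts, Poisson event times, seeded
substreams per channel) and multicentre cohorts with known outcome-generating
probabilities, so every stage has a ground-truth test surface. Clinical
recordings of this kind cannot be shared, so the synthetic module is the
package's first-class test bed; see `docs/methods.md` for what it does and
does not emulate.

## Worked example

```python
import hfoarea as h

spec = h.RecordingSpec(n_channels=4, duration_s=600,
                       event_rates={"S02": 4.0}, seed=42)
rec, truth = h.simulate_recording(spec)

epochs = h.segment_epochs(rec)
rates, _ = h.rate_matrix_from_epochs(epochs)
print(rates.rates.round(1))

area = h.compute_hfo_area(rates)
print(sorted(area.channels), area.conclusive)

cr = h.resection_status(area, {"S02", "S03"})
print("complete resection of HFO area:", cr)
```

prints

```
       0    1
S01  0.0  0.0
S02  4.6  2.2
S03  0.0  0.0
S04  0.0  0.0
['S02'] True
complete resection of HFO area: True
```

Channel S02 carried injected HFOs at 4/min; the detector measures 4.6 and
2.2 events/min in the two 5-minute epochs (the rest of the montage is clean),
S02 exceeds the per-epoch 95th-percentile threshold in 100% of epochs and is
the entire HFO area, and since S02 lies in the resected set the patient is
predicted to become seizure-free (a TN if the outcome is ILAE 1, an FN
otherwise).

Cohort-level use goes through `StudyRun`, which enforces the blinded two-phase
design — HFO areas are computed from signals alone before any clinical data
are accepted:

```python
run = h.StudyRun(h.AnalysisConfig())
run.run_phase1(recordings)          # dict: patient_id -> Recording
report = run.run_phase2(clinical)   # DataFrame with resections + ILAE outcomes
```

The report carries per-patient areas and crHFO flags, the confusion matrix,
predictive values with exact CIs, the relative-NPV test, pooled proportion
and odds ratio across centres, the SROC summary and the covariate model.

## Command line

Each stage is independently runnable and exchanges documented formats
(EDF or raw+JSON fixture recordings, events/rates CSV, area JSON, clinical
CSV, report JSON):

```bash
hfoarea simulate --channels 4 --duration 600 --rate S02=4.0 --seed 42 --out p1
hfoarea preprocess p1.raw --out p1_pre
hfoarea detect p1_pre.raw --out-prefix p1
hfoarea area p1_rates.csv --minutes-csv p1_minutes.csv --out p1_area.json
hfoarea predict areas.json clinical.csv --out pred.json
hfoarea stats areas.json clinical.csv --out report.json
hfoarea report p1.raw p2.raw ... clinical.csv --out report.json
```

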