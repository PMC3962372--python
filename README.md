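# fallseg

Pre-impact fall detection from whole-body segment kinematics: which body
segments do you need to watch to tell, within a few hundred milliseconds,
that a walking person has just been destabilised by a slipping perturbation?

`fallseg` is aimed at movement scientists and wearable-sensor engineers who
want to study sensor placement for fall detectors. It implements the full
analysis chain:

1. **Kinematics** — segment centre-of-mass (CoM) trajectories from endpoint
   markers via de Leva's anthropometric ratios, differentiated to global
   linear acceleration with three-point central differences, and assembled
   into the per-subject dataset `M` (15 segments × 3 axes = 45 rows; 20
   trials × 600 samples = 12 000 columns).
2. **Segment ranking (ICA1)** — FastICA on `M`; the retained component count
   `N` is the smallest PCA dimensionality explaining ≥95 % of variance; each
   segment's **Total Segment Weight** (TSW) is its cumulative absolute
   loading on the retained independent components, in percent. Subsets are
   chosen bilaterally from the ranking.
3. **Classification (ICA2 + NN)** — inside a double leave-one-out
   cross-validation (outer: test trial; inner: early-stopping validation
   trial), a per-fold ICA projects trials into component space and a
   three-layer tanh network (80 hidden units) trained by resilient
   backpropagation labels every sample W (walking) or P (perturbation), with
   NA for uncertain samples under the 0.5 activity threshold.
4. **Detection & metrics** — a perturbation is detected on 5 consecutive P
   samples; trials score TP/FN in the post-onset phase and TN/FP in the
   pre-onset phase. Reported: mean detection time (MDT), Sensitivity
   = TP/(TP+FN), Specificity = TN/(TN+FP), Accuracy = (Sens+Spec)/2.
5. **Comparison** — paired t-tests of each reduced segment combination
   against the full-body baseline and a two-way ANOVA of MDT on perturbation
   direction × side.

Because no public motion-capture dataset accompanies this protocol, the
package ships a first-class synthetic-subject generator (quasi-periodic
walking harmonics + a perturbation-locked damped transient with
segment-dependent gain and latency, seeded and reproducible) that every
stage is developed and tested against. See `docs/methods.md` for the model
details and what the synthetic data does and does not demonstrate.

## Worked example

```python
import fallseg as fs
from fallseg.nn import TrainConfig

params = fs.SubjectParams(seed=1, noise_sd=0.1)   # one synthetic subject
trials = fs.generate_subject(params)              # 2 sessions x 10 perturbations

cfg = fs.ExperimentConfig(
    train=TrainConfig(hidden_units=20, max_epochs=100, patience=25),
    master_seed=1)

ranking, _ = fs.run_ranking(trials, cfg)          # ICA1
print(ranking.n_retained, ranking.rank[:6])

report = fs.run_subject(trials, ["LH", "RH", "LF", "RF"], cfg,
                        combination_name="F-H")   # double LOOCV, feet+hands
print(f"MDT {1000 * report.mdt_mean:.0f} ms  "
      f"sens {100 * report.sensitivity:.1f}%  "
      f"spec {100 * report.specificity:.1f}%  "
      f"acc {100 * report.accuracy:.1f}%")
```

prints

```
8 ['RF', 'LF', 'LH', 'RS', 'LS', 'RH']
MDT 61 ms  sens 100.0%  spec 100.0%  acc 100.0%
```

Eight independent components carry 95 % of the variance of this subject's
45-channel dataset, and the feet rank as the most informative segments
(largest TSW), followed by the other distal extremities — the synthetic
perturbation response is strongest and earliest there. Watching only feet
and hands, every one of the 380 cross-validated test-trial instances is
detected, with no false alarms during walking. The 61-ms MDT is near the
detection rule's floor (5 samples at 100 Hz): the synthetic foot transient
starts at the onset with zero lag, so detection latency reflects the rule,
not a simulated human response — absolute synthetic timings are not
comparable to experimental ones.

The same pipeline is scriptable from the shell:

```sh
fallseg simulate --subjects 1 --seed 1 --out data/
fallseg rank --in data/ --seed 1 --out results/
fallseg evaluate --in data/ --combos ALL,F-H --hidden-units 20 \
        --max-epochs 100 --seed 1 --out results/
```

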