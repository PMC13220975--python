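# motistate

Analysis of **motivation-state fluctuations and learning** in head-fixed
go/no-go training data, together with a synthetic session generator that
emulates the recordings end to end.

Head-fixed mice trained on a whisker go/no-go task fluctuate between
motivation states on a timescale of minutes while they learn the task
over days. `motistate` implements the full analysis chain for such
datasets:

1. **Features** — per-trial performance metrics (whole-trial lick rate,
   binary correctness) and eight *nonperformance* variables not directly
   controlled by task contingencies: prestimulus lick count, wheel speed
   (signed cm/s from a wrapping 0–3.3 V encoder rescaled to the 36 cm
   wheel circumference), pupil diameter and eyelid aperture (top–bottom
   extent of tracked keypoint octagons), prestimulus power-spectrum
   slope (PSS: slope of log₁₀ power vs log₁₀ frequency, 1–100 Hz),
   stimulus-evoked LFP, prestimulus MUA band power (500–5,000 Hz) and
   stimulus-evoked MUA.
2. **State labeling** — trials are smoothed with a 50-trial moving mean
   (1-trial steps, independent per session), concatenated across days
   per mouse, and split along two binary axes: *low/no licking* (at or
   below the second bin of a 100-bin trial-count histogram) and *good
   performance* (at or above the mouse's 75th correctness quantile).
   Merging the axes yields the tripartite states **persistent**
   (licking at chance performance), **disengaged** (low/no licking) and
   **attentive** (good performance).
3. **State decoding** — bagged ensembles of 30 fully grown decision
   trees predict the states from the smoothed nonperformance variables
   (25-trial block shuffle, 1:1 swapped-halves split, held-out scores
   recombined chronologically). Accuracy is pooled one-vs-rest ROC AUC
   over groups of iterations with random predictor pools of size 1–8,
   summarized by a nonlinear least-squares fit of
   `AUC(m) = a − b·exp(−k·m)`. Controls: cross-mouse prediction, trial
   (row) shuffling, full shuffling, predictor subsets, and
   leave-one-predictor-out GLM/multinomial-regression t-statistics with
   Friedman tests against shuffled responses.
4. **Training progression** — trials sorted into eight state × outcome
   subcategories, mapped onto a normalized 99-block progression axis
   (early/mid/late stages of 33 blocks), peristimulus traces averaged
   on an 80-bin [−1, +4] s axis and compared across stages with a
   split-plot two-way ANOVA plus Tukey-protected per-bin comparisons.
5. **Laminar profiling** — peristimulus CSD (second spatial derivative
   of the LFP) and MUA-power maps over the 45 topmost probe channels
   (20 µm spacing, ~0.9 mm), reduced to normalized depth profiles, with
   deep-MUA landmark QC (~0.6 mm), whisker-pair somatotopy selection
   and depth-band (0.20–0.36 mm CSD / 0.50–0.64 mm MUA) Friedman
   comparisons.

The synthetic generator (`motistate.synth`) produces multi-mouse
bundles — trial tables, lick events, encoder voltage, keypoint
octagons, laminar LFP/raw epochs — whose latent states follow a
semi-Markov chain with ~150-trial dwell times, within-session
disengagement drift and across-day learning, so every stage above is
testable without any recordings.

## Worked example

```python
import motistate as ms
from motistate import config as cfg, features as feat, labeling, prediction

c = ms.MouseConfig(mouse_id="m1", n_sessions=7, trials_per_session=500, seed=11)
timeline = ms.gen_state_timeline(c)
trials = ms.gen_trials(timeline, c)
table = ms.gen_feature_table(timeline, trials, c, rng=5)  # fast feature path
table["mouse"] = "m1"

labels = labeling.label_states(table)
print(labels.labels["state"].value_counts().to_dict())
# {'persistent': 1999, 'attentive': 906, 'disengaged': 595}

smoothed = feat.smooth_per_session(table, list(cfg.NONPERFORMANCE_VARS))
run = prediction.train_predict(smoothed, labels.labels["state"], seed=1)
for state in cfg.STATES:
    roc = prediction.pooled_roc([run], labels.labels["state"], state)
    print(state, round(roc.auc, 3))
# persistent 0.961
# disengaged 0.975
# attentive 0.986
```

The three AUC values are held-out one-vs-rest discrimination of each
state from the eight nonperformance variables alone — far above the 0.5
chance level, i.e. motor and physiologic activity carries the
motivation state even though lick rate and correctness are excluded
from the predictors.

The full pipeline (simulate → features → label → decode → peristimulus
→ laminar) runs on a reduced dataset with

```sh
motistate run-all --out out/ --seed 0
```

and writes `features.csv`, `labels.csv`, AUC tables, ANOVA tables and a
JSON manifest of every seed and parameter.

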