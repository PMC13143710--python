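# gazephase

Time-resolved gaze-state dynamics of aesthetic judgment.

When people view an artwork until they feel able to judge its beauty,
their gaze typically moves from broad *exploration* to *convergence* on
a few regions. `gazephase` is a pipeline for asking **when** that
transition happens and whether its timing differs between artworks that
end up rated high versus low. It is aimed at eye-tracking and visual
aesthetics researchers working with self-paced viewing data (and at
anyone who wants a tested, seeded synthetic benchmark for scanpath
state-dynamics methods).

## The model and the indices

Scanpaths for each stimulus are modelled with a Gaussian-emission hidden
Markov model: each hidden state is a region of interest (ROI) emitting
2-D gaze positions from *N*(μ_k, Σ_k), with a row-stochastic transition
matrix over the K states (default K = 14). Fitting is maximum-likelihood
Baum–Welch over all observers' sequences for one stimulus, with two
constraints projected in after every M-step so the ROIs stay
interpretable: each ROI's ellipse area must lie within 0.1–5% of the
image area, and axis lengths are clamped to mean ± Nσ across ROIs.

Each decoded episode is aggregated over the first 30 s in 3-s bins.
With p the mean posterior state distribution of a bin:

- **Hnorm** = −Σᵢ pᵢ ln pᵢ / ln K — dispersion of gaze over states
  (1 = exploratory, 0 = converged)
- **MaxP** = maxᵢ pᵢ — dominance of the strongest state
- **NeffNorm** = exp(H)/K — effective number of states used
- **TV(t)** = ½ Σᵢ |pᵢ(t+1) − pᵢ(t)| — reorganisation between
  consecutive bins
- **Switch** = (1/(T−1)) Σₜ 1(Sₜ ≠ Sₜ₊₁) — switching rate on the
  Viterbi path

Artworks are split into high/low halves by mean within-participant
min–max-normalised rating; every bin × metric cell is compared between
groups with a Wilcoxon rank-sum test, a rank-biserial effect size
r = z/√N, and Benjamini–Hochberg FDR over the whole family.
Supplementary analyses cover fixations on annotated depth-cue points
(with cumulative aggregation) and the gaze-cascade curve of 2AFC
preference trials.

A seeded generator (`gazephase.simulate`) produces full synthetic
studies with the assumed structure — 35 participants × 12 artworks,
300 Hz, self-paced durations around 13.1 s, and an earlier
exploration→convergence onset for high-rated artworks — so every stage
is testable end to end without external data.

## Worked example

```python
import numpy as np
from gazephase import (GenerativeConfig, simulate_study, detect_fixations,
                       ConstrainedGaussianHMM, forward_backward,
                       metrics_table, GroupComparison, assign_groups,
                       normalize_ratings)

cfg = GenerativeConfig(n_participants=10, n_artworks=6, n_high=3,
                       sampling_rate_hz=60.0, K_true=6, seed=3)
data, gt = simulate_study(cfg)

# fit one artwork's gaze-state model on I-DT fixation centroids
eps = [e for e in data.episodes if e.artwork_id == "art00"]
for e in eps:
    e.fixations = detect_fixations(e)
res = ConstrainedGaussianHMM.from_episodes(eps, n_states=6).fit(
    n_restarts=5, seed=0)
print(res.summary())
```

```
Constrained Gaussian HMM gaze-state fit
=======================================================
states (K):          6
sequences:           10
observations:        425
log-likelihood:      900.275
best restart:        3 (of 5)
EM iterations:       38 (converged)
constraint events:   52

state   mean_x   mean_y   area_%  occupancy
    0    0.184    0.447    1.110      0.293
    1    0.182    0.301    0.529      0.263
    2    0.727    0.561    3.215      0.191
    ...
```

Every ROI area sits inside the 0.1–5% band; states are ordered by
stationary occupancy. Decoding all episodes and running the group
comparison:

```python
decoded, times = {}, {}
for ep in data.episodes:
    key = (ep.participant_id, ep.artwork_id)
    decoded[key] = forward_backward(gt.models[ep.artwork_id],
                                    np.column_stack([ep.x, ep.y]))
    times[key] = ep.t
table = metrics_table(decoded, times)
groups = assign_groups(normalize_ratings(data.ratings))
print(GroupComparison(table, groups).fit().summary())
```

```
Group comparison: high- vs low-evaluation artworks
=======================================================
observation unit:        episode
testable bin x metric:   24
p < 0.05 before FDR:    15
q < 0.05 after BH-FDR:  15

   metric     window       z         p       r       q
     MaxP     9-12 s    6.65    0.0000   0.859   0.000
    Hnorm     9-12 s   -6.65    0.0000  -0.859   0.000
 NeffNorm     9-12 s   -6.65    0.0000  -0.859   0.000
    ...
```

The negative z for Hnorm/TV in the 6–12 s windows says the
high-evaluation group's gaze-state distribution is already less
dispersed and more stable there — it converged earlier (this toy study
uses onsets of 6 s vs 12 s, so the effect is large by design).

The same pipeline runs from the shell:

```bash
gazephase run-all --seed 7 --out runs/demo
cat runs/demo/report.txt
```

which writes the gaze/ratings tables, per-artwork model bundles, the
tidy metrics table, the comparison table with q-values, and a phase
report (early 0–6 s / middle 6–12 s / late 12–30 s).

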