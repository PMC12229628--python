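# idionet

Person-specific (idiographic) symptom-network analysis for daily diary data
from people with psychotic disorders — and, more generally, for any intensive
longitudinal study that records a panel of ordinal symptom ratings once per
day and wants to ask: *what does each individual's symptom network look like,
how much do those networks differ between individuals, and is network density
associated with clinical relapse?*

## What it computes

For each participant with a day × item diary (e.g. 14 items such as
*anxious*, *cheerful*, *suspicious* rated 1–7), after reverse-coding the
positively valenced items, excluding participants with < 100 diary days or
stereotyped responding, and removing statistically redundant items
(goldbricker-style test on dependent overlapping correlations), the package
estimates a **non-regularized weighted partial-correlation network** — the
Gaussian graphical model obtained from the precision matrix Ω = R⁻¹ of the
participant's item correlation matrix R:

    w_ij = −Ω_ij / √(Ω_ii · Ω_jj)        (edge weight; w_ii = 0)

Each edge is the correlation between two symptoms conditional on all other
symptoms. From each network it derives, using edge lengths ℓ_ij = 1/|w_ij|:

- **strength** — Σ_j |w_ij|,
- **closeness** — 1 / Σ_j d(i, j) over shortest-path distances d,
- **betweenness** — Brandes pair-fraction count of geodesics through a node,
- **ASPL** and **global efficiency** — mean shortest-path length over
  reachable pairs and mean reciprocal shortest-path length over all pairs
  (density measures: dense networks ⇒ low ASPL, high efficiency),
- per-item **SD** and **RMSSD** (day-to-day) variability.

Inter-individual variability is summarised as the SD of each centrality
index per symptom across the sample, and relapse vs non-relapse groups are
compared (Welch t and Wilcoxon rank-sum, raw and within-person rank indices)
with Benjamini–Hochberg FDR control at q ≤ 0.10 — the hysteresis hypothesis
predicts denser networks in relapsers.

Because real diary cohorts of this kind are not public, the package ships a
first-class synthetic cohort generator (`idionet.synth`) with known
ground-truth networks per participant: ordinal-probit discretisation of a
latent Gaussian graphical model, participant heterogeneity, relapse-group
edge scaling, AR(1) carry-over, and missing days. Every stage of the
pipeline is validated against that ground truth.

## Worked example

```python
import numpy as np
from idionet import (CohortConfig, generate_cohort, estimate_network,
                     centrality_profile, density_metrics)

cohort, truth = generate_cohort(CohortConfig(seed=7))   # 30 participants
diary = cohort.diaries["P01"]                           # 222 diary days, 13 items
net = estimate_network(diary)                           # partial-correlation GGM
print(centrality_profile(net).values.head(4).round(4))
dm = density_metrics(net)
print("ASPL", round(dm.aspl, 3), "efficiency", round(dm.global_efficiency, 4))
iu = np.triu_indices(13, 1)
rmse = float(np.sqrt(((net.w - truth.partials["P01"])[iu] ** 2).mean()))
print("edge RMSE vs truth:", round(rmse, 4))
```

prints

```
        strength  closeness  betweenness
item01    1.0297     0.0105          2.0
item02    0.7580     0.0070          0.0
item03    1.6535     0.0120          8.0
item04    1.6463     0.0132         25.0
ASPL 8.301 efficiency 0.1462
edge RMSE vs truth: 0.0601
```

Strength is the summed absolute edge weight around each symptom; closeness
and betweenness are computed on 1/|w| edge lengths; ASPL ≈ 8.3 says the
average pair of symptoms is connected through paths equivalent to a direct
partial correlation of ≈ 0.12; the edge RMSE of 0.06 is the estimation error
against this participant's known ground-truth network at 222 observed days.

The same analysis end-to-end, from the shell:

```bash
idionet run --out results/run1 --seed 7            # synthetic cohort by default
idionet simulate --out sim --seed 7                # write diary.csv / labels.csv
idionet run --config my_study.yaml --out results/  # or point `inputs:` at CSVs
```

`run` writes per-participant network edge lists, metric/variability/density
CSVs, the dispersion table, the group-comparison table with BH-adjusted
p-values, and a `manifest.json` with the seed, config hash and per-file
digests (identical config + seed reproduces every file bit-for-bit).

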