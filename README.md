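# recovnet

Longitudinal functional brain-network recovery analysis for ROI-level
resting-state time series.

`recovnet` is built for studying how large-scale functional networks
(e.g. the language network and the cingulo-opercular / fronto-parietal
cognitive-control network) are disrupted after neurosurgery and how they
normalize as behaviour recovers. Its intended users are researchers who
have ROI time series (volumes × nodes) with per-volume motion traces,
per-subject language scores over up to five observation timepoints
(preoperative, 2 weeks, 1 month, 3 months, 6 months), and a healthy
control group — or who want to prototype such an analysis on a fully
synthetic cohort with known ground truth.

## The analysis

**Cleaning.** For each scan the initial 10 volumes are discarded, a
36-parameter nuisance design is regressed out (6 motion parameters,
white-matter, CSF and global signals, their temporal derivatives, and
all 18 squares), the residuals are band-pass filtered to 0.01–0.1 Hz
(zero-phase Butterworth), and high-motion volumes are scrubbed: every
volume with framewise displacement FD > 0.5 mm is removed together with
1 volume before and 2 after. A subject with fewer than 140 surviving
volumes is excluded.

**Connectivity.** Per network of interest, pairwise Pearson correlations
r over the surviving volumes, Fisher-transformed (z = atanh r) and
thresholded at r > 0.2 (sensitivity variants r > 0.1 and r > 0.3) to
eliminate weak connections.

**Global network properties.** On the thresholded weighted network with
edge length 1/w:

- FC strength — sum of suprathreshold edge weights;
- global efficiency, gE = mean over node pairs of 1/d(i,j), where d is
  the weighted shortest-path length (disconnected pairs contribute 0);
- local efficiency, lE = mean over nodes of the global efficiency of the
  subgraph induced by each node's neighbours.

Patient values are referenced to the control group as Z = (P − μ)/δ with
the control mean μ and sample SD δ.

**Language scoring and recovery.** The aphasia quotient

    AQ = (S_ss + S_com/23 + S_rep/10 + S_nam/10) × 2     (0–100)

summarizes spontaneous-speech, comprehension, repetition and naming
subscores. Recovery is *good* if AQ returns to 80% of the preoperative
baseline by 3 months or 85% by 6 months, else *poor*. The recovery
ratio, for AQ and for Z-scored network properties alike, is

    ratio = (chronic − subacute) / (pre − subacute)

with subacute = earliest post-operative observation and chronic = latest
chronic observation; trajectories with no transient decline to recover
from are capped at 1. Group-level inference uses paired t-tests against
baseline, pooled-variance two-sample t-tests, Pearson χ² tests, and
partial correlations (sex/age/education/grade covariates) between AQ and
network recovery ratios.

**Synthetic cohorts.** The `synthetic` module generates controls and
longitudinal patients as stationary Gaussian AR(1) node signals with
block-structured covariance; post-operative scans attenuate connectivity
around a designated peritumoral node set and its contralateral
homologues, decaying over timepoints, and AQ is a noisy monotone
function of the current attenuation — so every stage of the pipeline can
be tested against known ground truth.

## Worked example

```python
import recovnet as rn

summary = rn.summarize_cohort(rn.load_table2())
pre = summary["aq_by_timepoint"]["pre"]
print(f"pre-op AQ: {pre['mean']:.1f} +/- {pre['sd']:.1f} (n={pre['n']})")
for grp, r in summary["ratio_range_by_group"].items():
    print(f"{grp}-recovery AQ ratio range: {r['min']:.2f}-{r['max']:.2f} (n={r['n']})")
print("capped at 1:", summary["capped"])
```

prints

```
pre-op AQ: 90.1 +/- 9.0 (n=34)
good-recovery AQ ratio range: 0.49-1.17 (n=28)
poor-recovery AQ ratio range: 0.13-0.68 (n=6)
capped at 1: ['P204', 'P210']
```

i.e. in the packaged 34-patient cohort, patients who recovered well
regained 49%–117% of their transient AQ decline, while poor-recovery
patients regained only 13%–68%; two patients had already recovered by
their subacute observation and are capped at 1.

A full synthetic run — simulate, clean, connectivity, graph metrics,
Z-scores, recovery statistics:

```python
from recovnet.pipeline import RunConfig, run_pipeline
from recovnet.synthetic import CohortConfig

cfg = RunConfig(cohort=CohortConfig(n_controls=10, n_patients=4,
                n_nodes_per_network={"language": 16, "co_fp": 8}), seed=42)
report = run_pipeline(cfg)
print(report.zscores.groupby("timepoint")["global_efficiency"].mean().round(2))
```

```
timepoint
pre   -0.04
w2    -0.62
m1    -0.37
m3     0.17
m6    -0.11
```

showing the injected pattern: near-control efficiency preoperatively, a
drop at the 2-week nadir, and normalization through the chronic phase.
The same analysis is available from the shell via the `recovnet` CLI
(`simulate`, `preprocess`, `fc`, `metrics`, `recovery`, `report`, `all`).

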