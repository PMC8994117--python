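# Methods

This note documents the models, conventions and design choices behind
`recovnet`, in the order data flows through the pipeline.

## Synthetic cohort model

Node signals are drawn from a stationary multivariate Gaussian AR(1)
process: x_t = φ x_{t−1} + ε_t with innovation covariance (1 − φ²)C and
the first sample drawn from the stationary distribution, so the
cross-sectional covariance equals the target C at every volume. AR(1)
was chosen as the minimal stationary process with a controllable
cross-sectional covariance; no haemodynamic response, drift or 1/f
structure is modelled, because the preprocessing that would remove such
structure is itself under test and must not be entangled with the
generator.

The target C is a block correlation matrix: 1 on the diagonal,
`base_within_corr` (default 0.45) between nodes of the same network,
`base_between_corr` (default 0.08) between networks. If the requested
structure is not positive semi-definite it is repaired by eigenvalue
clipping at 0 followed by rescaling to unit diagonal; a repair that
changes any entry by more than 0.05 aborts generation, and any
non-trivial repair is reported as a warning.

A shared "physiological" AR(1) component g_t is added to every node with
amplitude 0.5 and is exposed as the measured global signal. This matters:
if the global signal were instead taken as the mean of the analyzed
nodes, global-signal regression would remove the networks' common
variance and destroy the block structure (the classic mean-regression
artifact on small node sets). In real data the global signal is
estimated from the whole brain, of which the analyzed networks are a
small part, and the shared-component construction emulates that. When no
measured global signal accompanies user data, the node mean is the
fallback, with this caveat.

**Disruption and recovery.** A contiguous fraction (`tumour_node_frac`,
default 0.25) of one hemisphere's nodes in the first network is
designated peritumoral. Post-operatively, off-diagonal covariance
entries incident to those nodes *or their contralateral homologues* are
multiplied by (1 − a), where a = `disruption_frac` ×
`recovery_profile[timepoint]`. The homologue of a node is the node with
the same within-hemisphere index on the opposite side — well defined
because the built-in node sets are hemispherically symmetric. The
default recovery profile is 1.0 at 2 weeks (the nadir, required by
construction), 0.7 at 1 month, 0.25 at 3 months and 0.1 at 6 months,
giving the transient-decline-then-recovery shape the analysis expects.
No estimate of the true physiological effect size exists, so
`disruption_frac` defaults to 0.5, calibrated once so that subgroup
separation is detectable by the downstream estimator at desk scale; the
parameter-recovery tests vary it over {0.2, 0.5, 0.8}.

**Language link.** AQ(tp) = baseline − slope × a(tp) × 100 + N(0, σ),
clamped to [0, 100], with slope 0.4 and σ = 2 AQ points by default;
baselines are drawn from N(90.1, 9), matching the packaged cohort's
preoperative distribution. Subscores are back-solved proportionally
(every subscore at the same fraction of its maximum), which reproduces
the AQ exactly under the AQ formula; the true subscore coupling is
unspecified, and nothing downstream depends on it. Motion traces are
random walks (step SD 0.02 mm) in the translations with one transient
0.8 mm spike per post-operative scan; rotations are held at 0, which
makes the motion-derived nuisance columns rank deficient — the regression
handles this by least-norm solution and a warning, and it exercises that
code path routinely.

What the generator does **not** emulate: spatial structure (no voxels,
no lesion geometry), physiological noise spectra, scanner drift,
inter-site variability, or realistic missing-visit patterns. Passing
tests therefore demonstrate that the estimation pipeline recovers the
statistical structure it assumes, not that it is robust to every
artefact of real acquisitions.

## Preprocessing conventions

Stage order is fixed: discard the first 10 volumes → nuisance regression
→ band-pass → scrubbing. Scrubbed volumes are removed, never
interpolated, and censoring is idempotent.

- **FD** uses the Power formulation, Σ|Δtranslation| + r·Σ|Δrotation|
  with r = 50 mm, FD(first volume) = 0. The threshold (0.5 mm), the
  censoring window (−1/+2) and the 140-volume exclusion guard are the
  study's stated values.
- **Nuisance design**: 9 base signals (6 motion + WM + CSF + global),
  backward-difference derivatives with 0 at the first volume (chosen
  over a forward difference for symmetry with censoring at the series
  start), and element-wise squares of all 18 — 36 columns; dropping the
  global signal removes it, its derivative and both squares, leaving 32.
  An intercept is always added at fit time. Rank-deficient designs use
  the least-norm solution with a warning; residual orthogonality to the
  design holds either way (tested to |Xᵀe|/n < 1e−8).
- **Band-pass**: 4th-order Butterworth applied forward and backward
  (zero phase). At TR = 2 s the contract is ≥95% amplitude at 0.05 Hz
  and ≤10% at 0.2 Hz, verified by FFT.

## Connectivity and graph metrics

Thresholding is always expressed on r with strict inequality
(r > threshold), so negative correlations never survive a positive
threshold, and edge sets are nested across 0.1/0.2/0.3 by construction.
Surviving edges carry Fisher-z weights by default; raw-r weights are a
configuration switch for sensitivity checks, since which scale the
metrics were computed on is ambiguous in the source analyses.

Efficiency metrics use the standard weighted convention, edge length
= 1/weight. The description of path length as a count of edges suggests
a binary reading, but the analysis is explicitly weighted; the weighted
convention is adopted and this note records the discrepancy. gE averages
1/d over unordered pairs (equal to the ordered average for undirected
graphs); disconnected pairs contribute 0. lE keeps the original weights
between neighbours in each neighbourhood subgraph (no rescaling by the
centre node's weights) and nodes with fewer than two neighbours
contribute 0 while remaining in the denominator. Implementation is
Dijkstra via `scipy.sparse.csgraph`; tests verify equality (1e−10)
against exhaustive path enumeration for all graphs up to 6 nodes and
against networkx Dijkstra independently.

Z-scores use the sample (n−1) control SD; zero control variance is an
error rather than a silent 0 or infinity. Lesioned-node exclusion drops
the listed nodes from the patient *and* from the control reference used
for that patient, so patient and reference are always computed on the
same node set.

## Recovery statistics

- **Classification**: good iff AQ(3 m) ≥ 0.80 × AQ(pre) or AQ(6 m) ≥
  0.85 × AQ(pre); a missing timepoint skips its clause. In the packaged
  cohort two patients (P044, P106) satisfy this rule yet carry the
  "poor" label; the package follows the stated rule, reports them as
  rule–label mismatches, and uses the shipped labels for grouped
  summaries rather than guessing an unstated criterion.
- **Recovery ratio**: subacute = earliest post-operative observation,
  chronic = latest available chronic observation. This pairing
  reproduces all four published group-range endpoints, whereas
  preferring 3 months as the chronic value does not. The ratio is capped
  at 1 (flagged `capped`) when the denominator pre − subacute ≤ 1e−9
  (no transient decline), and also when the chronic value shows no gain
  over the subacute value while the subacute value already meets the
  good-recovery criterion against baseline — the "recovered within the
  subacute phase" situation of P204 and P210, whose ratios the source
  cohort sets to 1 by hand. Both conditions generalize that ad-hoc
  handling; a denominator-only rule would assign those two patients
  negative ratios.
- **Inference**: paired and pooled-variance two-sample t-tests (pooled
  df matches the reported degrees of freedom), Pearson χ² without
  continuity correction, and partial correlation via double
  residualization with p from t = r√((n−k−2)/(1−r²)). No multiple-testing
  correction is applied by default (a Benjamini–Hochberg helper exists
  but is opt-in), matching the uncorrected reporting convention.

## Problem sizes and numerical tolerances

The test suite and the pipeline's own checks run at desk scale, chosen
as the package's own trade-off between statistical resolution and
turnaround: Monte-Carlo covariance-recovery checks use 10⁵ volumes
(±0.01 tolerance); parameter-recovery checks use 16-node networks,
8 controls and 3 patients per seed over 50 seeds per disruption level;
graph-metric oracle equivalence uses 200 random graphs of ≤6 nodes at
1e−10; linear-algebra identities are asserted at 1e−10–1e−12. A full
desk-scale cohort (26 controls, 34 patients × 5 timepoints, 68 + 18
nodes, 240 volumes) runs in well under 5 minutes on one CPU.

## Known limitations

- The generator's effect sizes are self-calibrated, not fitted to
  patient physiology; absolute Z-score magnitudes in simulations should
  not be read as clinical predictions.
- Edge-strength bins ("fair" [0.2, 0.4), "moderate" [0.4, 0.6),
  "strong" [0.6, 1]) are a descriptive package convention with no
  inferential role.
- Built-in node tables carry names, hemispheres and region labels;
  MNI coordinates are optional metadata and the per-region subdivision
  counts of the 68-node language set are package choices, as the exact
  parcel list lives in atlas supplementary material.
- No voxel-level processing, no task-activation analysis, no survival or
  mixed-effects longitudinal modelling.
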