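# ictonet

Computational biomarkers of photosensitive epilepsy from resting interictal
EEG: phase-locking functional networks, theta-model simulation of
seizure-like dynamics, and brain/node ictogenicity with group-level
nonparametric statistics.

## The problem

People with photosensitive epilepsy show a photoparoxysmal response (PPR)
to flashing light, but detecting that susceptibility currently requires a
stimulation protocol. This package implements a stimulation-free
alternative: infer a functional brain network from a few 20 s segments of
resting 20-channel scalp EEG, place a computational model of ictogenicity
on the network, and quantify in silico

- **BNI** (brain network ictogenicity) — the mean fraction of simulated
  time the network's nodes spend in the seizure-like state, robustly
  summarized as the integral of BNI(K) over the coupling range
  K ∈ [1, 40]; and
- **NI** (node ictogenicity) — for each electrode *i*, the normalized drop
  in BNI after deleting that node at the coupling K\* where the intact
  network sits at BNI = 0.5:
  NI(i) = (BNI_pre − BNI_post(i)) / BNI_pre.

The group-level claim this pipeline operationalizes: PPR individuals do not
show globally elevated BNI, but their right-occipital NI (electrode O2) is
elevated — occipital hyperexcitability is an enduring, interictally
detectable trait.

## The pipeline

1. **Preprocess**: resample to 250 Hz, zero-phase 6–9 Hz Butterworth
   band-pass (order 4, forward–backward), common-average reference.
2. **Networks**: per channel pair, PLV = |mean exp(iΔφ)| and mean lag
   τ = arg Σ exp(iΔφ) from Hilbert phases; discard near-zero-lag pairs
   (|τ| ≤ 2π/fs, volume conduction) and pairs whose PLV does not beat 95 %
   of 99 IAAFT-surrogate PLVs.
3. **Simulate**: theta neurons dθ/dt = (1−cos θ) + (1+cos θ)·I(t) with
   I0 = −1.2, noise σ = 0.6, coupled through the PLV matrix; count
   rotations as seizure-like time.
4. **Ictogenicity**: BNI-hat (area of BNI(K) over [1, 40]), calibration of
   K to BNI = 0.5, single-node deletion NI; subject values are means over
   three segments.
5. **Statistics**: one-sided rank-sum tests for BNI and occipital NI,
   exploratory two-sided tests for the other 18 nodes, Holm correction per
   family, BCa bootstrap median-difference effect sizes, ROC/AUC via the
   Mann–Whitney identity, plus relative alpha-power and connectivity-
   strength comparisons.

Because the clinical recordings are not public, the package ships a
synthetic cohort generator (latent narrowband source mixtures with exact,
independently controllable pairwise coherence and lags) that emulates the
study design: a PPR-like group whose occipital channels load more strongly
on the globally shared rhythm, versus a control group. See
`docs/methods.md` for the model, assumptions, and limitations.

## Worked example

```python
import numpy as np
from ictonet import (ranksum_from_summary, holm, cohort_baseline_spec,
                     generate_segment, preprocess_segment, build_network,
                     ThetaModelParams, calibrate_K, node_ictogenicity,
                     node_strength)

# 1. reproduce published group statistics from the printed rank sums
#    (26 PPR vs 20 non-PPR subjects)
z_o2, p_o2 = ranksum_from_summary(724, 26, 20, "right")
z_o1, p_o1 = ranksum_from_summary(652, 26, 20, "right")
p_corr = holm([p_o2, p_o1])
print(f"O2: z = {z_o2:.2f}, Holm-corrected one-sided p = {p_corr[0]:.3f}")
print(f"O1: z = {z_o1:.2f}, Holm-corrected one-sided p = {p_corr[1]:.2f}")

# 2. infer a functional network from one synthetic resting segment
#    (reduced size: 10 s at 125 Hz, 19 surrogates)
spec = cohort_baseline_spec(seed=11, fs=125.0, duration=10.0)
seg = preprocess_segment(generate_segment(spec), target_fs=125.0)
net = build_network(seg, n_surrogates=19, seed=2)
print(f"network: {int((net.weights > 0).sum() / 2)} significant edges")

# 3. calibrate the simulator and score three electrodes
params = ThetaModelParams(n_steps=100_000)
k_star = calibrate_K(net, params, n_reps=4, seed=0)
ni = node_ictogenicity(net, k_star, params, n_reps=4,
                       nodes=["O1", "O2", "CZ"], seed=0)
print(f"K* = {k_star:.1f}")
for ch, val in ni.items():
    print(f"NI[{ch}] = {val:+.3f}   strength = {node_strength(net, ch):.1f}")
```

Output:

```
O2: z = 2.49, Holm-corrected one-sided p = 0.013
O1: z = 0.90, Holm-corrected one-sided p = 0.18
network: 72 significant edges
K* = 38.2
NI[O1] = +0.036   strength = 11.0
NI[O2] = -0.001   strength = 8.9
NI[CZ] = +0.038   strength = 5.4
```

The first two lines are the published occipital NI comparison reproduced
exactly from its summary statistics: elevated right-occipital ictogenicity
in the PPR group (O2 significant after Holm correction, O1 not). The rest
scores one synthetic resting-state network: K\* is the coupling at which
the network's simulated seizure burden reaches 50 %, and each NI value is
the fractional drop in that burden when the electrode's node is deleted —
here a baseline (unboosted) network, so occipital NI is small — at this
run length indistinguishable from a central electrode's — whereas in a
PPR-like cohort the boosted occipital nodes stand out.

## Command line

```bash
ictonet simulate-cohort cohort/ --n-ppr 26 --n-non-ppr 20 --boost 0.2
ictonet run-all cohort/ results/ --fast --seed 1
ictonet print-config          # full parameter schema with defaults
```

`run-all` writes per-subject profiles, the three Holm-corrected test
families, and ROC metrics as CSVs. `--fast` shrinks simulation sizes for
smoke runs; a flat `key=value` config file plus CLI flags controls
everything else.

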