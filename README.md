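# pkamem

Analysis toolkit for constant-pH molecular-dynamics studies of
membrane-inserting peptides — pH-low insertion peptides (pHLIPs) and their
variants — whose therapeutic targeting hinges on the proton binding
affinity of a key aspartate inside the lipid bilayer.

A pH replica-exchange (pHRE) simulation produces, per frame, the replica's
pH, the residue's signed membrane-insertion depth, and the binary
protonation states of the titrable sites.  `pkamem` turns those records
into depth-resolved pKa profiles and the structural/electrostatic context
needed to interpret them, and also fits the companion spectroscopy data
(pH titrations, stopped-flow kinetics).  Every stage can be exercised on
synthetic data with known ground truth, so the whole pipeline is testable
by parameter recovery without any trajectory files.

## What it computes

**Insertion-binned pKa profiles.**  Frames are sliced into 0.5 Å bins of
insertion depth (negative = below the local phosphate surface).  Per bin,
the average protonations of each pH replica form a titration curve that is
fitted with the Hill equation

```
⟨prot⟩(pH) = 1 / (1 + 10^{n (pH − pKa)})
```

after three screening criteria: (1) ≥ 10 frames of each protonation state
per (replicate, pH) cell, (2) data from ≥ 3 replicates with ≥ 2 replicas
each, (3) monotonicity of the pooled curve within 0.05.  Errors are
Bayesian-bootstrap standard deviations (flat Dirichlet weights over the
average-protonation samples, 1000 resamples).  `pka_ins` summarises the
profile over the deep-membrane window (default −6 to −5 Å), the
computational analogue of the experimental insertion pK.

**Membrane geometry.**  Local phosphate-surface reference (≥ 10 atoms
within 6 Å in xy, with capped radius expansion), signed insertion depth,
radial half-thickness deformation scans per leaflet (0.5 Å annuli, bulk
beyond 15 Å), and TM tilt angles.

**Interaction-shell census.**  Group-level counts of phosphates, cholines
and water hydrogen bonds within the 5.2 Å first-shell cutoff, plus
Asp–Arg minimum side-chain distances and salt-bridge occupancy (4.0 Å).

**pH replica exchange.**  The Metropolis swap criterion
`p = min{1, 10^{(pH_m − pH_l)(x_i − x_j)}}` with exchange bookkeeping and a
toy ladder simulator for efficiency studies.

**Experimental fits.**  (0,1)-normalised Hill fits of pH-dependence data,
and multiexponential fits `I(t) = I∞ + Σ aᵢ exp(−t/τᵢ)` of stopped-flow
traces with the chi-square model-selection rule (stop at reduced
χ² < 3×10⁻⁵, or when one more term improves χ² by less than 10×).

**Feature attribution.**  Per-bin shell-property profiles interpolated at
the bin pKa, assembled across variants into a feature matrix and ranked
with a 2500-tree random-forest regressor (max depth 20).

## Worked example

Generate a synthetic pHRE data set whose true pKa rises from 6.0 at the
phosphate surface to 7.0 at −6 Å (a desolvation-like shift), then recover
the profile:

```python
from pkamem import synthetic_data as syn, pka_profiles as pk

truth = syn.GroundTruthProfile.linear(depth_range=(-6.0, 0.0), pka_range=(7.0, 6.0))
cfg = syn.SyntheticConfig(n_replicates=5, n_frames=5000, seed=1,
                          depth_bounds=(-6.0, 0.0))
frames = syn.generate_phre_frames(truth, cfg)          # 100000 frames
profile = pk.build_profile(frames, pk.ProfileConfig(n_boot=1000, seed=1))
print(profile.to_frame().round(3).to_string(index=False))
print(pk.pka_ins(profile).value)
```

Output (columns abridged):

```
 bin_low  bin_high   pka  hill_n    sd  n_frames
    -6.0      -5.5 6.940   1.024 0.017      4402
    -5.5      -5.0 6.864   1.004 0.018      4439
    -5.0      -4.5 6.791   1.001 0.017      4413
    -4.5      -4.0 6.667   1.081 0.014      4319
    ...
    -0.5       0.0 6.057   1.002 0.015      5696
pKa_ins over [-6, -5] Å: 6.90
```

Each row is one criteria-passing insertion bin: its fitted pKa and Hill
coefficient, the bootstrap standard deviation, and the frame count.  The
fitted trend tracks the generating truth (6.0 → 7.0 across 0 → −6 Å;
true deep-window mean 6.94), and the recovered Hill coefficients sit at
the generating value of 1.

A command-line interface mirrors the library:

```
pkamem simulate --preset desolvation-shift --seed 1 --out data/
pkamem profile data/frames_desolvation-shift.tsv --out profile.tsv
pkamem phre-sim --ladder 5.00,5.75,6.50,7.25 --pkas 6.5,6.0,5.5,4.5 --cycles 10000
pkamem fit-kinetics trace.tsv --exclude-prefix 0.02
pkamem run-all --config config.yaml --out run/
```

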