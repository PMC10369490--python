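# Methods

This note documents the models, estimators and numerical choices behind
`pkamem`, and what the synthetic-data experiments do and do not establish.

## Protonation model and pKa profiles

A titrable site at insertion depth z and solution pH is treated as a
two-state system whose protonated fraction follows the generalised
Henderson–Hasselbalch (Hill) form

    f(pH; z) = 1 / (1 + 10^{n(z) (pH − pKa(z))}),

with the depth dependence of pKa carrying the physics: desolvation raises
the pKa of an anionic residue as it buries, while a stabilising positive
partner (a salt-bridging arginine) lowers it.  The pipeline estimates
pKa(z) piecewise by slicing frames into half-open 0.5 Å insertion bins
anchored at integer multiples of the width (the generating convention for
`[-2.5, -2.0)` style bins) and fitting each bin's titration curve.

Insertion depth is the residue z minus a local surface reference: the mean
z of at least 10 phosphate atoms within 6 Å laterally (minimum-image), the
radius widening in 1 Å steps to a 12 Å cap when support is short.  The cap
is deliberate — averaging distant lipids would silently blur the reference
— so running out of radius is an error, not a fallback.

### Screening criteria

Three screens guard each bin before fitting:

1. **State counts** — every (replicate, pH) cell with data must hold at
   least 10 frames of each protonation state.  The check reports the
   strict verdict; `build_profile` then applies a configurable remedy,
   defaulting to dropping the whole pH level from that bin when any of its
   cells is undersized (`state_count_remedy="drop_ph"`).  Dropping whole
   levels rather than individual cells matters: discarding only the
   offending cells conditions the retained cells on their own outcome and
   measurably biases the fitted pKa toward the minority state (~0.02–0.05
   pK units at marginal cells in our recovery experiments).  The
   alternatives ("drop_cells", "drop_bin") are config-selectable.
2. **Replicate coverage** — at least three replicates, each contributing
   at least two replicas, evaluated per bin over the data that will enter
   the fit.
3. **Monotonicity** — the pooled average protonation may not rise by more
   than 0.05 from one pH to the next.  Violating pH levels are dropped
   from the fit by default ("drop_ph"); discarding the bin is the
   alternative.

A bin must retain at least three pH levels after the remedies; otherwise
it is rejected and recorded with its criteria ledger.

### Fitting and weighting

The fit points are the per-cell average protonations (cells are
(replicate, time-block, replica, pH) groups; see below).  Cells are
weighted by their frame counts.  A cell mean's sampling variance scales as
1/n, so frame-count weighting is the inverse-variance choice and makes the
fit equivalent to a pooled per-frame fit; with the strongly varying bin
occupancy that depth dynamics produce, an equally-weighted fit is
inefficient and its bootstrap error under-covers.  The Hill coefficient is
fitted freely by default (`fix_hill_n` pins it when the physics warrants a
single-site model).  Initialisation: pKa from the linearly interpolated
half-protonation pH, n = 1; Levenberg–Marquardt least squares.

### Uncertainties: Bayesian bootstrap over block averages

Errors are Bayesian-bootstrap standard deviations: each resample draws
flat Dirichlet weights over the average-protonation samples, refits the
weighted Hill curve, and the sd of the resampled pKa values is reported.
Resamples whose weighted pooled curve violates the monotonicity tolerance,
or whose fit fails, are discarded and redrawn (bounded at five times the
requested resamples; if none succeed the bin is dropped).

The samples are block averages: each replicate's production segment is cut
into equal-time blocks (default 8) and each (block, replica, pH) cell
contributes one sample.  Block averaging is the standard way to form
approximately independent samples from correlated simulation time series,
and it also stabilises the bootstrap when per-replicate bin occupancy is
heavy-tailed: with only ~5 replicate-level samples per pH the estimated sd
fluctuates enough that nominal 2-sd intervals cover only ~85% of ground
truths in our synthetic experiments, while the block-level bootstrap
restores close-to-nominal coverage (the improvement plateaus around 8
blocks, which we take as the default).

The first 30% of each replicate's time range is discarded as equilibration
by default, mirroring the usual discard of the leading segment of a
production run.

### Deep-window summary

`pka_ins` is the frame-count-weighted mean pKa over bins lying fully
inside the deep-membrane window, default [−6, −5] Å.  An empty window
yields an explicit undefined status rather than a number — sparse sampling
at depth is common (profiles can genuinely lack deep bins) and silently
extrapolating would misrepresent it.

## Membrane deformation scans

Leaflets are assigned by z relative to the instantaneous midplane (mean
phosphate z), which makes the scan robust to box drift.  Around a lateral
center, annuli of width 0.5 Å collect phosphate atoms out to 25 Å; a
leaflet's local half-thickness is the absolute distance of its mean z from
the midplane, and the deviation subtracts the leaflet's bulk
half-thickness pooled over all atoms beyond 15 Å.  Empty annuli are
reported as missing, never interpolated.  Single-snapshot annuli are
sparse near the center, so per-frame profiles are pooled count-weighted
across snapshots before interpretation; the synthetic −3 Å Gaussian dimple
is recovered within 10% from 30–40 pooled snapshots.

## Interaction-shell census

Counting is group-level (a phosphate counts once however many of its atoms
enter the shell) with a 5.2 Å first-shell cutoff taken as given from
radial-distribution minima.  The salt-bridge criterion is the conventional
4.0 Å between carboxylate and guanidinium heavy atoms.  Water hydrogen
bonds use the 3.5 Å donor–acceptor distance with the O–H···acceptor angle
within 30° of linear; both the geometry and the choice of counting the
whole choline headgroup versus its N atom are config-exposed, since
conventions differ between analysis tools.

## pH replica exchange

The swap criterion is the standard pH-RE Metropolis rule
p = min{1, 10^{(pH_m − pH_l)(x_i − x_j)}}, base 10, where x_i is the
protonated-group count of the replica currently at pH_m.  The sign
convention is pinned by a detailed-balance test:
p(a→b)/p(b→a) = 10^{ΔpH·Δx} for all tested tuples.  Neighbor pairs attempt
exchanges alternately (even pairs on even cycles, odd on odd).  The toy
ladder simulator redraws each replica's protonation count per cycle from
independent per-site logistic probabilities — deliberately decoupling
protonation from conformation — which suffices for efficiency studies:
efficiency is monotone non-increasing in the ladder step when the step
window is centered on the titrating region.  Ladder-step comparisons must
center the ladder on the site pKa; an off-center ladder can show the
opposite trend simply because no replica titrates.

## Experimental fits

pH-dependence data are min-max normalised to (0,1) with the acidic plateau
mapped to 1 (orientation detected from the acidic vs basic half-means),
then fitted with the Hill equation (Levenberg–Marquardt, pK initialised at
the interpolated half-response).  Kinetic traces are fitted with an offset
plus N exponentials; characteristic times are parametrised as log10(τ) so
they stay positive under an unconstrained optimiser, initial times are
log-spaced over the trace duration, and initial amplitudes come from a
linear solve at the fixed initial times.  N grows from 1, stopping at the
first reduced χ² below 3×10⁻⁵ (plain residual mean square on the
normalised intensity scale, which is what gives that threshold its
magnitude), or retaining N when the step to N+1 improves the reduced χ²
by less than a factor of 10; exhausting `max_n` returns the best candidate
flagged unconverged.  The factor-of-10 rule makes the selected N depend on
amplitude structure as well as time constants: a minor phase that improves
χ² less than tenfold is absorbed rather than resolved, which is the rule's
intent.  The synthetic kinetics presets therefore use fast-phase-dominated
amplitudes, the shape of fluorescence insertion traces.  An excluded
leading window (mixing artefacts, initial rises) is applied before
fitting; amplitude signs are unconstrained.

## Feature attribution

Per-bin, per-pH means of each shell channel (phosphate, arginine, choline,
water H-bonds) are linearly interpolated along pH and evaluated at the
bin's pKa; a pKa outside the ladder is flagged and clamped or dropped per
config.  Rows of (variant, bin) features plus the response pKa feed a
2500-tree random-forest regressor (max depth 20, bootstrap resampling).
The headline ranking is the impurity importance (normalised to sum to 1)
with the in-sample R² reported alongside the out-of-bag R²; the in-sample
figure is optimistic by construction, and the out-of-bag value is the
honest companion (near or below zero when the response is noise).
Permutation importance is available as a cross-check mode, but note that
in-sample permutation on an overfit forest does not vanish on noise — the
out-of-bag R² is the sharper null diagnostic.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed), with a named
substream per channel so adding one never perturbs another.  Defaults
mirror the targeted study conditions: five replicates, the four-replica pH
ladder 5.00–7.25 in 0.75 steps, 100 ns per replica sampled every 20 ps
(5000 frames).

* Depth follows a reflected Gaussian random walk (step sd 0.5 Å) inside
  configurable bounds; real depth dynamics are force-field driven and
  slower, so synthetic occupancy is more uniform than reality.
* Protonation is an independent Bernoulli draw per frame at the logistic
  probability of the local ground truth.  Real constant-pH engines
  resample protonation every cycle against a correlated conformational
  ensemble, so real average protonations carry autocorrelation the
  synthetic data lack.  Passing recovery tests therefore demonstrates the
  estimator chain is correct and calibrated under ideal sampling — not
  that any given real simulation is converged.
* The bilayer is a jittered phosphate lattice (64 Å² per lipid, optional
  multi-atom headgroups, 0.3 Å z-jitter) with additive parametric
  deformation fields; there are no lipid chains, curvature coupling or
  area fluctuations.
* Contact channels are Poisson (or deterministic) around user-supplied
  depth-dependent means; spectroscopy channels add Gaussian noise.
  Tautomers are collapsed into a single binary site.

Problem sizes in the recovery experiments (100 000 frames, 1000
bootstraps, 40 deformation snapshots, 500-replicate noisy refits) were
chosen so each estimate's statistical error is well below the effect being
recovered while a full run of the suite plus the acceptance script stays
comfortably on a single CPU.

## Known limitations

* Criterion 1's published wording does not say what happens to a bin that
  fails it; all three plausible remedies are implemented and the default
  (drop the pH level) is the least biased of them, but it is an
  interpretation.
* The bootstrap's 2-sd intervals are approximate; with four pH points and
  few replicates the coverage is near but not exactly nominal, so
  individual bins a little more than 2 sd from truth are expected at a few
  percent rate even under ideal sampling.
* The exchange simulator has no conformational degrees of freedom, so it
  cannot reproduce efficiency effects that stem from conformation–
  protonation coupling.
* The feature attribution inherits the usual caveats of impurity
  importances under correlated features: shell composition is strongly
  anti-correlated between partners, so importances describe the model's
  reliance, not causal contributions.
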