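# Methods

This note records the models, defaults and numerical choices behind `smbind`,
and what the synthetic benchmarks can and cannot establish.

## Synthetic binding traces

Each binding site is an alternating renewal process: exponential unbound
sojourns (mean `unbound_mean_s`) and bound sojourns from a two-component
exponential mixture. Defaults: weights (0.7, 0.3), time constants
(0.30 s, 2.34 s), weighted mean 0.912 s. The long component is anchored an
order of magnitude below the ~23 s mean fluorophore bleach time reported for
surface-adsorbed dye, which is why photobleaching of bound ligand is not
simulated. Per-concentration unbound means are calibrated so the stationary
per-site occupancy m_b/(m_b+m_u) equals the binomial-fit occupancies at the
five reference concentrations (10/30/60/100/200 nM → 0.08/0.10/0.12/0.21/
0.26). These occupancies do not follow a single-site mass-action law; the
calibration reproduces the printed values rather than forcing one.

Sojourn processes are started in the stationary regime (length-biased
component choice, exponential residual life), so short traces carry no
start-up bias in occupancy — this matters for the ±0.01 occupancy-recovery
check. A frame is "bound" if the site is bound at the frame midpoint
(midpoint sampling avoids the systematic bias of edge sampling; the frame
interval is 50 ms, 20 Hz).

Event amplitudes are drawn once per event from a skew-normal with mean
1000 au, SD 150 au and shape 3 (slight right skew); within-event frame noise
has SD = 50 + 0.1·I au (the observed linear intensity–noise relation), and
baseline noise (SD 50 au) is added only to frames where all four sites are
unbound, so noise from each bound ligand adds without quadrupling the
baseline noise. These amplitude/noise values are declared stand-ins chosen so
isolated events are clearly resolvable while summed noise makes one-frame
multi-ligand events marginal; the experimental distributions they replace are
not public.

Two generator modes exist: mixture-dwell sampling (default; used for
idealization benchmarks) and exact continuous-time Markov simulation from a
kinetic model (used for parameter-recovery tests). One root seed feeds
per-molecule child streams keyed by molecule index, so adding molecules never
reshuffles earlier ones.

### What the generator does not emulate

Sub-frame partial-intensity frames at transitions (occupancy is sampled at
midpoints and amplitudes fill whole frames), ligand photobleaching and
blinking, baseline drift, spot-level background variation, and any
correlation between a site's successive dwells. Benchmarks on this generator
therefore measure the idealization's behaviour under idealized noise
structure; on real data every metric should be expected to degrade somewhat.

## Idealization

1. **Changepoint partition.** Exact penalized optimal partitioning (PELT
   pruning) of the weighted Gaussian cost Σ w_t (x_t − μ)², w_t = σ̂_t⁻²,
   with a per-changepoint charge `penalty · 2 ln n` (one extra mean and one
   position at known noise; `penalty` defaults to 1.0). The per-frame noise
   scale σ̂_t is the rolling median (15 frames) of |x_{t+1} − x_t|/√2/Φ⁻¹(¾),
   refined in a second pass by each provisional segment's robust residual SD
   (segments ≥ 8 frames). Local noise matters because frame noise grows with
   the number of bound fluorophores: a one-frame event is kept when its
   standardized deviation exceeds the two changepoints it costs, which makes
   isolated events easy, singly-bound dips harder, and multi-ligand one-frame
   events the marginal calls. Binary segmentation was rejected: a single
   split across a one-frame event yields near-zero cost reduction, so
   mid-segment spikes are structurally invisible to it.
2. **Merging.** Adjacent segments merge while |μᵢ − μⱼ| < wᵢσᵢ + wⱼσⱼ with
   wᵢ = nᵢ/(nᵢ+nⱼ); repeated left-to-right passes until a fixed point (the
   rule itself names no order; left-to-right is the deterministic choice),
   pooled statistics recomputed from raw frames.
3. **Single-frame intermediates.** One-frame segments strictly between their
   neighbours' means are absorbed into the closer-mean neighbour (they
   overwhelmingly reflect noise at transitions). A segment exactly
   equidistant from both neighbours is retained: on noisy data this is a
   measure-zero event, while on noise-free equal-amplitude traces it is
   precisely the signature of a genuine one-frame intermediate dwell — this
   keeps the noise-free exact-recovery invariant intact.
4. **Baseline.** Segment means are clustered by frame-weighted 1-D k-means
   with the level count chosen by BIC (≤ 6 levels); the cluster variance is
   floored at the median within-segment variance, since level separations
   below frame noise are meaningless. The lowest level is the unliganded
   baseline; every segment containing baseline frames gets count zero.
5. **Counting.** Within each contiguous non-baseline block, counts follow
   step directions cumulatively. A step at least double every neighbouring
   opposite-direction event counts two ligands (neighbours below the 100 au
   tolerance are not events on the method's own resolution scale; the ≥
   comparison differs from strict > only on exact ties and makes noise-free
   two-fold steps count double). In any three consecutive steps whose net
   level change returns within 100 au of the starting level, the lone
   opposing step counts two ligands. Double-step is applied before triplet;
   the 100 au tolerance (`triplet_tolerance_au`) scales with the trace's
   amplitude units.
6. **Negative-count repair.** For each non-baseline segment with count ≤ 0,
   the maximal chain of monotonic unbinding steps containing the step into it
   (including the block-exit unbinding, when present) is examined: if a
   one-frame dwell sits inside the chain, the two unbinding events around it
   merge into one; otherwise the binding event preceding the chain is
   promoted by one ligand. Repairs iterate innermost-first with an iteration
   cap; molecules that remain unresolvable are flagged for exclusion.

**Domain of the exact-recovery invariant.** On noise-free traces with equal
event amplitudes the pipeline reproduces the true count series frame for
frame, with one documented exception: a one-frame intermediate dwell adjacent
to a simultaneous two-ligand step is not equidistant from its neighbours and
is absorbed by rule 3, exactly as the method prescribes. Such configurations
require two coincident rare events and do not occur in the test traces.

**Evaluation.** Binding/unbinding transitions are matched greedily in time
order (same direction, same post-transition count, within ±4 frames;
multi-ligand steps expand into unit transitions). Precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), accuracy = TP/(TP+FP+FN) — the
self-consistency PR/(P+R−PR) of the printed reference quadruple is what pins
this accuracy definition. Per-ligation one-frame miss fractions count true
one-frame dwells with no idealized frame at the same level within the
tolerance window.

**Benchmark outcome.** On the default generator (two hours each at 30 and
200 nM), the 200 nM event metrics land near precision 0.90, recall 0.82,
F1 0.86, accuracy 0.75, and the pooled one-frame miss fractions near 22%
(two ligands) and 17–21% (one ligand), as computed by
`scripts/acceptance.py`. Relative to the reference quadruple
(0.95/0.87/0.91/0.83) the main residual error mode is amplitude
heterogeneity: with between-event amplitude SD comparable to within-event
noise, ligand-exchange steps and transition-mixture segments survive the
SD-based merge rule and propagate one-count cascades through the
promote-on-negative repair. This is a property of the stand-in amplitude
model, not of the trace length or seeds.

## Dwell statistics

Channel dwells are maximal constant-count intervals; record-boundary dwells
are flagged censored and excluded from MLE by default (a right-censored
likelihood is a natural extension; the flags are retained for it). Bound
periods with several occupied sites are decomposed into per-ligand intervals
by closing one open interval per unbinding: uniformly at random (seeded),
oldest-first, or newest-first. The three policies conserve total bound
ligand-time exactly; repeated random assignment with different seeds leaves
the dwell distribution statistically unchanged (two-sample KS check).

Exponential-mixture MLE maximizes the left-truncated density
f(t)/S(t_d) over log time constants and softmax weights (multistart L-BFGS-B;
k = 1 uses the closed form τ̂ = mean − t_d). The dead time is one frame
(50 ms). Sequential-event correlation uses Pearson correlation of
log-durations (dwells span decades). The 2nd latency is defined conditional
on reaching two bound ligands before returning to zero — the reading of
"latency to binding of the second ligand after binding the first" adopted
here. Binomial occupancy fits use the closed-form MLE p̂ = mean(k)/4 with a
profile-likelihood 95% CI (χ²₁ cutoff); frame-based counts overstate the
effective sample size because frames within a dwell are correlated, so these
CIs are comparable to the reference values but anti-conservative in absolute
terms. Bleach-step counting reuses the segmentation plus merging, absorbs
segments shorter than five frames (blink-like dips), and counts downward
steps resolved beyond twice the noise scale, flagging resolved upward steps
for manual review.

## Kinetic models and fitting

States carry a ligation count (the emitted class) and a conformation tag;
binding transitions scale linearly with ligand concentration. Constraints are
fixed values plus monomial ties (value = coef·Π baseᵉ), which express
equality ties, statistical factors, split cooperativity (kon₂ = √f kon₁,
koff₂ = koff₁/√f) and the MWC exchange-rate scaling l_n = l₀φ^{n/2},
m_n = m₀φ^{−n/2} with φ derived from the four binding rates (detailed balance
holds on every cycle by construction). The catalog encodes single-site
schemes M1.A–F and two-site schemes M2.A_i/c, M2.B, M2.C_i/c, M2.D_i/c,
M2.E, M2.F_ii/ci/ic plus 10×/100× positive/negative cooperativity variants
of C/D/E/F; free-parameter counts follow the published pattern (e.g. M2.F_ii
4, M2.C_i/M2.F_ci/M2.F_ic 6, M2.C_c/M2.D_i 8, M2.D_c 10). The M1.C/M1.D
topologies and the M2.E parametrization reconstruct the narrative
description; the YAML serialization lets users substitute corrected
topologies without code changes.

The likelihood is frame-discretized: per concentration A = exp(QΔt), forward
recursion with deterministic class emissions, each truncation segment started
from the equilibrium distribution restricted and renormalized to its first
observed class (segments begin at truncation boundaries, not at process
start). The one-frame dead time is inherent to the discretization; no
continuous-time missed-event correction is applied, a known divergence risk
from dwell-based maximum-likelihood implementations. Runs of constant class
are advanced with cached masked matrix powers (binary exponentiation,
renormalized every 256 frames; on underflow the run falls back to per-frame
scaling so extreme rates stay finite rather than hitting a flat error
plateau, which would stall bounded line searches).

Fitting optimizes log rates (constraints applied by reparametrization) with
multistart L-BFGS-B — 10 log-uniform starts by default; bounds 10⁻⁴–10⁴ s⁻¹,
scaled by the geometric-mean data concentration for binding rates — with a
derivative-free restart when a bounded line search stalls and a gradient
polish from the best point. Standard errors come from the inverse numerical
Hessian in log-rate space (delta method back to rates). The forward MLE was
cross-checked against the closed-form transition-count MLE available for
two-state schemes. Microscopic reversibility is not enforced on cyclic
models (matching the practice of optimizing loop rates independently); BIC
uses n = frames entering the likelihood; five-fold BIC dispersion partitions
molecules, not frames, so within-molecule correlations stay inside folds.

## Problem sizes used by tests and the acceptance script

Idealization benchmark: 36 molecules × 200 s at each of 30 and 200 nM (two
hours per concentration). Occupancy recovery: 25 molecules × 12 min of
four-site occupancy (five hours) per concentration. Parameter recovery: ten
hours of simulated single-site data per replicate (three M1.A replicates,
one M1.B), with three or four optimizer starts — a problem-size choice for
the recovery checks; library defaults are unchanged. Bleach fit: 500 spots.
Recovery is asserted as ≥90% of (parameter, replicate) checks within 2 SE
with a 4 SE hard cap, the fixed-seed rendering of per-parameter ~95%
coverage.

## Known limitations

- Idealization metrics depend on the stand-in amplitude/noise model (above);
  the accuracy and singly-liganded miss-fraction land at the edge of their
  reference bands under these defaults.
- The evaluator's greedy earliest-first matching can trade a perfect match
  for an earlier in-window one; the reference matching algorithm is unstated.
- Binomial CIs treat frames as independent (anti-conservative).
- No missed-event (dead-time) correction beyond the frame discretization
  itself; rates much faster than ~1/Δt are not identifiable.
- `count_bleach_steps` assumes seconds-long bleach plateaus; it is intended
  for screening, with ambiguous traces flagged for manual review.
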