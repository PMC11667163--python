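# Methods

`adipoflux` implements the computational stack for steady-state
¹³C metabolic flux analysis (MFA) of cultured adipocytes: natural-abundance
correction of GC-MS mass-isotopomer distributions (MIDs), steady-state label
simulation in the elementary-metabolite-unit (EMU) framework, nonlinear
least-squares flux estimation over joint tracer experiments with
profile-likelihood confidence intervals, isotopomer spectral analysis (ISA)
of fatty-acid synthesis, and a synthetic-data generator that reproduces the
study design with known ground truth.

## The reference network

`networks/adipocyte_core.txt` encodes the core carbon-transition model:
lumped glycolysis (glucose → 2 trioses → cytosolic pyruvate), an oxidative
pentose-phosphate branch pinned at 0.3% of glucose uptake, lactate and
alanine secretion, the mitochondrial pyruvate node (PDH, pyruvate
carboxylase, a single lumped malic enzyme), the full TCA cycle, the citrate
shuttle to lipogenic cytosolic acetyl-CoA, glutamine/glutamate uptake and
secretion with glutaminase, glutamine synthetase and a reversible
glutamate/α-ketoglutarate interconversion, BCKDH-gated oxidation of leucine
(to three acetyl-CoA) and valine (to propionyl-CoA), isoleucine as an
always-unlabeled acetyl+propionyl source, propionyl-CoA carboxylase
anaplerosis plus a propionyl overflow efflux (B12-limited cultures
carboxylate little propionyl-CoA; without an overflow the network would
force all BCAA-derived propionyl into odd-chain fatty acids), and synthesis
sinks for C16:0, C15:0 and C17:0.

Modeling conventions:

- **Compartments.** `c`/`m` are balanced; `ext`, `dil`, `out`, `snk` are
  boundary pools. Pyruvate, acetyl-CoA, citrate, malate, OAA, glutamate,
  glutamine and propionyl-CoA have separate cytosolic/mitochondrial pools;
  exchange-carrying transporters connect malate, glutamate and glutamine,
  matching the compartmentation the fit can actually see. Aspartate pools
  are omitted: no aspartate measurement enters any fit here, and the
  malate/OAA shuttle carries the same labeling information.
- **Symmetric metabolites.** Succinate and fumarate are consumed as the
  average of their two carbon orientations (consumption-side scrambling,
  the standard treatment).
- **CO₂.** Decarboxylation releases into an unbalanced `CO2.out` pool;
  carboxylation (PC, PCC, the leucine pathway's biotin-dependent step)
  draws from the unlabeled dilution pool `CO2.dil`, so released label never
  re-enters.
- **Reversible reactions** are reported as net + exchange; the optimizer
  works on a bounded coordinate `t = x/(1+x)` per exchange.
- **oxPPP.** The non-oxidative return is lumped into a single
  3 pentose → 2 hexose + triose reaction with a generic carbon-preserving
  mapping; at 0.3% of uptake the internal rearrangement is numerically
  irrelevant and structurally unidentifiable, which is why the branch is
  not resolved further.
- **No biomass drain** other than the measured fatty-acid sinks
  (terminally differentiated, non-dividing cells).

## Label simulation

`emu.simulate_mids` decomposes the network into the minimal EMU reaction
graph reaching the requested fragments and solves one linear balance system
per EMU size, with convolution inputs from smaller sizes. Simulation
operates in natural-abundance-corrected MID space (the ¹²C backbone carries
no mass shift); tracer substrates enter with per-position purity (default
0.99) and pool fraction, all other boundary pools unlabeled. Dense LU
factorization is used per size level (the largest balanced-metabolite
system here is ~60 EMUs); direction fluxes are floored at 1e-12 so
zero-throughput pools take their well-defined limiting distribution, and a
balance whose solution is grossly non-simplex (a zero-flux trapped cycle)
raises an explicit error.

Two independent solvers cross-check each other: the EMU cascade and a
brute-force cumomer solver (`cumomer.brute_force_isotopomer_sim`) that
solves the full positional-isotopomer problem per labeling weight and
marginalizes. They agree to < 1e-9 on every shipped network; the guard on
the oracle (≤ 2¹⁶ isotopomer states) keeps it exact but small-scale.

For estimation, the simulator also returns analytic forward sensitivities
of every MID with respect to an arbitrary flux parameterization, obtained
by differentiating each balance system against its prefactorized operator.
These match finite differences to ~1e-6 and make profile-likelihood
confidence intervals affordable.

## Flux estimation

`FluxModel(network, experiments).fit()` minimizes the variance-weighted SSR
over all tracer experiments jointly: per measured fragment, mass channels
above M0 (the simplex constraint removes one channel); plus measured
net-exchange rates expressed as linear combinations of reaction nets.
Parameters are the null-space coordinates of the stoichiometry +
fixed-ratio constraints (16 free net fluxes for the reference network) and
one bounded exchange coordinate per reversible reaction (7).
Irreversibility is enforced by hinge penalty residuals that vanish on the
feasible set.

The label-space objective is strongly multimodal: broad basins exist in
which large futile cycles (e.g. a glutamine-synthetase/glutaminase loop
near 500 nmol/well/h) wash out TCA labeling while still matching every
measured rate, and plain trust-region solves started from uniform feasible
samples terminate there with dead gradients wherever a clipped direction
flux vanishes. The fit driver therefore uses a graduated continuation per
restart: starts are the minimum-norm solution of the (linear) rate
equations plus Gaussian draws in the rate null space (exchange coordinates
log-uniform in [0.1, 100]); the first stage adds a weak ridge on the free
coordinates and smooths the net-flux direction split
(`fwd = (v + sqrt(v² + eps²))/2 + exchange`, eps = 2 nmol/well/h), the
second stage releases the ridge and shrinks eps to 0.3, and the final
polish runs the exact objective (eps = 1e-6, ftol = xtol = 1e-10). The
smoothing preserves net balances exactly for reversible reactions and
perturbs irreversible ones by O(eps), so the homotopy ends at the true
objective. Every restart runs the presolve; the most promising presolved
points carry through the exact polish, and restarts that stop at the
presolve report the exact measurement SSR where they ended. On benchmark
datasets roughly one start in three reaches the global basin; the shipped
default remains 20 restarts.

Goodness of fit is the two-sided chi-square test at α = 0.01 with
dof = measurements − parameters. Confidence intervals are profile
likelihood: the target flux is constrained (an affine reparameterization of
the null-space coordinates), all other parameters re-optimized, and the 95%
bound is where the profiled SSR crosses SSR_min + 3.84 (χ²₁ at 0.95),
searched by geometric expansion plus bisection; a bound that never crosses
within ±10⁴ nmol/well/h is reported open. Whenever a warm-started profile
re-optimization lands above the decision threshold it is retried with the
same continuation used for fitting — warm paths trap on weakly identified
ridges (notably the glutamine uptake/secretion split) and would otherwise
produce false interval misses.

## Measurement processing

The correction matrix maps backbone-label distributions to observed mass
distributions: column *j* is the spectrum of the fragment with exactly *j*
backbone ¹³C and every remaining atom (including derivatization C, H, N, O,
Si, S) at NIST natural abundance. Correction solves the non-negative least
squares problem and renormalizes to a simplex vector. Mole percent
enrichment is `100 · Σᵢ i·Mᵢ / n`. Exchange rates are
`(fresh − spent) · volume / time` in nmol/well/h, positive for uptake.
FAME methyl carbons are treated as derivatization (unlabeled) atoms, not
backbone. Desaturation indices (C16:1/C16:0, C18:1/C18:0) and absolute de
novo lipogenesis (fraction-new × pool size) are simple reported summaries.

## Isotopomer spectral analysis

A newly made palmitate is 8 condensed acetyl units; C15:0 and C17:0 are one
propionyl primer plus 6 or 7 acetyl units (3 + 2n carbons). Under a
uniformly labeled tracer each acetyl unit is M2 with probability *g* (the
lipogenic acetyl-CoA enrichment), the propionyl unit optionally M3; the
measured pool is `D·synthesized + (1−D)·unlabeled` with *D* the fraction of
the pool made during the tracing window. M1 acetyl units (tracer impurity)
are neglected — appropriate for uniformly labeled tracers, a documented
limitation for partially labeled ones. Pre-existing fat is fully unlabeled
in corrected space. C18 species are outside the model (elongation not
modeled).

The fit is bounded least squares on (D, g[, propionyl enrichment]) with
residuals weighted by the per-channel measurement sd, started from the best
few points of an 11×11 grid — the origin is a stationary saddle of the D–g
trade-off and a single start can be trapped there. CIs are SSR-sensitivity
profiles at the same χ²₁ threshold, clipped to [0,1], with a flat-profile
flag; `results_differ` implements the non-overlapping-CI comparison. An
all-M0 measurement is flagged degenerate (only D·g is pinned at zero).

## Synthetic data

The generator defines the study conditions: three tracers
([U-¹³C₆]glucose, [U-¹³C₆]leucine, [U-¹³C₅]valine, purity 0.99), three
replicates, 48 h, MID noise sd 0.003 mol fraction, 5% relative rate noise.
Ground-truth flux vectors come from an L1 reconciliation LP that projects
documented scenario targets onto the balance manifold; the two printed
glutamine fluxes anchor the absolute scale (uptake 56 / secretion 43 in
control, 45 / 39 after BCKDH knockout), and the knockout scenario ablates
BCKDH flux (< 1% of control) with compensatory pyruvate oxidation and
carboxylation. All other magnitudes are documented modeling choices, not
claims about any real measurement. Per-tracer measurement panels contain
the fragments with a carbon path from that tracer (pyruvate only under
glucose; leucine/KIC only under leucine; valine only under valine; TCA
intermediates, glutamine, glutamate and the three fatty acids under all
three).

MID noise is independent Gaussian applied in corrected space, clipped at
zero and renormalized. Because clipping and renormalization change the
per-channel error — shrinking it strongly for near-empty channels and
inflating M0, which absorbs the normalization noise — the generator reports
each channel's true RMS error, computed by a deterministic inner Monte
Carlo seeded from the MID itself. These play the role replicate-derived sds
play for real data and are what make the chi-square machinery calibrated:
the SSR of the true flux vector then averages exactly its nominal dof
(813.2 observed vs 813.75 interval center over 1000 realizations).

What the generator does not emulate: correlated noise across mass channels
(independence is assumed), drift over the labeling window (isotopic steady
state is imposed), chromatographic artifacts, and natural-abundance
residuals (fixtures live in corrected space by default; a raw mode through
the correction matrix exists for exercising `correct_mid`). Passing tests
demonstrate correctness of the estimator under these idealized conditions,
not performance on real spectra.

## Calibration results and a known limitation

On the default conditions (reference network, three tracers, noise 0.003,
five restarts): profile-CI coverage of true net fluxes is ~92% against the
95% nominal (the χ²₁ threshold is slightly anticonservative for boundary
fluxes under the clipped noise); ISA recovers a 21×21 noise-free (D, g)
grid to < 1e-5 with noisy CI coverage ≈ 94–98%; and the knockout/control
contrast (higher PDH and PC, collapsed BCKDH with CIs excluding the control
value) is recovered from fitted fixtures.

One deliberate red flag: the SSR of the *true* flux vector falls inside the
α = 0.01 chi-square interval in only ~95% of noise realizations rather than
the nominal 99%. The mean is exactly calibrated, but channels whose true
fraction is below the noise sd acquire a point mass at zero from clipping,
which inflates the fourth moment of their standardized residuals
(per-channel χ² variance 5 instead of 2) and widens the SSR distribution
(sd 53.8 vs the 40.2 a χ² with this dof assumes). Removing this would
require a non-diagonal whitening of the residuals or a different noise
model; with diagonal sd weighting it is an intrinsic property of
clipped compositional measurements, and the test suite reports it honestly.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 20 (tests) / 6 (script)
synthetic datasets for flux-recovery coverage at 5 restarts; 200 noise
realizations for chi-square calibration; 400 noise-free grid points and
200 (tests) / 150 (script) replicates for ISA; single fits per scenario
for the knockout contrast. These sizes are the package's own validation
design; all are reproducible from a single seed.
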