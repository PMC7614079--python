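# Methods

This note documents the models, estimators and numerical choices behind
foldscape, and what the synthetic-data tests do and do not demonstrate.

## Polymer model

Unstructured polypeptide under force is modelled as a freely-jointed chain
(FJC). With β = F·l_K/kT, the relative extension is the Langevin function
φ(β) = coth β − 1/β and the axial extension variance per unit contour length
is v(F) = l_K·[β⁻² − csch²β] = kT·∂φ/∂F (fluctuation–dissipation; this
identity is verified numerically in the tests). Defaults l_K = 1.1 nm and
kT = 4.11 pN·nm live in configuration, not in code. For β < 10⁻³ both φ and
v switch to Laurent series (φ ≈ β/3 − β³/45, v/l_K ≈ 1/3 − β²/15) to avoid
cancellation; the branches agree to better than 1e-10 at the crossover, and
v(0) = l_K/3 is the ideal-chain one-axis limit.

The central inversion is ΔL_c = Δσ²/v(F): the excess extension variance of a
conformation, referenced to the natively folded state, divided by the
per-unit-length variance at the operating force. The printed form of this
relation is typographically ambiguous (product vs quotient); dimensional
analysis forces the quotient and that is what is implemented.

**A known discrepancy.** Plugging the catalogued unfolded-state variance
(5.8 nm²) at 8.5 pN into the inversion yields ΔL_c ≈ 35.1 nm, not the
42.5 nm quoted as the unfolded increment — the per-molecule forces actually
entering the published average are not stated. The package does not tune
constants to bridge this: force is an explicit argument everywhere, and the
synthetic generator derives the unfolded-state variance from the *forward*
model (42.5 nm × v(8.5 pN) ≈ 7.01 nm²) whenever the round trip is the
quantity under test.

## Synthetic trajectories

The generator realises a continuous-time Markov jump process over a
conformation catalog (label, Δz offset, excess variance Δσ²) with directed
rate edges. Each printed mean transition time is read as the reciprocal of
that edge's exponential clock, clocks competing independently — this
interpretation reproduces the observed ≈1.3 s unfolded dwell (reciprocal of
the summed exit rates) while keeping rare-state entries rare. Force enters
through Bell factors k(F) = k₀·exp((F−F_ref)·Δx/kT) on edges with a signed
distance-to-transition-state Δx (positive for unfolding-like edges); the
total Δx across a folding/unfolding pair sets the 10–90 % width of the folded
fraction, kT·ln 81/Δx_total ≈ 1.5 pN for Δx_total = 12 nm. Piecewise-constant
force protocols exploit the memoryless property: the dwell clock is redrawn
at each segment boundary.

Rendering draws per-sample Gaussian noise with sd = √(baseline² + Δσ²),
where the baseline (default 0.85 nm) is the instrument point-spread width;
only unstructured sequence adds variance, mirroring the fluctuation model.
Options exercised solely by robustness tests: linear drift, AR(1) noise with
a set correlation time, and finite linear transition ramps (default:
instantaneous switches). Rare-state entry and exit rates are held
force-independent by default; only occupancies, not entry rates, have a
quantified force response to emulate.

What the generator does *not* emulate: bead–magnet magnetostatics, camera
image formation, tracking artefacts (beyond the Gaussian PSF), slow
instrument drift unless requested, and any coupling between conformations
beyond the catalogued network topology (all rare states attach to the
unfolded conformation; only the short-lived intermediate also touches the
folded state). Recovery results on synthetic data therefore demonstrate the
estimators' correctness under the stated observation model, not robustness
to every instrumental pathology.

## Idealization

Levels are estimated by a Gaussian-mixture fit (scikit-learn, full
covariance, 3 initialisations, EM tolerance 1e-6 — the looser sklearn default
leaves visible convergence error on close levels) on at most 200,000
deterministically strided samples; the component count is fixed or selected
by BIC among 1–4. Resolvability is checked with a density-dip criterion: the
fitted mixture must dip between each pair of adjacent component means,
otherwise the components describe a single mode and an error names the
histogram. A gap/σ rule cannot make this distinction — genuine neighbouring
levels in the three-level region sit at gap/σ ≈ 2.1 while EM slicing of a
single Gaussian produces gap/σ ≈ 1.9.

Thresholds are the level means themselves, implementing the stated procedure
literally (midpoint thresholds are available behind a flag). The labeller is
a hysteresis state machine: dwelling at level a, a transition to b is
recorded at the first sample reaching b's mean; samples after the last
home-side crossing of a's mean and before that arrival are excised as the
transition path, a diffusive barrier excursion whose contribution to dwell
and variance statistics would be spurious. Dwells shorter than 3 samples
(configurable; below the ~1–2 ms instrument resolution at 1,500 Hz) are
excised as chatter, and consecutive same-label dwells then merge at the
event level. Segments use 0-based half-open sample intervals; the partition
(dwell samples + excised samples = all samples) is exact and tested. First
and last dwells are censored by the observation window: they count toward
occupancy but never toward dwell-time means.

## Fluctuation analysis

Fragment j of conformation c contributes Δz_{c,j} = ⟨z_j⟩ − z_ref and
Δσ²_{c,j} = var(z_j) − ⟨σ²_ref⟩, with the reference level and variance taken
as duration-weighted means over all folded-state fragments. Fragments
shorter than 8 samples are dropped (variance estimates too noisy); the count
of exclusions is reported. Summaries convert the *mean* excess variance to
contour length (mean-then-convert, matching the phrasing of the published
procedure) with duration weighting by default; spreads are fragment standard
deviations propagated linearly through the (linear) inversion.

Region classification operates at two levels. `classify_region` is the pure
rule matcher: level count plus offsets within ±1.5 nm of the catalogued
values; the two-state regions (native vs trans-proline isomer) are split by
folded-state occupancy at 0.25 (native ≈ 0.52, trans ≈ 0.02 under the
catalogued times). `classify_stretch` scores a raw stretch by the BIC of
matched-template mixtures — component means and variances fixed from the
catalog, only weights fitted by EM — against a free BIC-selected mixture as
the "unknown" alternative (declared when the free fit wins by more than 0.02
per sample in −2·log-likelihood). The template approach is what keeps the
three-level region detectable: its top level holds only ~2 % occupancy under
the catalogued internal kinetics (0.09 s dwells against 2.52 s re-entry), too
little for a free mixture fit to localise reliably.

## Kinetics

The transition table pools, over recordings, the dwell time preceding each
directed transition (censored edge dwells excluded) with counts and s.e.m.
The running unfolded fraction P_U = ⟨t_U⟩/(⟨t_U⟩+⟨t_F⟩) uses a window of
n = 10 consecutive transitions at stride one. Isomer switches are detected
with hysteresis: onset when P_U ≥ 0.8 for ≥ 3 windows, offset when ≤ 0.6
likewise (the published criterion is only "an abrupt change"; the cutoffs
are configuration). The isomerization rate fits r(F) = P_U(F)·k by least
squares with the per-force empirical rates r̂ = events/observation-time —
the per-force bookkeeping behind the published fit is unstated, and this
estimator is the documented choice. Folded fraction versus force is
occupancy-based (time fraction, consistent with P_U's time-based definition)
and fitted with a two-parameter logistic; rescue probabilities are binomial
proportions with a trial counted as rescued when ≥ 5 native-region
transitions occur within 200 s after the pulse (configurable).

## Landscape

The PSF is the standard deviation of a reference-bead trace after zero-phase
Butterworth high-pass filtering (default cutoff 1 Hz) with a Gaussian
histogram fit reported as a cross-check. The measured extension density uses
0.25 nm bins on [−5, 25] nm (≤ σ/3 for the 0.85 nm PSF). Estimated
histograms are pre-smoothed with a 3-bin binomial kernel (sd ≈ 0.18 nm,
negligible against the PSF) before deconvolution: deconvolution amplifies
bin-level shot noise and the subsequent −ln is convex, which otherwise biases
recovered barriers upward.

Jansson's iteration updates p ← p + r(p)·(m − S⊗p) with the two-sided
relaxation r(p) = r₀·(1 − 2|p − A/2|/A), A = max(p), clamping at zero and
renormalising each step (reflect padding at the boundaries; zero padding
available). Defaults r₀ = 1, 500 iterations, stopping when the residual
fails to improve by 1e-6 over 10 consecutive iterations (the best iterate is
returned); a residual that doubles over the best raises a divergence error.
Two properties of this relaxation are worth knowing: updates vanish at both
p = 0 and p = A, so (a) any configuration whose bins sit at zero or at the
common maximum is a fixed point — a δ-like input re-concentrates into a
compact flat top rather than a single bin — and (b) terminal convergence in
near-bound bins is slow, so reconstructions approach but do not exactly
reach the true density even in noiseless tests. Neither affects barrier
recovery at the tested scales.

Boltzmann inversion G = −ln p (kT units, floored at 1e-8 before the log,
minimum shifted to zero) is followed by basin extraction: local minima of G
holding at least 1e-3 probability mass in their neighbourhood, merged when
the separating rise is below 0.5 kT (post-deconvolution ripples inside one
basin otherwise masquerade as basin pairs). The barrier is the maximum of G
between the two deepest surviving minima, measured from the shallower one;
a unimodal density reports no barrier. On synthetic double wells (18.2 nm
basin separation, 4 kT barrier, 0.85 nm blur) the recovered barrier is
4.0–4.3 kT across seeds at 10⁶–4×10⁶ samples, with a small residual upward
bias from noise amplification in the barrier region.

## Structure hypotheses

The four-helix bundle is treated as four independently folding units
(foldons). The default topology splits the 110 residues into four 22-residue
helices separated by 7-residue loops plus a terminal residue — the true
helix boundaries are not determinable from extension data, so the split is
even and configuration-overridable. Unstructured contour length is 0.4 nm
per released residue; a loop or terminal residue counts as released exactly
when an adjacent helix is unfolded (loops packed against the native bundle
do not fluctuate), which makes the all-folded configuration 0 % unstructured
and the all-unfolded one 100 %. Predicted Δz is the released contour length
times the FJC relative extension at the operating force, plus per-helix
folded-extension contributions (default 0: helix axes assumed orthogonal to
pulling). All 16 configurations are enumerated and ranked by weighted squared
mismatch in (Δz, ΔL_c), ties resolved toward fewer unfolded helices. The
output is a ranking of hypotheses compatible with two scalar measurements —
never a structure determination.

## Pipeline, determinism and problem sizes

Every stochastic step flows from a single seed through
`numpy.random.Generator`; two runs with the same configuration produce
byte-identical reports, each carrying the configuration hash and seed in its
header. Unknown configuration keys are rejected before any computation.

Test and acceptance problem sizes are chosen so statistical tolerances are
meaningful at interactive runtimes: 5,000 s at 1,500 Hz for dwell-time
recovery (≈1,900 events, s.e.m. ≈ 0.03 s), 2,000 s for the contour-length
round trip (relative error ≲ 0.3 %), five 1,000 s trajectories for the
coexistence-force fit (midpoint error ≲ 0.03 pN), and 4×10⁶ draws for the
landscape recovery. The published experiments run two to five orders of
magnitude longer; nothing in the estimators depends on the shorter spans
beyond wider error bars.
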