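# Methods

This note records the models behind each analysis stage, the assumptions
they make, the defaults and why, and what the synthetic generators do and
do not emulate.

## Chemical-shift perturbations and titration fitting

The combined amide perturbation is Δδ = sqrt(½(ΔδH² + (0.14·ΔδN)²)) ppm.
The nitrogen weight 0.14 rescales the ~25 ppm ¹⁵N amide dispersion onto
the ~3.5 ppm ¹H scale; it is fixed by default and only changeable through
an explicit argument, since changing it silently would make profiles
incomparable across studies. Deviations are stored signed (sample minus
reference); only magnitudes enter Δδ, so the metric is symmetric under
swapping the two spectra and obeys the triangle inequality across composed
titration steps (it is a weighted Euclidean norm).

"Large" shifts use a strict > 0.025 ppm cutoff, the conventional
significance threshold for amide CSPs; residues observed in only one
spectrum are flagged unmatched and excluded rather than zeroed, so a
broadened-out residue does not masquerade as an unperturbed one (an
include-as-zero alternative would bias spatial maps toward apparent
rigidity).

Peak correspondence, when assignments cannot be transferred, is greedy
nearest-neighbour in the weighted ppm metric with a hard cutoff (default
0.1 ppm): pairs are accepted in ascending distance, each peak once. Greedy
matching is not guaranteed globally optimal, but at peak-list scale with a
tight cutoff ties are rare and the failure mode (leaving both peaks of an
ambiguous pair unmatched) is the safe one. A Hungarian assignment would
add a dependency for no practical gain here.

Kd fitting assumes fast exchange: the observed shift is the
population-weighted average of free and bound endpoints, with the bound
fraction from the single-site depletion quadratic
fb = ((P+L+Kd) − sqrt((P+L+Kd)² − 4PL))/(2P). The global mode shares one
Kd across residues — appropriate when a single binding event is being
quantified — with per-residue bound-state endpoints. Because the endpoints
enter linearly, they are profiled out exactly for any trial Kd (variable
projection), leaving a one-dimensional optimisation in log Kd: no starting
values to tune and no spurious local minima in practice. ¹⁵N residuals
carry the same 0.14 weight as the CSP metric so both dimensions contribute
on one scale. The Kd standard error comes from the curvature of the
profiled residual surface. A titration with no measurable shift raises an
unidentifiability error rather than returning an arbitrary Kd. Per-residue
mode exists as a diagnostic; its estimates bracket the global one.

## ¹⁵N relaxation and rotational correlation times

Decay series are fit as I(t) = I0·exp(−Rt) with positivity-bounded rates;
default delay schedules are the standard CPMG loop lengths (16.5–247.5 ms)
and R1 recovery delays (100–1500 ms) at 500 and 850 MHz, stored as named
constants.

The apparent correlation time uses the T1/T2 estimator
τc = (1/4πνN)·sqrt(6·T1/T2 − 7) on the arithmetic means of per-residue
T1 = 1/R1 and T2 = 1/R2. The default includes every residue; a hetNOE
cutoff filter is available but off, and when flexible tails are present
the unfiltered average mixes internal motion into the estimate — the
output notes the filter state for this reason. The estimator assumes
rigid isotropic tumbling, ωNτc ≳ 1, and exchange-free R2 (CPMG-measured
R2 is taken as exchange-free; no Rex correction is applied). Round-trip
tests against the full spectral-density forward model show the closed
form is good to ~2% for τc in 5–15 ns at 500–850 MHz; the documented
tolerance is 10%.

The predicted τc for a rigid globular protein is a deliberate
reconstruction of the familiar empirical MW-based estimate:
τc = k·MW·(η(T)/T)/(η(298.15 K)/298.15 K), with water viscosity from the
Andrade-type correlation η(T) = 2.414e−5·10^(247.8/(T−140)) Pa·s. The
Stokes–Einstein–Debye relation τc = ηV/(kBT) motivates linearity in MW
(hydrated volume ∝ mass) and the η/T scaling. The single coefficient
k = 6.1496e−4 ns/Da is calibrated by least squares through the origin on
two single-domain anchor constructs of known MW and τc at 25 °C
(10,785 Da → 6.64 ns; 11,411 Da → 7.01 ns) and validated against three
further constructs at both temperatures, which it reproduces within 2%.
This is a linear-in-MW model, not a hydrodynamic calculation: it ignores
shape anisotropy and assumes a fixed hydration layer, adequate for the
rigid-vs-flexible comparison it serves.

The verdict compares calculated and predicted τc with a ±10% margin:
below, the domains tumble faster than one rigid body of that mass
("independent/flexible"); within, consistent with a rigid particle;
above, slowed tumbling (disordered tails, ligand binding,
oligomerisation). The 10% margin matches the estimator's own accuracy —
differences inside it are not interpretable.

The forward model behind the generators uses the standard ¹⁵N dipolar +
CSA expressions with the two-Lorentzian model-free spectral density
(r_NH = 1.02 Å, Δσ = −160 ppm, standard gyromagnetic ratios, all named
constants). νN is derived from the ¹H field with |γN/γH| = 0.101329.

## RDC alignment tensors

The fit solves D = vᵀAv for the five independent elements of the traceless
symmetric order tensor A by SVD of the direction-cosine design matrix,
directly in coupling units (Hz): the dipolar prefactor is absorbed into
the tensor, so no bond-length-dependent physical constants enter, matching
how Da is conventionally reported in Hz. The solution is linear and global;
noise-free recovery is exact to numerical precision, which the property
suite verifies over random tensors and geometries. The design-matrix
condition number is reported (warning above 100) and a rank-deficient
geometry — e.g. all bond vectors collinear, as in an ideal straight
helix — is an error, not a silent bad fit. Weighting by 1/σ² is available
but off by default.

Parameters follow the usual principal-frame convention: |Azz| ≥ |Ayy| ≥
|Axx|, Da = Azz/2, rhombicity R = (Axx − Ayy)/(3Da) ∈ [0, 2/3], Euler
angles in ZYZ. A traceless symmetric tensor determines its frame only up
to four sign-degenerate rotations; the representative with θ ∈ [0, 90°]
(and φ ∈ [0, 180°) where the remaining degeneracy allows) is returned.
Near-axial tensors (|Ayy − Axx| < 1e−9) snap R to the exact boundary.
Euler angles are convention-dependent and are validated only by
construct/decompose round trips, not against external tables.

The R-factor is 100·sqrt(⟨(Dobs − Dcalc)²⟩/(2⟨Dobs²⟩)); the factor 2 in
the denominator normalises so that a random (zero-correlation) prediction
scores ~100%.

The rigidity test fits each domain separately and all residues jointly.
The comparison metric is the percent increase of the joint R-factor over
the RDC-count-weighted mean of the per-domain R-factors, plus the
normalised generalised scalar product and inter-frame rotation between the
per-domain tensors. For a rigid two-domain arrangement matching the
coordinates the increase is ~0; for independently reorienting domains each
domain acquires its own effective alignment and the joint fit degrades
(>50% increase in the simulated flexible scenario). Residue selection
(e.g. secondary-structure elements only, to avoid structural noise from
flexible loops) is by explicit residue list; no automatic
secondary-structure detection is attempted.

## ITC models

Concentration bookkeeping uses the perfusion-cell convention: injecting
volume v into cell volume V0 dilutes existing contents by (1 − v/V0);
the titrand is only diluted while the titrant also gains syringe
material. Per-injection heats are differences of cell heat content with
the midpoint ("instantaneous mixing") displacement correction
Δq_i = Q_i − Q_{i−1} + (v_i/V0)·(Q_i + Q_{i−1})/2, matching common vendor
practice. V0 defaults to 1.4 ml (the standard cell of the instrument
class modelled) and is configurable. Heats are μcal
(exothermic-negative), enthalpies kcal/mol, concentrations μM.

One-site: bound titrant from the depletion quadratic with site
concentration n·[titrand]; cumulative heat ΔH·V0·[bound]. Over a
saturating titration the heats sum to n·ΔH·V0·[titrand]₀ within the
displacement-correction bound (<2% for the standard schedule).

Sequential two-site: free titrant [X] solved per injection from the
binding-polynomial mass balance
X_t = [X] + M_t·(K1[X] + 2K1K2[X]²)/(1 + K1[X] + K1K2[X]²) by bracketed
Brent root finding on [0, X_t] (always bracketed for positive inputs;
relative tolerance 1e−13); cumulative heat
V0·M_t·(ΔH1·θ1 + (ΔH1+ΔH2)·θ2) with θ the singly/doubly ligated species
fractions. The K2 → 0 limit reduces exactly to one-site with n = 1
(verified to 1e−9), and both constants tight with equal enthalpies give a
single sharp step at molar ratio 2. Constants are stored as dissociation
constants in μM for unit consistency. An independent-identical-sites
variant is provided via the statistical mapping K1 = 2k, K2 = k/2, since
calorimetric data alone rarely distinguish the schemes.

Fitting is Levenberg–Marquardt (lmfit) on the matching forward model with
Kd's in log space. Start values come from the data: n from the
molar ratio at the steepest heat change, ΔH from the first usable
injection heat per mole injected, Kd from a transition-width heuristic.
Pre-injections (use_flag 0 — small first injections that absorb the
syringe-tip diffusion artifact) are excluded from residuals but kept in
the concentration bookkeeping. The Wiseman c = n·[titrand]/Kd is reported
with a warning outside [1, 1000], where parameters grow poorly
determined. Noise-free recovery is <0.1% over c in 5–500; q_offset is
fixed at 0 unless offset fitting is requested, since the offset and ΔH
trade off in low-c data (a measured dilution-control offset should be
subtracted instead).

The equivalence point is located on the heat-vs-molar-ratio curve: each
injection's heat samples dQ/d(ratio) over its own molar-ratio interval
and is therefore attributed to that interval's midpoint; the extremum of
the discrete derivative is refined by a local quadratic through its three
neighbours. Accuracy is limited by the injection grid (about one spacing);
a featureless isotherm returns a no-transition flag.

## Synthetic data

Generators draw from exactly the forward models the analysis inverts, so
zero-noise round trips recover generating parameters (to machine precision
for the linear RDC fit and the ITC least squares; within the ~10%
estimator tolerance for τc). All randomness comes from explicit integer
seeds; noise is Gaussian and independent across residues/injections.

Toy structures are backbone-only (N, H, CA, C, O) chains with ideal
covalent geometry built by internal-coordinate (NeRF) placement; the
amide H sits 1.02 Å from N in the C′(i−1)–N–CA plane, anti to the bond
bisector. Geometries: ideal α-helix, ideal β-strand, a "coil" that
alternates jittered 3-residue α/β blocks, and a two-domain construct (one
continuous coil chain whose second half is rigidly rotated by a recorded
angle). The coil exists because well-conditioned tensor fitting needs
orientationally spread N–H vectors — an ideal helix's near-parallel
vectors are precisely the degenerate geometry the fit must reject — and
the two-domain construct uses coil domains for the same reason.

Titration series place observed peaks at the population-weighted shifts
with depletion-quadratic bound fractions. Broadening uses the
fast-exchange-limit closed form Rex = pf·pb·Δω²/kex with Δω (rad/s) from
the larger of the two dimensions' endpoint differences, attenuating
intensities by R2,0/(R2,0 + Rex); this reproduces the qualitative
shift/broaden/re-sharpen pattern of intermediate-fast exchange (Rex peaks
at half saturation) without a full Bloch–McConnell lineshape simulation,
which is out of scope. Bound-state endpoint shifts are free generator
parameters.

What the generators do not emulate — and hence what passing tests do not
demonstrate about real data: peak overlap and assignment ambiguity,
baseline and phase artifacts, anisotropic or temperature-gradient
tumbling, heteroscedastic or correlated noise, ITC baseline drift and
integration error, and slow-exchange regimes. The pipeline's accuracy
claims are claims about the stated models under Gaussian noise.

## Numerical choices and problem sizes

Tolerances: SVD recovery asserted at 1e−10 Hz; two-site/one-site limit at
1e−9 μcal; fraction-bound against a brute-force mass-balance root at
1e−10; τc round trips at 10%; titration Kd recovery at 1% (noise-free)
and 15% (0.002 ppm shift noise); ITC recovery at 0.1% (noise-free).
Simulated test beds are desk-scale by design — 20–50 residues or
vectors, 30–40 injections, ≤20 replicate simulations — which keeps the
full suite and the acceptance script in the seconds-to-minutes range on
one CPU while leaving every estimator in its asymptotically valid regime.

Known limitations: no per-residue model-free fitting, no anisotropic
diffusion tensors, no lineshape-based kex/Δω extraction, no multi-
alignment RDC fitting or structure refinement, no raw thermogram
integration, and no NMR-STAR/mmCIF parsing (the bespoke TSV formats are
deliberately minimal).
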