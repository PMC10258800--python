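# Methods

`noemd` computes intermolecular ¹H–¹⁹F NOE cross-relaxation rates and
related solvation observables from MD trajectories of a peptide in a
fluoroalcohol–water mixture, and validates the whole chain on synthetic
Brownian systems with known ground truth. This note records the models,
the numerical choices, and what the synthetic validation does and does not
establish.

## The observable

A solvent fluorine spin F at distance r from a peptide hydrogen H couples
to it through the dipolar lattice function P₂(cos θ)/r³. The pipeline
computes the intermolecular dipolar correlation function

    G(t) = ⟨ Σ_k P₂(cos θ_k(t₀, t₀+t)) / ( r_k(t₀)³ r_k(t₀+t)³ ) ⟩_{t₀}

summed over fluorines within 3.0 nm of H at the origin frame, averaged
over origins (default every snapshot), in nm⁻⁶. Included spins are
followed through their unwrapped displacement after the origin, so G(t)
decays smoothly even when a spin leaves the cutoff. G(t) is fitted to a
sum of 1–6 decaying exponentials; the fitted model has the closed-form
one-sided cosine transform J(ω) = Σ aᵢτᵢ/(1+(ωτᵢ)²), and the
cross-relaxation rate is

    Σ_HF = (1/10)(μ₀/4π)² ħ² γ_H² γ_F² [ 6 J(ω_H+ω_F) − J(ω_H−ω_F) ]

with J converted to SI (1 nm⁻⁶ ps = 10⁴² m⁻⁶ s). The 1/10 prefactor is
tied to this specific G normalisation and one-sided transform; the
identical constant is used on the analytic side, so every theory
comparison is convention-free. Σ_HF may be negative: slow solvent motion
moves spectral weight from the double-quantum term 6J(ω_H+ω_F) into the
zero-quantum term J(ω_H−ω_F). The default field is B₀ = 11.744 T (500 MHz
¹H); the source experiments do not state their field, so B₀ is
configurable and every report echoes the value used.

## Analytic hard-sphere reference

The force-free (Ayant/Hwang–Freed-type) model — spins of uniform density
N_F diffusing freely with mutual coefficient D outside a reflecting sphere
of radius b around the reference spin — admits an exact reduced spectral
density

    j(z) = (1 + 5z/8 + z²/8) / (1 + z + z²/2 + z³/6 + 4z⁴/81 + z⁵/81 + z⁶/648),
    z = √(2ωτ_b),  τ_b = b²/D.

Rather than transcribing a literature prefactor (conventions differ), the
absolute scale is pinned by quadrature of the reflecting-boundary
propagator expanded in spherical Bessel modes:

    G(t) = (8N_F/b³) ∫₀^∞ x² e^{−D t x²/b²} A(x)²/W(x) dx,
    A(x) = [y₂'(x) j₁(x) − j₂'(x) y₁(x)]/x,   W(x) = j₂'(x)² + y₂'(x)²,

where the radial overlap ∫_b^∞ u₂(kr)/r dr has the closed form A via
d/dx[x⁻¹j₁(x)] = −x⁻¹j₂(x). This reproduces G(0) = 4πN_F/(3b³) to 10⁻⁶
and gives J(0) = (8N_F/(bD))·I₀ with I₀ = ∫A²/W dx ≈ 0.23271, i.e. an
effective correlation time of (4/9)τ_b. The k-space quadrature of J(ω)
agrees with the closed-form polynomial to better than 10⁻⁵ over
ωτ_b ∈ [0.1, 100]; the two routes are kept as mutual cross-checks in the
test suite.

Because the trajectory pipeline only seeds pairs inside the 3.0 nm origin
cutoff, the matched analytic object for equivalence tests restricts the
*origin* integral to b..R (closed form `A_R`), leaving the lagged position
unrestricted. Without this matching, the finite-cutoff tail deficit alone
biases the comparison by up to ~25% at slow D and large b; with it, the
residual disagreement is a few percent. The standalone calculator
(`ayant_sigma` without `origin_cutoff`) uses the infinite-medium closed
form.

## Synthetic data generator

The generator emulates the sampling conditions of the solvated-peptide
study: a cubic periodic box (default 6.7 nm) of HFIP (6 fluorine sites per
molecule) and water point particles, snapshots every 10 ps, translational
diffusion at the study's bulk coefficients (HFIP 4.8×10⁻¹⁰, water
17×10⁻¹⁰ m² s⁻¹), and a reflecting solute sphere of radius b centred on
the fixed reference hydrogen. It is force-free: no solvent–solvent
interactions, no rotation (a rapidly rotating HFIP is the effective
0.556 nm sphere that motivates the shell width), no hydrodynamics.

Numerics: each snapshot interval is split into substeps (default 10);
steps are isotropic Gaussians of per-axis variance 2DΔt; reflection is
radial (r → 2b−r) against the nearest periodic image of the solute. This
first-order scheme requires the substep RMS displacement to stay well
below b — specs that violate RMS < b/2 are rejected with the required
substep count, and statistically sensitive runs use finer substeps (the
near-wall density error is first order in step size). The Gaussian step
stream and all auxiliary randomness (initial placement, site geometry,
unbinding clocks) are independent children of the seed, so trajectories
are bit-reproducible and sticky mode with unit diffusion scaling shares
the step noise of free mode.

Fluorine-site geometry: six rigid sites per molecule at radii drawn from
[site_offset/2, site_offset] (default max 0.2 nm), fixed orientation.
These offsets are *not* a small perturbation for near-contact observables:
with b = 0.3 nm they inflate G(0) by ~3× over the centred hard-sphere
value, because 1/r⁶ is dominated by the closest approach of individual
sites. Theory-equivalence runs therefore use `site_offset = 0`, which
makes the simulated microphysics coincide with the centred analytic model;
the eccentric default is kept for occupancy, contact and clustering
analyses where molecular extent matters.

Sticky mode: a molecule whose centre enters the capture shell binds — its
diffusion is scaled by `bound_d_scale` and it is confined between the
solute sphere and the capture shell — and unbinds by a Poisson clock of
rate k_off, after which it must leave the shell before rebinding. The
unbinding clock runs from the binding substep, so k_off → ∞ degenerates
exactly to free dynamics. The confinement makes the logged bound
intervals the ground truth that distance-based contact detection must
reproduce, and makes bound durations exactly exponential with mean
1/k_off; finite windows right-censor long events, so the recovered mean
uses the standard censoring-corrected exponential estimator (total
exposure / number of observed unbindings). k_off = 0.05 ns⁻¹ reproduces
the ~20 ns rare persistent contacts regime.

An optional piecewise diffusion profile (scale vs distance from the
solute) imposes known near-surface slowdowns for validating the
distance-resolved diffusion estimator. The Itô convention without drift
correction is used; its steady state accumulates density ∝ 1/D in slow
regions, which is irrelevant to the local-D estimator but means imposed
profiles are not an equilibrium solvation model.

## Analysis modules

**Shells and occupancies.** Shells are 0.556 nm-wide concentric layers
around the reference hydrogen (shell 1 = 0–0.556 nm). Occupancies count
fluorine atoms and water oxygens per snapshot under the minimum-image
convention; the bulk water:fluorine ratio of the emulated composition is
7434/2892 = 2.57 (the printed variants 2.54/2.56 in the source tables are
rounding differences), and a shell ratio above the bulk value flags local
water enrichment.

**Contacts.** An H–F contact exists while the pair distance is ≤ 0.5 nm
(H–Ow: ≤ 0.4 nm); persistence follows the strict consecutive-snapshot
rule (one frame outside the cutoff ends the event), so durations have
±10 ps resolution at the default cadence. Events touching either
trajectory end are flagged censored; they count toward rates and
over-threshold percentages at their observed length but are excluded from
the mean duration of long (> 60 ps) contacts. Fluorine contacts are
atom-level by default (six fluorines of one HFIP can hold six concurrent
events, matching how the shell tables count fluorine atoms); molecule
-level aggregation is available via `per_molecule=True`.

**Diffusion.** Bulk D comes from the Einstein relation (MSD slope/6 over
a window defaulting to 10–50% of the span, averaged over molecules, with
a molecule-wise standard error); slow solutes use the fixed-interval
displacement estimator ⟨Δr²⟩/(6Δt) over 1000 successive 10 ps intervals.
The local profile bins molecules by origin-frame distance to the
reference hydrogen and converts each bin's MSD over a short lag (default
20 ps — long enough to beat binning noise, short enough that molecules
rarely change bins) to a local D; bins with fewer samples than a floor
are masked, and steps in D(r) are smeared over roughly a diffusion length
√(6D·lag) ≈ 0.1–0.25 nm, so recovery checks use bins ≥ 0.15 nm from an
imposed interface.

**Clustering.** Two HFIP molecules are linked when their minimum
interatomic minimum-image distance is ≤ a cutoff; aggregates are
connected components labelled by their smallest member. The underlying
study states no aggregation criterion, so the cutoff is a first-class
parameter (default 0.35 nm, a typical small-molecule contact distance at
the first RDF minimum) and is embedded in every output. Cluster lifetimes
chain components across consecutive analysed frames when they share at
least half of the larger component's members.

**Exponential fitting.** Variable projection (amplitudes solved linearly
per time-constant iterate) with bounded least squares on log τ from three
deterministic/log-spaced starts per order; model order is the smallest k
that a (k+1)-term fit does not significantly improve (F-test, α = 0.05),
with an AICc guard for ambiguous cases. Weights default to the inverse
per-origin standard errors of the correlation function. Identifiability
safeguards matter in practice: time constants are capped at 3× the lag
window (a τ beyond the window is indistinguishable from a slower one;
fits at the cap are flagged non-decaying and call for a longer window),
at most one term may lie beyond the window, and near-coincident τ pairs
(ratio < 1.2) or amplitudes above 3× the data scale are rejected as
degenerate directions — such cancelling pairs fit the window perfectly
but corrupt the extrapolated J(ω_H−ω_F), up to flipping the sign of
Σ_HF. Constant inputs short-circuit to a flagged plateau. Negative
amplitudes are allowed but flagged.

## Validation design and problem sizes

All validation runs on one CPU in minutes; sizes were chosen once as the
desk-scale analogue of the microsecond source simulations:

- **Theory equivalence** (the central property): 3×3 grid of
  b ∈ {0.3, 0.45, 0.6} nm × D ∈ {4.8, 10, 21.8}×10⁻¹⁰ m² s⁻¹, each point
  4 replicate trajectories of 20 000 frames × 100 centred-site HFIP in a
  6 nm box, origin stride 2, lag window 8τ_b (min 1 ns). Replicate
  averaging with mean-deviation uncertainty mirrors the study's own 5–10
  trajectory averaging and is needed because G(0) sampling noise is
  heavy-tailed (nearest-spin 1/r⁶). Pipeline vs matched theory agrees to
  a few percent at every grid point, within the 15% acceptance band.
- **Sign physics**: the analytic D-scan crosses zero exactly once at the
  default field; a fast free system (21.8×10⁻¹⁰) gives Σ_HF > 0 and a
  slow one (0.15×10⁻¹⁰) gives Σ_HF < 0, in both simulation and theory.
- **Parameter recovery**: Einstein D within 5% (300–500 molecules,
  1500–2000 frames), interval-displacement D within 20% single-run / 7%
  ten-seed mean, imposed 4× near-surface slowdown recovered within 15%.
- **Fit layer**: on 100 seeded three-term decays with 1% noise, J(0) is
  recovered within 5% in ≥95% of replicates; closed-form J(ω) matches a
  dense numerical cosine transform to <0.5%.
- **Sticky contacts**: detected contact events vs logged bound intervals
  reach ≥90% frame-wise intersection-over-union, with the 20 ns unbinding
  clock recovered within 15% over hundreds of events.

What this does and does not show: the synthetic systems validate the
*computational chain* — correlation accumulation, fitting, transforms,
unit handling, shell/contact/diffusion bookkeeping — against exact ground
truth and exact theory. They do not contain force fields, hydrogen
bonding, preferential solvation, solvent structure or peptide dynamics,
so passing them says nothing about whether a particular force field
reproduces experimental NOEs; absolute Σ_HF values, shell occupancies and
aggregation fractions of the real system are outside this package's
claims.

## Known limitations

- Rotational modulation of the H–F vector by HFIP tumbling is not
  modelled (translational-only, matching the effective-sphere picture);
  eccentric-spin (off-centre) analytic corrections are not implemented.
- The radial reflection scheme is first-order; near-wall observables need
  substeps well below the b/2 guard (the guard names the required count).
- The exponential tail extrapolation underestimates the t^(−3/2)
  long-time tail of free diffusion; with lag windows ≥8τ_b the effect on
  Σ_HF is at the percent level, but J(ω→0) of very slow systems is
  window-limited.
- Finite-size (periodic-image) effects on diffusion and long-lag
  correlations are not corrected, consistent with the assumption of
  negligible box-size artifacts in the emulated study.
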