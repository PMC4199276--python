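# Methods

## Scope

`axodiff` studies how the maximal gradient strength G_max of a PGSE
acquisition governs the contrast and stability of the fitted axon diameter
index a′. Everything is synthetic and seedable: substrates with known axon
diameter distributions (ADDs), signal synthesis (Monte-Carlo or analytic),
four-compartment model fitting with an MCMC posterior, and CRLB-guided
allocation of a measurement budget across HARDI shells. Scanner-side work —
image I/O, ROI drawing, coregistration, artifact handling — is out of scope;
`roi_summary` operates on plain value vectors.

## Protocols

A protocol is an ordered list of shells, each with shared pulse parameters
(G in mT/m, δ and Δ in ms, TE in ms) and a direction set; the first shell is
b = 0. Derived quantities use t_d = Δ − δ/3, q = (2π)⁻¹γδG with
γ = 2π × 42.57 × 10⁶ rad/s/T, and b = (2πq)²t_d. γ is fixed to that value
(not CODATA) so the shipped protocol tables reproduce their printed derived
columns. Interfaces accept table units; all computation is SI.

The built-in fixtures are the optimized ex-vivo protocols for G_max = 60,
140, 200 and 300 mT/m (T2 = 50 ms, T1 = 800 ms, 360 measurements each; the
b = 0 shell holds the remainder after the printed per-shell counts, giving
68–71 repetitions) plus two 300 mT/m variants optimized for artificially
long T2 of 400 and 4000 ms. The long-T2 tables print no per-shell counts or
TE; the fixtures use an equal 90-per-shell split and a TE just above the
longest δ + Δ — package choices, exposed as ordinary `Protocol` objects.
Two entries of the printed 140 mT/m table are internally inconsistent with
their own pulse parameters at any print rounding (the t_d/1/q/b triple of
its first shell matches δ ≈ 10.0, not the printed 10.4); the package always
computes derived quantities from the pulse parameters.

Direction sets are generated per shell by seeded electrostatic repulsion
with antipodal symmetrization (the tables specify counts, not coordinates).
Scheme I/O uses the STEJSKALTANNER one-measurement-per-line dialect in SI
units with a version header.

SNR-versus-TE adjustment uses snr_ref·exp((te_ref − te)/T2) with the
reference SNR 20 at te_ref = 62.7 ms. Note the reference TE is quoted as
62.7 ms for the 60 mT/m protocol while that protocol's table TE is 67.2 ms;
both constants are exposed and 62.7 is the default.

## Substrates and indices

Substrates are square periodic cells of non-overlapping parallel cylinders.
Packing fixes the cell size from area algebra, L = √(Σπr²/f_ic), so the
achieved intracellular fraction equals the target; placement is random
sequential addition (largest first) up to φ ≈ 0.35, then stepwise cell
compression (1.5 % per step) with collective rearrangement — over-relaxed
pair separation plus small random kicks when the overlap count stalls. This
reaches the 0.7 target for monodisperse mixes in well under a second; the
packer raises rather than ever returning an overlapping configuration.
Targets are capped at 0.7 (the disc bound is π/√12 ≈ 0.9069, but random
packings near it are impractical and 0.7 covers dense white matter).

The idealized index is the volume-weighted mean diameter α = Σa³/Σa²
(equal-length cylinders: volume ∝ a²). `alpha_truncated` excludes diameters
above a cutoff (default 10 μm). `weighted_index` generalizes α to an
arbitrary sensitivity modulation: given a discretized ADD p(a) and a
non-negative sensitivity f(a), both normalized to unit integral on a shared
grid, it returns the volume-weighted mean under the renormalized product
f·p. Constant f reproduces α exactly and a step f reproduces the truncated
α; the package pins down only these constraints, since no specific algebraic
form for f is canonical.

The default battery spans target α log-spaced over 0.5–15 μm (one per
substrate), cycling gamma shapes k ∈ {3, 10} (wide/narrow ADDs; scale
θ = α/(k+2) so the distribution-level volume-weighted mean hits the target)
and packing densities {0.45, 0.6}; 60 axons per substrate. Twelve substrates
is the desk-scale default, 44 the full-scale setting.

## Monte-Carlo signal synthesis

Spins take fixed-length 3-D steps √(6·D·dt) in uniformly random directions,
dt = duration/n_steps. Cylinder walls are impermeable: in-plane segments are
clipped against the circle cross-sections (nearest periodic image per
cylinder) and reflected specularly, up to 16 sub-reflections per step;
motion along the axis is free. Positions stay unwrapped so phase accrual
sees true displacements; periodicity enters only through the minimum-image
collision test. A step is dropped (position kept) in the rare event that 16
sub-reflections cannot resolve it; the run aborts if that happens for more
than 0.1 % of all steps, and a warning fires when the step length exceeds
r_min/3. Defaults: 10⁴ spins, 2000 steps, D = 0.45 × 10⁻⁹ m²/s (parallel
ADC of dense white matter at room temperature, fixed tissue).

Per measurement, the phase is the discretized γ∫s(t)·G·u·x(t)dt with the
rectangular effective gradient (+1 during the first pulse, −1 during the
second, pulses symmetric about TE/2, fractional weights at pulse edges);
the signal is |mean of e^{iφ}| over spins, and b = 0 measurements are exactly 1.
Cross-validation against the GPD closed form for a 4 μm cylinder over the
300 mT/m shells agrees to well under 1 %.

Rician noise replaces each magnitude S with |S + n₁ + i·n₂|, n₁, n₂ i.i.d.
zero-mean Gaussians of standard deviation 1/SNR (signals normalized to a
unit b = 0 level).

`free_displacement_stats` provides the displacement arithmetic that frames
the upper diameter bound: the 1-D rms displacement √(2Dt) (≈ 4 μm at the
largest 300 mT/m diffusion time of 18 ms) and the probability
2(1 − Φ(r/√(2Dt))) that a free 1-D displacement exceeds r — the fraction of
spins starting on a 10 μm axon's axis that reach the wall (≈ 22 % at
t_d = 18.1 ms). The boundary-reaching figure is deliberately the free-
diffusion exceedance, not a first-passage quantity; that is the arithmetic
that reproduces the quoted number.

## The MMWMD forward model

Four compartments with fractions summing to one: intra-axonal cylinders of
a single diameter a′ (GPD perpendicular attenuation, 30 roots of J₁′ at
double precision; free Gaussian along the axis), extra-axonal axially
symmetric tensor with the tortuosity link d_perp = d_par·(1 − f1/(f1+f2)),
CSF exp(−b·d_iso) with d_iso = 2.0 × 10⁻⁹ m²/s by default, and a
zero-displacement stationary compartment (S = 1), the appropriate ex-vivo
reading of an isotropically restricted pool. Diffusivities are fixed during
fitting (d_par = 0.45 × 10⁻⁹ m²/s by default); both are configurable.

`ForwardModel` precomputes per-measurement SI arrays and groups shells by
unique (δ, Δ) so one evaluation costs a ~60 μs vectorized pass — the MCMC
budget is dominated by these evaluations.

Fisher information is computed under Gaussian noise of σ = S0/SNR (offset-
Gaussian justification at the SNRs used) from a central-difference Jacobian
(relative step 10⁻⁴) over the free parameters (f1, f2, f3, a′, S0);
orientation is treated as known. CRLB(a′) is read from the inverse; a
singular matrix reports an infinite bound rather than raising.

## Fitting

Stage 1 scans a deterministic grid (a′ ∈ {0.5, 1, …, 16} μm ×
f1 ∈ {0.1, …, 0.8} × f3 ∈ {0, 0.1}, f4 = 0.05) by sum of squares, ties
breaking toward the smaller diameter. Stage 2 refines by L-BFGS-B on
transformed coordinates — softmax logits for the fractions, log a′ on
[0.1, 20] μm, log S0 — minimizing the offset-Gaussian objective
½Σ(√(S²+σ²) − data)²/σ² (plain least squares when no SNR is given), and
never returns a point worse than its initializer. Orientation comes from a
log-linear tensor fit on the lowest-b shell (the b = 0 mean supplies the
intercept; a single shell cannot separate it), antipodally canonicalized and
flagged when FA < 0.1.

Stage 3 is an adaptive Metropolis sampler on the same transformed
coordinates: componentwise Gaussian proposals with per-coordinate scales
adapted in blocks during burn-in toward a 0.1–0.6 acceptance window, plus,
each sweep, one joint proposal along the empirical covariance
(2.38²/d scaling, frozen at the end of burn-in) — needed because the intra
fraction and diameter trade off along a curved ridge that axis-aligned moves
explore poorly — and an occasional (10 %) independence proposal on log a′
drawn uniformly over its support, which lets the chain hop between a sharp
mode at the true diameter and the flat plateau below the resolution limit.
Priors are uniform on the natural parameters (the fraction simplex, a′ on
[0.1, 20] μm, S0), implemented as transform Jacobians; a prior left flat on
the transformed coordinates instead piles up at simplex corners and small
diameters and visibly distorts the weakly identified posteriors. The
reported a′ is the posterior mean; posterior overlap is histogram
intersection on a shared 64-bin grid. Defaults are 40,000 iterations /
10,000 burn-in / thinning 20 for production and 2,500/600/4 for desk-scale
batch runs. The noise σ is taken from the known simulation SNR, or can be
estimated from b = 0 repeats.

The full Rician likelihood (Bessel-I₀) is deliberately not used; the
offset-Gaussian approximation is standard at SNR ≥ 5 and keeps the
objective smooth.

## Shell optimization

The greedy reassignment starts from an equal split of 360 measurements over
the shells (b = 0 included) and repeatedly moves the single measurement
whose reassignment most increases the objective, stopping when no move
helps; ties break toward the lowest destination index. The objective is the
mean over a-priori tissue models (1, 4 and 20 μm at f1 = 0.7,
d_par = 0.45 × 10⁻⁹ m²/s) of −CRLB(a′), with per-shell unit information
matrices precomputed from each shell's own direction set and counts entering
as multiplicities — direction geometry is secondary at realistic counts, and
the counts-weighted form makes each greedy step O(1) matrix algebra.
Aggregation by mean is the default (min and product are available; the
choice is not pinned down by anything stronger than convention). The
continuous search over pulse parameters that produced the fixture tables is
out of scope; shells' pulse parameters are inputs.

## Experiment drivers and problem sizes

`run_gmax_comparison` crosses substrates × protocols, synthesizes the
noise-free signal once (analytic cylinder-mixture by default — the
area-weighted GPD mixture over the substrate's diameters plus the tortuosity
tensor — or Monte-Carlo), adds independent Rician trials, fits each trial
and tabulates a′ against α. `run_single_diameter_posteriors` does the same
for single-diameter substrates at f_ic = 0.7 and returns full posteriors;
`bounds_report` scans adjacent diameters and reports the smallest diameter
whose posterior is distinguishable from the next larger one (overlap below
0.5 by default — the threshold is a documented choice, always reported with
the bound). Desk-scale defaults — 12 substrates, 10 noise trials at SNR 20,
reduced chains — keep a full two-protocol comparison at about five minutes
on one CPU while preserving the orderings of interest; the analytic forward
isolates fitting behaviour from walker noise, and the Monte-Carlo source is
available where the walk itself is the object of study.

## What the synthetic data do and do not show

The generator reproduces the geometric essentials (polydisperse parallel
cylinders, periodic packing, restricted/hindered water, Rician magnitude
noise) but not orientation dispersion, undulation, permeable membranes,
gland/glial geometry, T2 differences between compartments, or gradient
nonidealities. Passing tests therefore demonstrate the estimator's behaviour
under its own generative assumptions plus walker-simulated restriction —
the contrast and stability orderings across G_max, the lower bound of a few
micrometres and the weakened sensitivity near 10 μm — not accuracy on real
tissue, where ADD width, dispersion and exchange further blur a′.

## Numerical notes and limitations

* GPD series: 30 Bessel-derivative roots; the a′ → 0 limit returns exactly 1
  and large radii at short t_d approach the free limit smoothly.
* Packing: clearance factor 10⁻⁹ keeps "non-abutting" strict; compression
  raises `PackingError` rather than relaxing the no-overlap invariant.
* Walker: reflections resolved to machine precision with a 10⁻⁹·r surface
  nudge toward the incoming side; phase discretization error is O(dt) and
  immaterial at ≥ 1500 steps for the protocols shipped.
* MCMC chains are single-chain; convergence is monitored only through
  acceptance windows and seed-to-seed agreement in tests. Very thin posterior
  tails (~10⁻² mass) need production-length chains to register in histogram
  overlaps.
* Histogram overlap depends weakly on the bin count (64 by default); it is a
  comparison statistic, not a calibrated probability.
* The lower bound reported by `bounds_report` moves with the overlap
  threshold; 0.5 is a convention.
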