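# Model and methods

`tumorsim` couples three descriptions of a growing solid tumor on a single
cubic lattice: discrete tumor cells (at most one per voxel), a discrete
endothelial segment network (one segment per voxel, on its own lattice), and
five continuum fields — interstitial pressure, oxygen `n`, carbon dioxide
`w`, tumor angiogenesis factor (TAF) `c` and cytotoxic drug `d`. All
concentration fields are evolved in units normalized by their standard
concentrations (`n0 = 8.4`, `w0 = 10.5` mol/m³, `c0 = 4.3e-4`, `d0 = 2.13`
mol/m³); pressure is in mmHg. One iteration represents 1/33 day; the default
full-scale problem is a 1 cm³ box at 200³ voxels simulated for 60 days.

## Interstitial pressure (growth-pressurization model)

Pressure is the sum of a cell-induced part (CTP) and a vasculature-induced
part (VTP). Each is a Gaussian-like kernel sum over sources within a
K-neighborhood cube (default K = 3):

    P(X0) = sum_i rho(theta) * exp(-|Xi - X0|^2 / (2 lambda(theta)^2)),

where `theta` is the occupied fraction of the (2K+1)³ cube around the *field
point* X0. The density maps are `rho(theta) = rho_max * theta` and
`lambda(theta) = lam_min + (lam_max - lam_min) * theta` (defaults 0.75 and
2.0 index units). `rho_max` is calibrated in closed form so that a fully
dense core reaches the configured dense-core pressure (60 mmHg for tumor
cells, 6 mmHg for endothelium); with everything else fixed this makes the
pressure scale an exact configuration input. Whether `theta` is evaluated at
the field point or at each source is ambiguous in kernel formulations of
this kind; this implementation evaluates it at the field point, which makes
the sum separable by squared distance and exactly reproducible by a
brute-force pairwise oracle. Interstitial fluid obeys Darcy's law
`u = -k grad p` with `k = 4.5e-15 cm²/(mmHg s)`; at that conductivity the
fluid moves well under one voxel per simulated run, so the transport step
skips the upwind convection pass whenever the per-step displacement is below
1e-4 voxel (the cumulative transport error of this cut-off is bounded by a
few percent of one voxel).

## Transport

Oxygen, CO₂, TAF and drug obey diffusion–convection–reaction equations
advanced by forward Euler with a 7-point Laplacian and first-order upwind
convection in flux form, Dirichlet values re-imposed on all six faces after
every sub-step. Sub-step counts satisfy
`(dt/m) (6D/h² + sum|u|/h) <= 1/2`. Negative values produced by explicit
sinks are clipped to zero and the clipped mass logged on the field.

Vascular exchange (oxygen supply, CO₂ uptake, drug extravasation) is
weighted by the radius factor `g = R / R_sat` and the clamped transmural
head `h = max(p_v - p_i, 0) / p_v`, so perfusion shuts down where the
interstitial pressure exceeds the capillary pressure (30 mmHg) — the
mechanism by which a high-pressure core starves itself even when
vascularized. Cellular reaction terms: oxygen consumption `lambda_n0 A n`,
CO₂ secretion `(rho_w0/w0) A`, TAF secretion `(rho_c0/c0) s(n)` with the
hypoxia weight `s(n) = max(0, 1 - n/n_thr)` (live cells only), TAF
clearance `lambda_c0 r(p) c` with `r(p) = p_ref/(p_ref + max(p,0))` — off by
default because the tabulated TAF clearance rate is zero.

## Cellular scale

Activity couples a cell to its microenvironment through a product of Hill
terms,

    A(n, w) = n² / (n² + K_n²) * K_w⁸ / (w⁸ + K_w⁸),   K_n = 0.25, K_w = 1.25.

The steep waste term encodes the sharp loss of proliferative capacity once
regional waste rises a few tens of percent above baseline. Each live cell
carries a Cell Vital Energy (CVE). Active cells (A > 0.5) gain
`k_active * A` and pay a Hill-shaped synthesis cost
(`coefficient 6, half-max 0.45, cost(1) = 0.76 k_active`); quiescent cells
(A <= 0.5) drain the housekeeping rate `k_quiescent = 0.1`; drug adds
`k_drug * A * d`. The cost constants are chosen so the *net* gain is
positive only above a proliferation checkpoint (A ≈ 0.75): cells divide when
well resourced, idle between the checkpoint and the quiescence threshold,
and a CVE that reaches zero is irreversible necrosis. Without the
checkpoint — e.g. with a shallow cost that leaves every A > 0.5 strongly
net-positive — marginally active rim cells divide almost as fast as healthy
ones and the growth front never arrests, so no stasis stage exists; the
checkpoint is what turns the waste signal into a growth-stage switch.

The division threshold is calibrated at start-up as
`2 * steps_per_day * net_gain(n=1, w=1)`; a newborn holds half its parent's
CVE, so the birth-to-division time under abundant oxygen is exactly one
24-hour day (33 steps). Daughters are placed on the unoccupied Moore
neighbor with the largest pressure drop, ties broken by a seeded uniform;
with no free neighbor the division defers and the CVE caps at the threshold.

## Angiogenesis

Tips advance up the TAF gradient one lattice step at a time once their
accumulated proliferation (`g1 + g2 max(p_v - p_i, 0)/p_v` grid-steps per
iteration, with a higher baseline inside tumor tissue) reaches one spacing;
direction weights are the positive directional TAF derivatives over the six
face neighbors, with uniform fallback when all derivatives vanish, and
necrotic or vessel-occupied voxels are never admissible. Branching hotpoints
are sampled per vessel-adjacent voxel with probability
`min(1, k_BH c^alpha_BH)` (k_BH = 3e-4, alpha = 1.3); at most one branch per
segment per step, and segments younger than `branch_min_age` cannot branch —
immature sprouts extend by tip migration, they do not ramify, which keeps
the angiogenic front speed a tip-migration property rather than a
branch-cascade property. Segment radii follow the saturating age map
`R = k_AR1 R_max Age/(k_AR2 + Age)`; tips stalled beyond the stall limit
age backwards, any segment reaching age zero is pruned together with its
distal subtree, and segments caught inside the necrotic core collapse.
Parent-vessel fixtures place every voxel of a mature vessel as an
independent root, because the pre-existing vasculature is perfused from
outside the simulated patch and must not be severed wholesale when the
tumor engulfs one voxel of it.

## Drug

Extravasation follows Starling's law with the Patlak partitioning between
convective and diffusive transmural exchange; the surface-to-volume ratio is
computed from the local segment radius (`2 pi R / h²`). The tabulated wall
conductivity makes the convective term strong enough that, with no washout
pathway in the model, interstitial drug at a vessel voxel would grow without
bound; the implementation therefore caps interstitial drug at vessel voxels
at the current plasma concentration (filtration cannot concentrate solute
above plasma). Net tissue-to-blood exchange is clipped off by default and
logged. Plasma concentration is a constant infusion level from the dosing
schedule (zero before the treatment start day). Cellular damage enters the
CVE balance as `k_drug A d` (k_drug = 0.5 per step per normalized unit), so
a plasma dose of 10 mol/m³ overwhelms the CVE gain of any active cell near
a vessel within a day, 1 mol/m³ slows cycling, and 0.1 mol/m³ is nearly
inert — the qualitative dose-response ordering.

A consequence of the waste-mediated growth control is worth flagging:
killing tumor cells removes waste secretors, so cytoreduction relieves the
metabolic inhibition of the survivors. Over windows of a week or more a low
or intermediate dose can leave the tumor *larger* than an untreated control
— accelerated repopulation. The dose-response scenario therefore doses an
established tumor grown around a static vessel grid (sprouting disabled, so
all dose levels share every random decision) and reads the viable count
three days after dosing starts, before repopulation can mask the direct
kill.

## Randomness and determinism

All stochastic decisions (division tie-breaks, branching Bernoullis, tip
direction draws) come from counter-based Philox streams keyed by
`(seed, step, purpose)` and indexed by voxel. A decision at a voxel on a
step is therefore independent of how many draws other code paths consumed:
trajectories are bitwise reproducible, and two runs that differ only in a
perturbation (a dose level, a pressure regime) share every random decision
until the perturbation changes the dynamics themselves. This is what makes
fixed-seed dose sweeps cleanly monotone.

## Desk-scale scenarios

The shipped scenarios keep the full-scale lattice spacing (5e-5 m), so all
per-voxel kinetics are untouched, and shrink the domain to a few millimeters
(50³ or 40³). To let the slow secreted-species dynamics complete within a
20-day horizon instead of 60+ days, the scenarios compress them:
vascular oxygen delivery ×8, CO₂ secretion ×16 with clearance ×32 and
diffusivity ×14 (so waste accumulates regionally on the compressed clock
while single-cell self-poisoning stays negligible), TAF secretion ×150 with
diffusivity ×2 (so the branching trigger, once the plume reaches the parent
vessel, is sharp rather than a long-tailed waiting time), sprouts start
partially matured (age 100) and may branch only above age 200. TAF is
initialized at zero and gated on `n < 0.75`, i.e. secreted by the
quiescent/idle population — angiogenesis is induced by quiescence — which
makes the avascular stages finish before the vascular rescue arrives. The
parent vessel runs along one axis offset 15 voxels from the tumor center:
far enough that its exchange halo does not feed the avascular tumor, close
enough that sprouts arrive within the horizon.

Under these conditions the reference run reproduces the canonical growth
phenomenology: exponential growth (T1) while the seed is unconstrained,
decelerating expansion (T2) as regional waste approaches the cycle-arrest
band, stasis (T3) with an expanding necrotic core once waste passes it, and,
only when angiogenesis is enabled, secondary growth (T4) when the sprouting
network reaches the rim, supplies oxygen and clears waste. The stage
detector classifies daily relative growth rates (window 1 day; exponential
≥ 30 %/day; the downward crossing below 12 %/day opens stasis; renewed
growth ≥ 10 %/day after stasis is secondary growth — the two tolerances are
asymmetric on purpose, one describes deceleration into stasis and the other
re-acceleration out of it); the lag before the first completed doubling is
not classified. These tolerances are matched to the desk-scale rate bands —
T1 runs at 40–200 %/day, the stasis plateau fluctuates at 2–7 %/day and the
vascular burst reaches 15–30 %/day — and are configuration parameters of
the detector, not of the model.

## What the synthetic scenarios do and do not show

The generator emulates: a five-cell seed in homogeneous tissue, growth
limited by oxygen and waste exchange, quiescence-induced TAF signalling, a
pre-existing vessel as the sprouting source, pressure-dependent perfusion
shutdown, and constant-infusion chemotherapy. It does not emulate: real
vascular geometry (the edge-list reader accepts measured networks, but no
measured data ship with the package), lymphatic drainage or systemic
pharmacokinetics, cell migration or invasion separate from division, or
mechanical tissue deformation. Passing tests therefore demonstrate the
internal consistency of the coupled model and the reproduction of the
qualitative phenomenology at desk scale — not calibration against any
particular tumor.

## Numerical choices and limitations

- Explicit stepping only; stability is enforced by sub-stepping, not by
  implicit solves. The steep-gradient limit is the vessel exchange terms,
  which are local and bounded by the clamped head `h`.
- Operator splitting order within one iteration: pressure → transport →
  cells → angiogenesis → bookkeeping. Cells see end-of-transport fields.
- Kernel pressure sums restrict to the bounding box of their sources; the
  result is exactly zero outside it by construction.
- Division order is increasing linear voxel index; earlier daughters block
  later ones, which the one-cell-per-voxel invariant requires.
- Boundary voxels hold Dirichlet values, so a tumor that reaches the domain
  face sees an unphysical fresh reservoir; scenarios are sized so the tumor
  stays clear of the boundary.
- The sensitivity harness averages fields over the whole grid (the
  alternative — tumor-region averages — is a one-line change but a
  different, sharper statistic).
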