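# Methods

This note documents the models implemented in `renalnet`, the choices made
where the design was genuinely open, and what the packaged defaults do and
do not represent.

## Vascular tree generation

Both generators are recursive, depth-first (first daughter first), and
enforce Murray's law exactly: at every bifurcation the second daughter is
the Murray complement D_d2 = (D_p³ − D_d1³)^(1/3) of the sampled first
daughter, and every side-branching arteriole in the kidney-specific tree
(KSABT) reduces the continuing vessel by the same cube rule. Murray
conservation is a validated invariant (relative cube error < 1e-9 at every
internal node) of every generated or loaded tree.

Sampling laws (all parameters live in a YAML profile, `profiles/default.yaml`):

| law | form | default |
|---|---|---|
| daughter diameter vs parent | Gaussian; cubic mean, linear SD | mean ratio ~0.80 (small D) to ~0.83 (renal artery); SD 0.2 + 0.025·D μm |
| vessel length vs diameter | Gaussian; linear mean and SD | mean 12·D μm, SD 3.6·D μm |
| inter-arteriole spacing | exponential, rate λ | λ = 0.015 μm⁻¹ (mean 67 μm) |
| side-arteriole diameter | Gaussian | 16.4 ± 1.8 μm |

Gaussians are truncated by rejection (100 retries, then clamping just
inside the boundary): daughter diameters to (0, D_p), lengths to (0, ∞),
arteriole diameters to (0, D_feed). A daughter draw above 0.99·D_p is
clamped to 0.99·D_p so the Murray complement stays a usable vessel.
Evaluating a fit outside its fitted diameter range is permitted but warned
about once per call site — the generator necessarily queries just below the
20 μm lower end near the stop diameter.

**Segmentation walk.** The KSABT walk carries a scalar shift S — the
remaining distance to the next arteriole site — along each vessel and into
its *first* processed daughter; second daughters and the daughters of the
unsegmented root restart the walk with a fresh exponential draw, which is
statistically equivalent by memorylessness. An attachment that would push
the continuing diameter to or below D_stop is not made and ends the walk
for that vessel. (Near-)zero spacings are legal — arterioles occur in
doublets — and materialize as segments of at least 1e-6 μm so the strict
positive-length invariant holds.

### Calibration of the default profile

The source fits for these laws are published only as figures, so the
default coefficients are approximate digitizations constrained by an exact
property of Murray trees: the cubes of all terminal diameters must sum to
the root diameter cubed. Consequently **arteriole count and arteriole
diameter are not independent**: N · E[D_aa³] = D_initial³. For a 530 μm
renal artery, terminal arterioles of 19.37 ± 1.36 μm imply ≈20,190
arterioles — and the calibrated default reproduces both (≈20,400 and
19.3 μm across seeds). A kidney-specific tree with ≈32,000 arterioles from
the same root *requires* a mean arteriole cube of ≈4,600 μm³, i.e. mean
diameters near 16.6 μm; a 19.25 μm mean would cap the count at ≈20,300.
The default therefore uses 16.4 ± 1.8 μm side arterioles, which yields
≈30,800 arterioles — matching the realistic whole-kidney nephron count —
at the cost of a smaller realized mean arteriole diameter (~17 μm) than
the morphometric tables suggest. Within the exact-Murray design this
trade-off is unavoidable; count (a functional quantity) was prioritized.

The length law (mean 12·D) reproduces the geometry of the two-nephron
electrotonic experiment (a ~300 μm feeding vessel of ~25 μm diameter) and
gives a several-mm renal artery; λ was then calibrated so the KSABT count
lands near 32,000.

## Hemodynamics

Each artery (never the arterioles) is a Poiseuille resistance
R = 128·η(D)·L/(π·D⁴); with η in cP and lengths/diameters in μm this is
directly in kPa·s/nL. η(D) is the in-vivo viscosity law at hematocrit 0.45,
η = [1 + 6e^(−0.085D) + 2.2 − 2.44e^(−0.06·D^0.645)]·(D/(D−1.12))², with
asymptote 3.2 cP. Pressure states sit on junction nodes with one global
compliance C_hdr = 3 nL/kPa (configurable within the stable range
0.3–5 nL/kPa); the root pressure is a fixed boundary and each nephron
appears as an outflow (P_node − P_g)/R_a at its arteriole-origin node,
with R_a supplied by the nephron model. Steady states are solved directly
as the sparse resistor-network linear system.

## Electrotonic coupling

Vessel walls are chains of units of one effective endothelial-cell length
(L_c = 50 μm); a unit lumps the N = round(πD/W_c) cells of the
cross-section (W_c = 5 μm), giving leak G_u = N·G_c, capacitance
C_u = N·C_c, and longitudinal gap conductance G_g = N·G_gj. Cell counts
round half away from zero and floor at 1. At a branch point the three
vessel ends couple through a triangle: each vessel's cells split toward
the other two in proportion to their diameters (largest-remainder
apportionment, so the parts sum exactly; an exact tie splits the leftover
cell evenly to keep the rule symmetric), and the pairwise junction count is
the mean of the two directed counts. A pairwise conductance can be exactly
zero when two small vessels meet a much larger one — connectivity is then
through the large vessel, and every vessel retains positive total coupling.
The root's upstream end is clamped toward rest through 2·N_root·G_gj.

Because membrane dynamics are treated as instantaneous and linear, the
voltage field is quasi-static: one sparse factorization gives the transfer
matrix K[m, n] — the voltage deflection at arteriole m's distal (macula
densa) unit per unit deflection at arteriole n's distal unit under test
current injection there. K is dimensionless, in (0, 1] and generally
asymmetric (signals prefer the wider branch).

One published coefficient was interpreted rather than transcribed: the
inner-unit balance as printed couples neighbors with the *leak*
conductance; this contradicts the adjacent equations and the circuit
figure, so the gap-junction conductance is used. The literal form remains
available via `ElectricalParams(eq6_literal=True)`.

**Coupling into the dynamics.** The published reduction states only that
macula-densa depolarization is proportional to the TGF activation Ψ. The
composition rule used here is
Ψ̃_m = Ψ_m + g_md · Σ_{n≠m} K[m,n]·(Ψ_n − Ψ_eq),
applied in the wall-equilibrium pressure only. The gain g_md (default 3.0)
is the one free parameter of the electrical pathway; it was calibrated on
the two-nephron Y fixture so that a transfer coefficient of ≈0.1 produces
in-phase locking while ≈0.05 does not, reproducing the published
synchronize/desynchronize dichotomy.

## Nephron model

Six ODEs per nephron (P_t, r, v_r, X₁, X₂, X₃) with the standard algebraic
closure: Henle flow (P_t − P_d)/R_Hen; afferent resistance
R_a = R_a0(β + (1−β)/r⁴); a cubic A·C_e³ + B·C_e² + C·C_e + D = 0 for the
efferent protein concentration; P_g = b·C_e² + a·C_e + P_t; the sigmoidal
activation Ψ(X₃) with Ψ(T·F_Hen0/3) = Ψ_eq = 0.38 exactly; and the
elastic/active wall equilibrium. The delay chain is the printed third-order
gamma approximation of the transport delay T — no delay-differential solver.

**The cubic's resistance ratio.** As printed, the closure defines
R = R_a0/R_a and uses R in the cubic coefficients. Deriving the cubic from
first principles (filtration equilibrium, blood conservation
F_in = F_filt + F_eff with F_eff = (P_g − P_v)/R_e, protein conservation)
reproduces the printed coefficients exactly — but with R = R_e/R_a. The
printed ratio violates blood conservation by ~26% at the operating point
and renders the operating point non-oscillatory; the flow-conserving
R_e/R_a is used. `afferent_resistance` still returns R_a0/R_a, which is the
correct ratio where it is genuinely needed (the passive-segment share of
the pressure drop in P_av).

The cubic is solved by vectorized Cardano with Newton polishing (residual
audited at < 1e-10 relative, with a bracketing fallback) at every
right-hand-side evaluation; in the filtration regime it has exactly one
positive root. When the feed pressure falls below the filtration regime
the positive root disappears; the right-hand side then falls back to the
no-filtration closure C_e = C_a, F_filt = 0, which lets the tubule drain
and reproduces the negative tubular pressures characteristic of
insufficient perfusion. Such nephrons are flagged and classified inactive.

**Single-nephron behavior with the tabulated constants** (measured by this
package's own sweeps): sustained TGF oscillations for feed pressures
P_a ≈ 11.6–13.9 kPa (amplitude ~0.7 kPa at 13.3, period ~30 s), an
efferent-flow plateau whose flattest 3-kPa window is ≈11–14 kPa, and
negative tubular pressure below ≈7 kPa. The oscillatory window shifts down
by about 1 kPa when β is lowered to 0.4; oscillations persist across
β ∈ [0.4, 0.67] and α ∈ [12, 20].

## Coupled network

The assembled system has one pressure state per junction node plus six
states per nephron; nephron feed pressures are bound to their
arteriole-origin nodes and nephron outflows are node sinks, with K applied
to the activations at every evaluation. The system is stiff (node
relaxation ~0.1 s vs the ~30 s TGF cycle), so the default integrator is
BDF with the model's Jacobian sparsity pattern; tolerances 1e-6 relative /
1e-8 absolute. Initial conditions: the published example nephron state with
a seeded ±0.01 kPa spread of tubular pressures to break symmetry, and node
pressures from a few fixed-point iterations of the steady linear solve.
All runs are deterministic given the seed.

Experiment windows default to 300 s transient discard + 300 s measurement
(≥10 TGF cycles). A nephron is "active" when its P_t peak-to-peak exceeds
0.01 kPa (well above solver noise, well below the ~1 kPa physiological
oscillations), its mean P_t is positive, and it stayed inside the
filtration regime. Phase extraction is by quadratic peak interpolation
with piecewise-linear phase; a pair is "in-phase locked" when the circular
variance of the phase difference is < 0.1 and the circular mean is within
π/4 of zero.

Network experiments are run on branches of tens of nephrons
(D_initial = 40 μm), where the whole physics is exercised in minutes on one
CPU; generation alone scales to the full kidney (~30k arterioles in ~1 s).

## What the defaults do and do not represent

The synthetic trees emulate measured morphometry in distribution (diameter
ratios, length-diameter scaling, exponential arteriole spacing, Murray
consistency) but have no 3D embedding, no arteriole triplets/quadruplets at
a single site, no juxtamedullary subpopulation, and no venous side. All
nephrons share one parameter set; heterogeneity, pulsatile flow, non-fixed
hematocrit and nonlinear membrane dynamics are out of scope. Passing tests
on these trees show the algorithms are faithful to the stated laws — not
that the laws exhaust real renal anatomy.

A known model-level tension, inherited rather than introduced: with the
tabulated constants no isolated nephron oscillates below ≈11.6 kPa, so on
a small kidney-specific branch the smallest root pressure with *all*
nephrons oscillating comes out ≈13 kPa, not ≈8 kPa as the source network
figures suggest; the qualitative contrast (the kidney-specific tree
activates at lower pressure than the terminal-only tree, which stays
silent at 10 kPa) is reproduced. The package reports what the printed
equations produce.
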