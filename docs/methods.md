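# Methods

## Lattice model

The membrane patch is a two-dimensional square lattice with periodic
boundaries.  Tracers perform one nearest-neighbour hop attempt per time
step; the direction is drawn from quartiles of a single uniform variate
(u < 0.25 left, < 0.5 right, < 0.75 up, else down).  The physical
constants are tied together by the free-diffusion closed form
⟨r²⟩ = 4DΔt per step, giving the hop length Δl = √(4·D·Δt).

| parameter | default | units | meaning |
|---|---|---|---|
| D | 0.2×10⁻³ | μm²·ms⁻¹ | receptor free-diffusion coefficient (extrasynaptic estimate) |
| Δt | 10⁻³ | ms | simulation time step |
| Δl | 8.944×10⁻⁴ | μm | lattice edge length, √(4DΔt) |
| n_side | 1119 (reference) / 200 (desk) | sites | lattice side; 1118 edges ≈ 1 μm |
| P_reflect | 0.5 | — | PRO partial-reflection probability |
| E | 2 / 6 / 10 | k_BT | weak / intermediate / strong binding energy |
| a_DT, a_CRO, a_PRO | condition | — | area fractions of tracers / reflecting / binding obstacles |

Sites-vs-edges: `derive_n_side` returns round(L/Δl) + 1 because a patch of
side L has round(L/Δl) edges; this is the reading under which a 1 μm side
yields 1119 sites from Δl = 8.944×10⁻⁴ μm.  Obstacle and tracer counts are
round-half-up of fraction × n_side²; realized fractions are recorded next
to requested ones.  Obstacles are placed uniformly at random without
overlap (exact counts, not per-site Bernoulli sampling); tracers are placed
uniformly on non-CRO sites, and a tracer placed on a PRO starts bound.

## Hopping rules

A CRO destination always reflects.  An unoccupied PRO destination reflects
with probability P_reflect; a tracer that enters a PRO site becomes bound.
A bound tracer draws an escape variate each step and participates only
when u < P_escape = e^(−E/k_BT); on escape it immediately attempts one
isotropic hop in the same step.  If that hop fails (reflection or
blocking), the tracer is still on its PRO site and is treated as bound
again — the bound flag is identical to "currently on a PRO site".  This
convention slightly lengthens dwell times at high blocking rates; the
alternative (escaped-but-unbound on a PRO site) would let a tracer sit on
a scaffold without interacting with it, which has no physical reading
here.

The escape inequality deserves a note: escape with probability P_escape
requires *u < P_escape*, so that larger binding energies give longer dwell
times (mean dwell 1/P_escape steps).  The opposite convention (escape when
u ≥ P_escape) would make strong binding release almost surely and is
retained only behind the `literal_escape` switch for comparison; the test
suite demonstrates the inversion it causes.

## Self-crowding and the recursive update

With steric exclusion, at most one tracer occupies a site and a PRO
holding a bound tracer acts as a CRO.  Tracers are updated sequentially in
fixed index order, which creates false self-blocking: a tracer whose
target is vacated later in the same step is wrongly reflected.  The
recursive update removes this artifact:

1. pre-draw all participation/direction variates;
2. sequential pass: apply the hop rules; tracers whose destination holds a
   tracer are labelled "blocked by another DT";
3. one re-check pass over the labelled set against the *same* destinations
   (directions are not redrawn).  Destinations now free are taken; a PRO
   vacated during pass one re-applies partial reflection with a fresh
   variate; the rest stay blocked;
4. time advances by Δt.

Exactly one re-check pass is performed, not iteration to a fixpoint, so a
dependency chain A←B←C may resolve only partially within one step.  The
pass-two sweep is itself sequential in index order, so a blocked tracer
may enter a site vacated by an earlier *blocked* tracer in the same pass.
Reflection variates are pre-drawn for every tracer each step (not lazily
on PRO contact); the draws are independent, so this is statistically
equivalent and keeps a single step-logic code path between the testable
single-step API and the compiled long-run loops.

MSD bookkeeping uses unwrapped displacement accumulators (±1 per accepted
hop), never wrapped coordinates; the MSD is displacement since measurement
start, averaged over tracers (ensemble definition) and then over
independent ensembles.  No time-averaging over sliding origins is used.
Under binding conditions the population is annealed for 2 s before the
measurement clock starts, so the bound fraction is stationary at t = 0.

Randomness: per-ensemble seeds are spawned from a root `SeedSequence`;
placement uses numpy Generators and the compiled stepping loop seeds the
kernel RNG once per run, so identical seeds give bit-identical output.

## Continuous-space oracle

Receptors are hard disks of exclusion radius 6 nm in a periodic square
box.  Each step proposes (Δx, Δy) = √(2DΔt)·(ξ_x, ξ_y) with independent
standard-normal ξ; disks are updated sequentially and a proposal that
would bring any pair of centres within 2r (minimum image) is rejected, the
disk keeping its position.  Rejection is the standard Monte-Carlo
realization of hard-core exclusion; specular "elastic" reflection is not
implemented, and this matters for interpretation: rejection dynamics
discards the entire step on contact, so the long-time mobility at area
fraction φ falls roughly as 1−2φ, a stronger suppression than the lattice
exclusion produces at equal nominal fraction.  Consequently the hard-disk
oracle is *slower* than both lattice variants at φ ≳ 0.1, and the
convergence comparison between the recursive and single-pass lattice
updates is informative mainly at dilute-to-intermediate densities (the
test suite documents where the ordering holds under these dynamics).
Periodic boundaries with minimum-image distances were chosen to match the
lattice engine and avoid wall artifacts.  A cell list (rebuilt per sweep,
5×5 neighbourhood scan to tolerate within-sweep cell drift) accelerates
pair checks without changing outcomes; small systems use all-pairs checks.
Initial placement is uniform rejection sampling; beyond the random
sequential adsorption saturation (~0.55) it falls back to a square grid
seed, recorded in the run metadata, which should be followed by an anneal.
Disk counts are round(φ·L²/(πr²)).

## Analysis

The ensemble MSD is fitted through the log-log profile
log(⟨r²⟩/t) = log(4D) + (α−1)·log t (natural logarithms).  Classification
is three-branch:

* **normal** — global |slope| ≤ 0.05 (`FLATNESS_TOL`): α = 1, D from the
  mean profile level, D_eff = D;
* **anomalous** — the last 25% of the log-time span has slope ≤ −0.5:
  long-range power law, α = 1 + tail slope, D from the tail intercept;
* **transition** — otherwise: local slopes over sliding windows of one
  fifth of the log-time span locate the first time after which the profile
  stays flat (the crossover time; the MSD there is the crossover length),
  and α is fitted on the segment before it.  If no sustained flat tail
  exists the first half is fitted and the crossover left undetermined.

α is clipped to [0, 1.05]; values above 1 (fit noise) are reported as 1
with regime normal.  D_eff for non-normal regimes is the apparent
diffusivity D_app(t) = D·t^(α−1) evaluated at t_obs = 2000 ms, the
measurement horizon; D_inst = α·D_app.  The flatness tolerance, tail
window and sliding-window width are exposed as keyword arguments; their
defaults separate clean α = 1 plateaus from transition profiles at the
ensemble sizes used here, and no estimator for the crossover is claimed
beyond this operational definition.  The generic power-law fitter
`fit_msd_powerlaw` accepts any positive (t, MSD) table and offers both the
default log-log linear fit and nonlinear least squares on the original
scale.

## Desk scaling

Reference-scale conditions (1119² lattice, 2 s measurement and annealing,
hundreds of ensembles) are far beyond interactive budgets, so the tests
and the acceptance script use desk scale: 100–200 site lattices, 20–200 ms
measurements and a handful of ensembles, with Δl, Δt, D and all
probabilities unchanged.  Area fractions, not absolute counts, control the
statistical regime, so desk runs preserve the phenomena at reduced
precision; every result row records which scale produced it.  Desk-scale
sizes were chosen so the full suite runs in minutes on one CPU.

## What the generator does and does not emulate

The synthetic worlds realize homogeneous, immobile obstacle fields and a
single uniform binding energy on a periodic patch.  Real PSDs have
inhomogeneous scaffold nanodomains, heterogeneous binding states, mobile
crowders and open boundaries with receptor exchange; none of these are
modelled, so passing tests demonstrate correctness of the stated model,
not fidelity to any particular synapse.  Rotational diffusion is
neglected; tracers are points (lattice) or monodisperse disks
(continuous).

## Known limitations

* The self-crowding lattice gas at low density (a_DT ≤ 0.01) produces only
  a per-mille-scale depression of the anomalous exponent over desk-scale
  windows — tagged-particle diffusion in a 2D lattice gas is
  asymptotically normal — so ordering claims at those densities sit at or
  below desk-scale statistical resolution.
* The rejection-dynamics hard-disk oracle is not a model of elastic
  collisions; see the continuous-space section.
* One re-check pass resolves most, not all, blocking chains; iterating to
  a fixpoint would be a different (also defensible) algorithm and is not
  the default.
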