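# crowddiff

Monte-Carlo simulation of receptor lateral diffusion in crowded
postsynaptic membranes.

AMPA-type glutamate receptors diffuse laterally in the postsynaptic
membrane and are trapped at high density inside the postsynaptic density
(PSD), a region crowded with inert transmembrane proteins and
receptor-binding scaffold proteins.  Because the receptors themselves are
bulky (a ~128 nm² steric footprint each), at synaptic densities they also
obstruct *each other*.  `crowddiff` is a simulator and analysis toolkit for
studying how these three crowding factors — inert obstacles, binding
scaffolds and receptor self-crowding — shape the anomalousness and
effective diffusivity of receptor motion.  It is aimed at computational
neuroscientists and membrane biophysicists who want a reproducible,
scriptable testbed for obstructed-diffusion experiments.

## Model

Receptors are point tracers hopping on a periodic square lattice, one
nearest-neighbour hop of length Δl per time step Δt, with Δl = √(4·D·Δt) so
that an unobstructed walk reproduces normal diffusion ⟨r²⟩(t) = 4Dt at the
receptor free-diffusion coefficient D = 0.2×10⁻³ μm²·ms⁻¹ (Δt = 10⁻³ ms,
Δl = 8.9×10⁻⁴ μm, a 1 μm² patch of 1119×1119 sites).  Lattice sites can
hold:

* **CRO** — completely-reflecting obstacle: always blocks a hop;
* **PRO** — partially-reflecting-cum-binding obstacle: blocks a hop with
  probability P_reflect (0.5 by default) and *binds* an arriving tracer,
  which then escapes per step with probability P_escape = e^(−E/k_BT);
* **DT** — a diffusing tracer.  In *self-crowding* mode at most one tracer
  per site; a PRO holding a bound tracer acts as a CRO.

Sequential updating of mutually excluding tracers creates *false
self-blocking*: tracer 1 can be blocked by tracer 2 even though tracer 2
vacates the contested site in the same time step.  The engine therefore
uses a two-pass recursive update: blocked tracers are labelled in pass one
and re-examined against their original destinations in pass two.  A
continuous-space oracle — hard disks of exclusion radius 6 nm moved by
Gaussian steps √(2DΔt)·ξ with hard-core rejection — provides an independent
check on the lattice algorithm.

Analysis follows the standard anomalous-diffusion decomposition
⟨r²⟩(t) = 4Dt^α: the log-log profile log(⟨r²⟩/t) vs log t has slope α−1,
and the effective diffusivity is D_eff = D·t_obs^(α−1) at the 2 s
observation horizon (equal to D when diffusion is normal).

## Worked example

Simulate 1000 independent tracers on an obstacle-free 200×200 desk-scale
lattice and characterize their motion:

```python
import crowddiff as cd

cfg = cd.LatticeConfig.desk(200)
sched = cd.SimulationSchedule(measure_ms=200.0, record_interval_ms=0.2,
                              n_ensembles=2, seed=101)
prof = cd.ensemble_msd(cd.simulate_ensemble(
    cfg, sched, a_dt=1000 / cfg.n_sites, exclusion=False))
char = cd.characterize(prof)
print(char.regime, round(char.alpha, 3), round(char.d_eff_nm2_per_us, 3))
```

```
normal 1.0 0.202
```

The walk is classified as normal diffusion (α = 1) with an effective
diffusion coefficient of 0.202 nm²·μs⁻¹, recovering the input
free-diffusion coefficient 0.2 nm²·μs⁻¹ to about 1%.  Adding reflecting
obstacles (`a_cro=0.2`) lowers D_eff to ≈ 0.10 nm²·μs⁻¹ while diffusion
stays normal; binding obstacles (`a_pro=0.4, binding_energy=6.0`) lower it
a further two orders of magnitude.

The same functionality is exposed on the command line:

```
crowddiff simulate --a-dt 0.002 --n-side 100 --measure-ms 50 --ensembles 4
crowddiff convert --density-per-um2 3000 --footprint psd95
crowddiff sweep crowding-switch
```

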