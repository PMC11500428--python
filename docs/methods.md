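# Methods

## The measurement

`slabhb` estimates the thickness of the liquid–vapour interface of a water
slab from the *convergence* of two deliberately biased estimates of
interfacial hydrogen-bond (HB) kinetics, evaluated as a function of the
interface-layer depth `d`.

The instantaneous liquid boundary is the Willard–Chandler construction:
the isosurface, at half the bulk value, of a Gaussian coarse-grained
oxygen density field.  The interface layer of thickness `d` is the region
between that surface and its copy translated a distance `d` along the slab
normal (z) into the liquid; a molecule belongs to the layer iff its oxygen
depth `a` below the nearer sheet satisfies `0 ≤ a ≤ d`.

Two population operators are correlated:

* **LC route (Scenario 1).**  The trajectory is cut into consecutive
  sub-trajectories of length `t_traj` (default 40 ps).  In each window the
  union of molecules found inside the layer at `n_sampling` evenly spaced
  moments (default 10) is collected, and the plain Luzar–Chandler
  populations `h` (pair H-bonded) and `h^d` (pair in O–O contact) are
  correlated over pairs drawn from that union, with no further interface
  gating.  Molecules that wander into the bulk keep contributing, so this
  route *under*estimates interfacial HB breaking.

* **IHB route (Scenario 2).**  The interface HB population
  `h^(s) = h · 1{both molecules in the layer}` (and its contact analogue
  `h^(d,s)`) is evaluated at every frame.  A pair whose partner leaves the
  layer counts as lost even if the bond survives, so this route
  *over*estimates interfacial HB breaking.

For either route the package computes

    c(t) = <h(0) h(t)> / <h>                       (survival correlation)
    n(t) = <h(0) [1 − h(t)] h^d(t)> / <h>          (broken but in contact)
    k(t) = −dc/dt                                  (reactive flux)

over all pairs and all origins on a uniform grid, and fits the kinetic
relation `k(t) = k c(t) − k′ n(t)` by bounded least squares over a lag
window (default 0.2–10 ps, excluding the sub-0.2 ps transient) to obtain
the breaking rate `k`, the reforming rate `k′`, and the HB lifetime `1/k`.

A property is then scanned over a depth grid (default 0.5–8 Å, step
0.5 Å): correlation values `c(t*)` at reference times `t* = 1, 2, 5` ps, or
the fitted breaking rates.  The depth beyond which the property stops
changing is the convergence depth; the LC and IHB routes give `d_f1` and
`d_f2`, and the thickness estimate is `d_f = (d_f1 + d_f2)/2`, always
reported together with both inputs, because the bracket is the
information.  The orientational anisotropy `C2(t) = <P2(û(0)·û(t))>` of OH
bond vectors (gated at the time origin only) and the persistence of free
(non-donating) OH groups provide independent scans through the same
machinery.

## Convergence detection

Two discrete stand-ins for `dC/dd = 0` are implemented in
`thickness.convergence_depth`:

* **threshold** — the smallest grid depth from which every later slope
  satisfies `|ΔC/Δd| ≤ tol · |C(d_max)|` (default tol = 1%/Å).  Appropriate
  when `C(d)` approaches its plateau steeply, e.g. exponentially.

* **knee** (pipeline default) — the depth maximizing the windowed
  curvature of `C(d)` (±1 Å slope windows), with a prominence guard
  (peak ≥ 2.5 × median curvature) that reports "not converged" for
  curvature-free profiles.

The knee mode is the default for a structural reason.  Any layer-averaged
property of a slab whose kinetics differ only within a band of width `d0`
carries a geometric-dilution tail: for `d > d0` the interfacial fraction of
the layer is `d0/d`, so `C(d) = C_∞ − d0·ΔC/d` and the slope decays as
`1/d²`.  A fixed slope threshold then triggers at
`d* = sqrt(d0·ΔC/(tol·C_∞))`, a depth set by the kinetic contrast `ΔC`
rather than by the band edge — and scaling as `sqrt(d0)`, it cannot track
the band edge across different `d0`.  The curvature of `C(d)`, by
contrast, peaks at the band edge itself, where the profile switches from
flat (pure interfacial layer) to the dilution tail.  The threshold mode
remains available (and exactly tested) for profiles without that
structure.

For property *matrices* (one column per reference time) the threshold mode
converges each column and takes the maximum depth; the knee mode pools
columns after subtracting each column's minimum — amplitude-weighted, not
range-normalized, so a reference time at which the property carries no
depth dependence (e.g. `C2` at `t* = 5` ps, which has fully decorrelated)
contributes little rather than injecting normalized noise.

## The synthetic slab generator

`synthdata.generate_markov_slab` emulates the statistical structure the
analysis measures, not water physics (no forces, no thermostat, no
capillary waves).  Design:

* **Disjoint donor–acceptor pairs on a lateral lattice.**  Pitches
  (8.75 Å × 4.25 Å) guarantee that molecules of different pairs never come
  within the 3.5 Å O–O cutoff, for any pair state and lateral jitter, so
  the geometric detector reproduces the generator's bookkeeping exactly
  (asserted with zero mismatches).
* **Pair states.**  Each pair carries an independent two-state telegraph
  HB process; geometry is snapped to canonical configurations — bonded
  (R_OO = 2.8 Å, donor H on the O–O axis), unbonded-in-contact (3.2 Å,
  donor H tilted 60°), or separated (4.5 Å; an unbonded sojourn is
  in-contact with probability 0.8).  Pair independence is what makes
  closed-form oracles available; the estimators under test are themselves
  pairwise.
* **Depth-dependent kinetics.**  Rates are (κ_i, κ_i′) = (1.2, 0.7) ps⁻¹
  when the pair sits within `d0` of the nearer surface and
  (κ_b, κ_b′) = (0.4, 0.7) ps⁻¹ deeper: interfacial HB breaking three
  times faster than bulk, reforming unchanged — the qualitative picture of
  faster interfacial HB dynamics, with `d0` (default 4 Å) the ground truth
  the pipeline must recover.
* **Stratified depths and swap exchange.**  The pair z coordinates form an
  exactly uniform grid over the occupied slab (|z| < z0 = 12 Å);
  z-exchange swaps the z values of random pair couples at a per-pair rate
  of 0.02 ps⁻¹.  Swapping preserves the z multiset, so the density profile
  is statistically static while molecules migrate between layers.  The
  mean layer residence (50 ps) slightly exceeds `t_traj = 40 ps`: molecules
  can leave the layer within a sub-trajectory but most do not, which is
  the premise of the LC sampling scenario.
* **Scale.**  576 waters, 8000 frames at 0.1 ps (800 ps) by default — a
  problem size that keeps the full four-route analysis under a minute on
  one CPU while leaving the depth-scan noise well below the kinetic
  contrast.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: HB-network cooperativity (pairs are
independent), capillary-wave roughness (the surface is flat), realistic
molecular densities (the pair lattice is ~15× sparser than water; surface
analyses of the synthetic slab use ξ = 4 Å, grid 2 Å instead of the
standard ξ = 2.4 Å, 1 Å), continuous diffusion (depth changes are jumps),
and surface-localized dangling OH.  The last point matters for the
free-OH route: in the generator three of four OH groups never donate at
*any* depth, so the free-OH population is depth-uniform and its depth scan
has no sharp marker at `d0`; the free-OH operator and scan are therefore
exercised for correctness (telegraph closed form, physical bounds,
monotone persistence) but no thickness recovery is claimed for that route
on synthetic data.

## Numerical choices

* Coarse-graining kernel truncated at 4.5 σ so the field integrates to the
  atom count to better than 1e-3 (a 3 σ spherical cutoff would lose 2.9%).
* Surface sheets from the outermost isovalue crossing per lateral column
  (single-valued height field; overhangs ignored), linear interpolation
  between grid planes; an OBJ/TSV exporter serves visualization.  A
  laterally averaged "flat" mode handles interfaces that are flat by
  construction.  Time-averaged density (default stride 10) is used when
  the interface is statistically stationary.
* Bulk density measured from the central 25% of the occupied z range;
  isovalue = half of it, per frame or per averaged field.
* Correlations use every frame as a time origin (0.1 ps spacing) with
  per-lag origin normalization, FFT-based accumulation over pairs, and the
  pair universe fixed to all pairs ever in contact (absent pairs
  contribute zeros).
* Reactive flux by second-order central differences (one-sided at the
  ends); `∫k dt = c(0) − c(T)` holds to differencing order.
* Rate fits by non-negative linear least squares; when `n ≡ 0` in the
  window the design is singular and `k′` is reported as undefined rather
  than zero.
* Biexponential `C2` fits use bounded trust-region least squares with
  multistart over log-spaced time constants; components are relabeled so
  `τ1 ≤ τ2`, and near-single-exponential solutions are flagged degenerate.
* O–H covalent assignment cutoff 1.2 Å; z is treated as non-periodic for
  all depth logic even if a file declares a periodic cell.
* All generator randomness flows from a single seed; identical seeds give
  byte-identical trajectories and reports.

## Known limitations

* The knee detector assumes the scanned property has a kink; on profiles
  with smooth curvature everywhere it returns the curvature maximum, which
  need not mark an interface.  Judging "no structure at all" reliably
  requires error bars (block resampling is available for that purpose).
* The height-field surface ignores overhangs by construction; droplets
  and bicontinuous geometries are out of scope.
* Scenario 1 windows are non-overlapping with the trailing partial window
  discarded; very short trajectories lose statistics accordingly.
* The LC/IHB bracket is an ordering of expectations; at depths where the
  two routes nearly coincide, sampling noise can bring the measured gap
  near zero (tests allow for this within the measured dynamic range).
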