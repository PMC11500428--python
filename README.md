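# slabhb

Air–water interface thickness from two bracketing views of interfacial
hydrogen-bond dynamics.

## The problem

Interfacial water behaves differently from bulk water, but deciding *where
the interface ends* is notoriously ambiguous — experimental and simulation
estimates for the air–water interface span roughly 3–10 Å.  `slabhb`
implements a kinetics-based determination for molecular-dynamics slab
trajectories.  It is aimed at simulators post-processing water-slab (or
solution-interface) trajectories who want a thickness estimate that does
not rest on a density criterion.

## The idea

Let `h_ij(t)` be the Luzar–Chandler HB population (1 when waters *i, j*
are H-bonded under the geometric criterion `R_OO ≤ 3.5 Å`,
`∠H–O_d–O_a ≤ 30°`) and let the interface layer of depth `d` be the region
between the Willard–Chandler instantaneous surface and its copy translated
`d` into the liquid.  Two estimates of interfacial HB kinetics bracket the
truth:

* **LC scenario** — correlate plain `h` over molecules sampled from the
  layer during 40 ps sub-trajectories.  Sampled molecules may drift into
  the bulk, whose slower HB breaking contaminates the estimate from below:
  it **under**estimates interfacial HB breaking.
* **IHB scenario** — correlate the interface HB population
  `h^(s) = h · 1{both molecules in the layer}`.  Pairs whose partner
  leaves the layer count as losses: it **over**estimates interfacial HB
  breaking.

From either population the package builds the correlation functions
`c(t) = ⟨h(0)h(t)⟩/⟨h⟩`, `n(t) = ⟨h(0)[1−h(t)]h^d(t)⟩/⟨h⟩`, the reactive
flux `k(t) = −dc/dt`, and the rate constants from
`k(t) = k c(t) − k′ n(t)`.  As `d` grows, both scenarios converge to the
same (layer-averaged) kinetics; the depth at which a scanned property —
`c(t*)` at `t* = 1, 2, 5` ps, or the fitted breaking rate — stops changing
gives a convergence depth per route (`d_f1` for LC, `d_f2` for IHB), and

    d_f = (d_f1 + d_f2) / 2

is the thickness estimate.  Orientational anisotropy decay
`C2(t) = ⟨P2(û(0)·û(t))⟩` of OH bonds and free-OH persistence provide
independent scans through the same machinery.  See `docs/methods.md` for
the full model, parameter defaults, and numerical choices.

## Worked example

The package ships a synthetic-slab generator with *known* depth-dependent
HB kinetics: 576 waters in isolated donor–acceptor pairs, interfacial
breaking rate 1.2 ps⁻¹ within 4 Å of the surface, bulk rate 0.4 ps⁻¹
deeper, slow layer exchange.  Because the construction depth `d0 = 4 Å`
is known, the full pipeline can be validated end to end:

```python
from slabhb import SyntheticSlabSpec, generate_markov_slab
from slabhb.pipeline import AnalysisConfig, SlabAnalysis

slab = generate_markov_slab(SyntheticSlabSpec(seed=1))
config = AnalysisConfig(xi=4.0, grid_spacing=2.0, surface_mode="flat")
analysis = SlabAnalysis(slab.trajectory, config)

corr = analysis.hb_correlation_scan()   # c(t*) and c^(s)(t*) over d
rates = analysis.hb_rate_scan()         # k_LC(d), k_IHB(d)
print("correlation route: d_f1 =", corr.d_f1, " d_f2 =", corr.d_f2,
      " d_f =", corr.d_f)
print("rate route:        d_f  =", rates.d_f)
print("k_IHB(0.5 A) = %.3f  k_LC(0.5 A) = %.3f ps^-1"
      % (rates.matrices["IHB"][0, 0], rates.matrices["LC"][0, 0]))
```

prints

```
correlation route: d_f1 = 4.0  d_f2 = 4.0  d_f = 4.0
rate route:        d_f  = 4.0
k_IHB(0.5 A) = 1.244  k_LC(0.5 A) = 0.847 ps^-1
```

Both routes recover the constructed 4 Å interface depth.  The rate pair
shows the bracket at a thin layer: the IHB estimate (1.244 ps⁻¹) exceeds
the construction's interfacial rate (1.2 ps⁻¹, inflated by layer-exit
events) while the LC estimate (0.847 ps⁻¹) falls below it (diluted by
bulk excursions); both relax toward the bulk rate as `d` grows.

The same analyses run from the shell on any extended-XYZ slab trajectory:

```sh
slabhb synth --seed 1 --out slab.extxyz
slabhb thickness slab.extxyz --property correlation --property rate \
       --config analysis.toml --out-dir out/
slabhb hbcorr slab.extxyz --method both --d 2 --d 4 --out-dir out/
slabhb c2 slab.extxyz --d 4 --out-dir out/
```

`thickness` writes a JSON report with the scan matrices, `d_f1`, `d_f2`,
`d_f`, and the fully resolved configuration; "not converged" is an
explicit report field, not an error.

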