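# polypack

Monte Carlo simulation and crystallographic structure identification for
coarse-grained polymer and sphere packings under extreme conditions —
dense/jammed states, hard confinement, and nanofilled matrices.

`polypack` is aimed at researchers studying entropy- and energy-driven
ordering in particulate and macromolecular systems: how chains of (nearly)
tangent hard spheres pack, jam and crystallize; how square-well attraction
drives cluster and crystal formation; and how walls, cylinders, spheres
and immobile nanofillers reshape the accessible volume.

## Model

Systems contain `N_at` spherical monomers: `N_ch` linear chains of mean
length `N` plus `N_s` single monomers, `N_ch·N + N_s = N_at`.  Reduced
units: the collision diameter σ is the unit of length, `k_B T` the unit of
energy.  Non-bonded pairs interact through hard-sphere (HS), square-well /
square-shoulder (SW/SS, range σ₂, strength ε_SW) or Lennard-Jones
potentials; bonds live in a window `[σ, σ + dl]` (tangency `dl = 0`
supported) and chain stiffness enters through a harmonic bending potential
`U = k_θ (θ − θ₀)²` on the supplement θ of the bond angle, with an
optional torsion hook (off by default).

Sampling combines four move families in NVT, NPT and semigrand ensembles:

* **local moves** — single-site displacement, flip, end-mer rotation,
  reptation, intermolecular reptation, end-segment regrowth, all optionally
  executed in a configurational-bias (CB) pattern with `n_trials` trial
  placements and Rosenbluth-weight acceptance;
* **connectivity-altering moves** — simplified end-bridging (sEB),
  intramolecular end-bridging (sIEB) and double bridging (sDB), which
  delete and form bonds between bridgeable pairs without displacing sites;
* **identity exchanges** — IdEx1/2/3 swap single monomers in and out of
  chains;
* **collective moves** — rigid cluster displacement/rotation on
  proximity-detected clusters, volume-fluctuation moves, and a compression
  protocol that drives athermal systems to their jammed state.

Three density measures quantify crowding: the packing density
`φ = (π/6)(N_at/V)σ³`, the effective density `φ_eff = V_mon/(V − V_fill)`
that removes the nanofiller volume, and the depleted density `φ_dep` that
additionally strips the σ/2 layer next to every wall and filler surface
that monomer centers cannot enter.

The **descriptor** assigns each site a similarity norm against reference
crystals — FCC, HCP, BCC, HEX and fivefold (FIV) local symmetry in 3-D;
triangular, square, honeycomb and pentagonal in 2-D.  The norm is the
worst-element RMS self-mismatch of the site's Voronoi neighbor shell under
the crystal's characteristic symmetry operations, minimized over the
orientation of the element frame; a site is labeled with its arg-min
crystal when the minimum norm falls below the threshold ε_thres = 0.245,
otherwise AMO (amorphous).  Crystallinity is `τ_c = S^HCP + S^FCC`.

## Worked example

Build the 48-chain, `N = 100` hard-sphere nanocomposite (4800 monomers at
`φ = 9.9×10⁻³`) with a single immobile nanosphere of diameter `d_sph = 5σ`
and measure the three density measures; then label a thermally jittered
FCC crystal:

```python
from polypack import generate_ideal_lattice, cce_norms, label_sites
from polypack.cce import order_summary
from polypack.scenarios import ScenarioSpec, run_scenario

r = run_scenario(ScenarioSpec(
    "nanocomposite",
    {"phi": 9.9e-3, "d_sph": 5.0, "n_chains": 48, "chain_length": 100},
    seed=1,
))
print(f"phi      = {r.series['phi'].iloc[0]:.6f}")
print(f"phi_eff  = {r.series['phi_eff'].iloc[0]:.6f}")
print(f"phi_dep  = {r.series['phi_dep'].iloc[0]:.6f}")

cfg = generate_ideal_lattice("FCC", 4, noise=0.05, seed=7)
labels = label_sites(cce_norms(cfg))
s = order_summary(labels, cfg, include_voronoi=False)
print(f"tau_c = {s.tau_c:.3f}, S_FIV = {s.s_fiv:.3f}")
```

prints

```
phi      = 0.009900
phi_eff  = 0.009903
phi_dep  = 0.009904
tau_c = 0.988, S_FIV = 0.000
```

The filler barely dents the accessible volume at this dilution, so
`φ_eff` rounds to 0.01 at two decimals while exceeding `φ` only in the
fourth significant digit; and 98.8% of the jittered crystal sites keep
their FCC label at the 0.245 threshold, with no spurious fivefold sites.

A command-line interface mirrors the library (`polypack generate |
simulate | describe | analyze | scenario`); each verb takes a YAML run
configuration and writes extended-XYZ configurations, CSV series and JSON
summaries.

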