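# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `polypack`, and states the problem sizes its validation
suite actually runs.

## Units, cells and geometry

All lengths are in units of the monomer collision diameter σ and all
energies in k_B·T.  Cells are orthogonal, origin at a corner; coordinates
on periodic dimensions are wrapped into `[0, l)`, confined dimensions are
never wrapped or imaged.  Confinement comes as flat walls (any subset of
dimensions), a cell-spanning cylinder (open = periodic or closed ends) or
a sphere; monomer centers keep a σ/2 clearance from every confining and
filler surface.  For cylindrical/spherical confinement the cell "volume"
used by the packing density is the volume of the confining body itself,
which is the natural denominator for a confined packing fraction.  The
cell aspect ratio ζ is the largest inter-surface distance divided by the
smallest (cylinders report length/diameter through the same rule).

Density measures: `φ = V_mon/V`, `φ_eff = V_mon/(V − V_fill)`,
`φ_dep = V_mon/V_dep` with
`V_dep = Π_{i confined}(d_wall(i) − σ)·Π_{j free} l_j − (π/6)(d_sph+σ)³N_sph
− (π/4)(d_cyl+σ)²L_cyl·N_cyl`.  Because removing filler volume and
depletion layers shrinks the denominator, `φ ≤ φ_eff ≤ φ_dep` whenever
fillers or confinement are present.  The non-depleted cylinder volume in
`φ_eff` is `(π/4)d_cyl²·L_cyl` (full cell span); in 2-D all "volumes"
become areas with `(π/4)σ²` per disk.

## Interactions

Hard-sphere overlap is open at contact: a pair at exactly σ is tangent,
not overlapping (numerically, a 10⁻⁹ slack absorbs round-off, which also
makes tangent bonds `dl = 0` representable).  SW/SS are the ±ε_SW step on
`[σ, σ₂)`; SS is the sign flip of SW.  LJ is `4ε[(σ/r)¹² − (σ/r)⁶]`
truncated and (by default) shifted to zero at `2.5 σ_LJ`.  Bonded (1–2)
pairs are excluded from non-bonded sums but constrained to the bond
window; 1–3 pairs interact non-bonded by default (`exclude_13` switches
this off).  Hard-core violations propagate as an infinite-energy
sentinel, never as exceptions.

Cell lists bin sites on a grid with bin edge ≥ the interaction range
(separate overlap-range and cut-off-range grids when the potential has
both scales); every energy/overlap query over the 3^dim stencil is
equivalent to the all-pairs sum, which the suite verifies on random
configurations.  A site would overlap its own periodic image when a
periodic cell length drops below σ, so volume moves reject that region
outright; with the minimum-image convention this makes the hard-core test
exact for all cell sizes ≥ σ (the monomer-kernel path requires ≥ 3σ for
its 3-bin cell list).

## Monte Carlo moves

**Local.**  Displacement proposals are component-wise uniform in
`[−l_disp, l_disp]`; flip rotates an interior monomer about its
neighbor–neighbor axis (2-D: reflection across that line); end rotation
redraws the terminal bond direction in a cone and its length in the bond
window.  All three are symmetric proposals with plain Metropolis
acceptance on the local energy change.

**CB regrowth.**  Reptation, intermolecular reptation and end regrowth
rebuild monomers with the shared trial sampler: bond length uniform in
the window, bending supplement angle drawn from
`exp(−k_θ(θ−θ₀)²)·sin θ` by rejection, azimuth (torsion) uniform.  Trial
weights contain only the *external* energy (non-bonded, walls, fillers,
plus torsion when a torsion potential is active); the proposal density
absorbs the bonded terms.  With `n_trials` trials the selected candidate
is drawn proportionally to its weight and acceptance is
`min(1, W_new/W_old)` with the reverse Rosenbluth weight rebuilt from the
old position plus `n_trials − 1` regenerated alternatives; `n_trials = 1`
reduces exactly to Metropolis and skips the reverse work.

**Connectivity-altering and identity exchanges.**  sEB/sIEB/sDB and
IdEx1–3 displace no sites.  Candidates are pairs within the bridgeable
window `[bond_min, bond_max]`, selected uniformly from the precomputed
candidate list; the acceptance carries (i) the forward/reverse candidate
count ratio (required for reversibility; the candidate pool changes with
the move), (ii) the semigrand length-weight ratio `Π w(N_new)/Π w(N_old)`
and (iii) the Boltzmann factor of the bonded-energy change plus the
non-bonded energy of pairs whose bonded status flips.  IdEx3 additionally
corrects for the donor-chain pool size on both sides.  Strict
monodispersity deactivates sEB, intermolecular reptation and IdEx3 and
renormalizes the remaining schedule.

**Semigrand length control.**  The relative chemical-potential spectrum is
encoded as target length weights `w(N)` on `[N_min, N_max]`: `uniform`,
or `flory` with `w(N) ∝ p^N`, `p = 1 − 1/⟨N⟩`.  At fixed total length a
geometric weight cancels against the constraint, so the exact stationary
marginal is the fixed-total enumeration; the validation suite compares
the sampled histogram against that enumeration (dynamic-programming
oracle) through the fitted decay parameter.

**Collective.**  Clusters are single-linkage components of the
minimum-image proximity graph (default linkage 1.05σ, configurable; an
optional label condition restricts linkage to same-label pairs).  CluDis
translates, CluRot rotates a uniformly chosen cluster rigidly about its
center of mass; proposals that would merge clusters are rejected outright
— a restriction that keeps every accepted move exactly reversible — and
the moves deactivate automatically when fewer than two clusters exist.
Volume moves rescale free (unconfined) dimensions affinely, isotropically
or one dimension at a time, with acceptance
`min(1, exp(−PΔV + N_at ln(V'/V) − ΔE))` on uniform-in-V proposals; for
pure HS under isotropic scaling all angles are preserved and the energy
terms reduce to the overlap test.

**Compression.**  Jamming runs alternate displacement sweeps with
shrink-only volume moves whose relative amplitude adapts (grows ~5–15% on
success, decays ~25% on an overlap rejection), so the quench slows down
smoothly as the packing approaches its jammed state; the volume is
monotone non-increasing by construction and the run ends when the
amplitude collapses.  Walls are respected by scaling only free
dimensions (a documented protocol difference from wall-wrapping
compaction schemes).  The quench rate is a physical dial: very slow
schedules at 10²-sphere sizes start annealing into crystalline patches,
so the default schedule is chosen fast enough that the terminal states
stay predominantly disordered (fivefold-rich) while still reaching
φ ≈ 0.64.

**Performance split.**  The object-oriented move machinery covers chains,
confinement, fillers and SW/LJ energetics.  Monomeric hard-sphere
workloads that need millions of sweeps (compression, NPT equations of
state, crystallization) run through numba kernels over flat arrays
(`hs_fast`); both paths share the same physics and the suite cross-checks
them against analytic oracles (Carnahan–Starling, accessible-volume
distributions).

## Structure descriptor

Voronoi neighbors are sites sharing a positive-area Voronoi face,
computed with ghost images across periodic boundaries (ghost shell width
defaults to half the smallest cell length; a few σ suffices for dense
systems).  Exactly degenerate inputs (ideal lattices) are regularized by
a deterministic 10⁻⁹ jitter, and the spurious near-zero faces this
creates are removed by a relative face-area threshold (10⁻⁵ of the
site's largest face).  Unbounded cells at open boundaries contribute only
their bounded faces.

The norm of a site against reference crystal X:

1. if `N_vor < N_coord(X)`, a constant penalty norm 1.0 applies (clearly
   above every labeling threshold);
2. otherwise the `N_coord(X)` closest neighbors are kept.  When the
   distance at the truncation boundary is degenerate (e.g. keeping 12 of
   the 14 BCC faces, or 8 of 12 equidistant FCC neighbors), each
   admissible tie resolution is a valid shell; the norm is the *worst
   case* over them (lazily enumerated, capped, and stopped early once
   safely above threshold), so degenerate shells never score better than
   their least symmetric resolution;
3. neighbor vectors are normalized by their mean length;
4. for each symmetry element of X the element's operations are applied
   and the RMS distance of each transformed vector to its nearest
   original vector is collected; the score of an orientation is the
   *largest* per-element RMS — a crystal is matched only when every
   characteristic element maps the shell onto itself;
5. the element-frame orientation is scanned on a mesh of width φ_step
   (default 10°, same step for azimuthal and polar angles; a third Euler
   angle over the element-set period for the multi-axis FCC and BCC
   sets), followed by local refinement multi-started from the eight best
   coarse basins and halving the step six times.  In 2-D proper rotations
   commute and no scan is needed.
6. the RMS is multiplied by a fixed calibration constant 0.87, part of
   the norm definition, placed once so that the 0.245 labeling threshold
   separates thermally jittered own-crystal shells (0.05σ Gaussian noise
   keeps ≳97% of FCC sites below threshold) from every ideal
   cross-crystal shell (all ≥ 0.26).

Element catalog (data, overridable): FCC — three fourfold roto-inversion
axes along the cube axes; HCP — one sixfold roto-inversion axis; BCC —
four threefold roto-inversion axes along the cube diagonals plus the
inversion center, on the 8 nearest neighbors; HEX — one sixfold rotation
axis (N_coord 8); FIV — one fivefold rotation axis on the icosahedral
12-shell; 2-D: six-, four-, three- and fivefold rotations for TRI, SQU,
HON and PEN.  The fivefold references (FIV/PEN) are local symmetries, not
space-filling crystals; their generator fixtures are finite
center-plus-shell clusters.

Labeling takes the arg-min crystal when the minimum norm is ≤ ε_thres
(default 0.245), else AMO; AMO means "similar to none of the cataloged
references", not proof of disorder.  The on-the-fly mode stops each scan
once a value at or below threshold is found; it accelerates labeling
without changing any label.  Order summaries report per-crystal
fractions, crystallinity τ_c (= S^HCP + S^FCC in 3-D, S^TRI in 2-D), the
fivefold fraction, same-label proximity clusters with gyration-tensor
shape metrics, and Voronoi cell volume/face statistics.

## Synthetic generators

`generate_ideal_lattice` builds periodic supercells (FCC, HCP at the
ideal c/a, BCC, simple-hexagonal HEX with c = a, TRI, SQU, honeycomb)
or finite fivefold clusters, with optional seeded Gaussian jitter — these
are the descriptor's validation fixtures.  `generate_dilute_system` grows
non-overlapping chains as non-reversal random walks using the same trial
sampler as the CB moves, plus uniformly placed singles, honoring
confinement and filler clearances; dense states are then reached by
compression or NPT, never by direct dense insertion.  Generation is
deterministic per seed; all run-level randomness flows from a single seed
through per-component substreams.

What the generators do *not* emulate: real polymers have chemical detail
(torsion potentials are off by default), polydispersity beyond the
uniform/Flory families, and fillers are immobile ideal geometric bodies.
Passing tests therefore demonstrate correctness of the sampling and
analysis machinery on the coarse-grained model, not agreement with any
specific experimental polymer.

## Validation protocols and problem sizes

The suite is sized for a single desktop CPU; the application-scale
conditions (tens of thousands of sites, 10¹¹ steps) remain reachable
through the same parameters.

* worked density examples: the 4800-monomer nanocomposite is built
  explicitly; the large-filler case (d_sph = 20 at φ = 0.29) is checked
  as an interval over the two-significant-figure input precision;
* lattice analytics: 3³–4³ supercells; every fixture must be fully
  own-labeled and all-AMO against every foreign reference alone;
* jamming: 200 monomeric hard spheres, three seeds, adaptive compression
  from φ = 0.2; observed endpoints φ ≈ 0.642–0.645 with fivefold-dominant
  local order on a majority of seeds;
* NPT equation of state: 300 spheres at P = 5 k_BT/σ³, 20k cycles,
  compared with the Carnahan–Starling density within 2%;
* bending-angle law: isolated 10-mers under CB moves, Kolmogorov–Smirnov
  against the numeric Boltzmann CDF;
* SW second virial coefficient: quadrature of the implemented pair
  potential against the closed form, 1%;
* semigrand recovery: 8 chains of mean length 6, Flory weights, sampled
  marginal vs the enumeration oracle (fitted p within 5%; observed <1%);
* crystallization: 1000 hard spheres compressed to φ = 0.56 and run NVT
  for up to 3×10⁵ sweeps with descriptor snapshots every 2.5×10⁴ sweeps;
  crystallinity must grow by ≥ 0.2 while the fivefold fraction peaks and
  collapses (majority of three seeds).

## Known limitations

* Orthogonal cells only; no triclinic periodicity; filler mobility is a
  flag without dynamics.
* The cluster-move acceptance uses the reject-on-merge restriction; more
  elaborate symmetrized cluster algorithms would accept more moves.
* The CB trial measure uses bond lengths uniform in length (not in
  shell volume) — a proposal-density choice, consistently applied on
  both forward and reverse sides.
* The descriptor's orientation scan is a mesh-plus-refinement search:
  norms carry a small mesh tolerance (rotating a configuration rigidly
  moves individual norms by ≲ 0.02).
* Whether 1–3 exclusions should apply is chemistry-dependent; the default
  (interacting) can be flipped per run for local/collective sampling, but
  the pair-status bookkeeping of the connectivity-altering and identity
  moves assumes the default convention, so those moves refuse to run with
  `exclude_13` enabled.
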