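# Methods

## Model

`bfmdend` simulates solutions of single-spacer dendrimers with the bond
fluctuation model (BFM): unit centres live on a simple cubic lattice,
every centre blocks its 26 neighbouring sites (so two centres are never
closer than a Chebyshev distance of 2 — hard excluded volume, i.e. a
good-solvent, athermal SAW condition), and bonds are restricted to the
108 lattice vectors generated by sign flips and coordinate permutations
of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0) and (3,1,0).  The
(±2,±2,0) family is excluded because such bonds can cross during
single-site moves.  Squared bond lengths are therefore 4, 5, 6, 9 or 10.

A generation-G dendrimer is built from two bonded central units; each
central carries two branch segments and every branching unit is
bifunctional.  Segments consist of two identical bond vectors with one
intermediate (spacer) unit at the midpoint, giving

    N(G) = 10 + 16 (2^G − 1)        N = 250 (G4), 506 (G5).

Each unit blocks 8 lattice sites net, so a molecule carries a site mass
M = 8N and a system of n_t molecules in a box of edge L has volume
fraction Φ = n_t·M/L³.  One lattice unit maps to 1.45 Å (half the 2.9 Å
bead-overlap distance of coarse-grained PAMAM-EDA models, matched to the
BFM minimal distance 2), which places the model's branching-point
spacing in the range of common dendrimer chemistries (PAMAM-EDA,
PPI-DAB).

### Bond energies

The six bond classes can carry energies (k_B T) supplied as
configuration; the default table is all-zero (athermal), making the
Metropolis rule a pure connectivity + excluded-volume check.  This is a
deliberate default: the distance-dependent energy table used in earlier
parameterisations of this model is not part of this package, and all
shipped defaults and tests run athermally.  The athermal equilibrium is
measurably more compact than published production values obtained with
bond energies — in our runs an isolated G4 molecule equilibrates at
Rg ≈ 12.0–12.1 versus the published 12.9 (−6 to −7%), and the mean
branching-point distance at ≈ 4.2 versus 5.2 (−19%) — so comparisons
against those reference values carry this known systematic offset.
Shape ratios are much less sensitive (Rce/Rg ≈ 1.13 vs 1.15).

## Monte Carlo dynamics

A bead jump displaces one uniformly chosen unit to a neighbouring site
(default: the 6 axial directions; a 26-neighbour move set is available).
The jump is accepted when all incident bonds remain in the allowed set,
the target site is free of other units, and the Metropolis criterion on
the bond-energy change passes.  One step (sweep) is n_t·N attempts.
Rejected attempts leave the state unchanged (the previous configuration
is counted again in averages).  Unwrapped coordinates are the source of
truth; wrapped positions are derived modulo L for occupancy and
scattering.  Occupancy uses a dense L³ blocked-count grid (27 cells per
centre); for a Chebyshev-norm-1 move the excluded-volume test is a
single cell read because the mover contributes exactly one count to its
target cell.

Equilibration follows a 1% criterion: the run is split into equal
blocks and production starts only once the block means of two
successive blocks agree within 1% (inclusive), topped up to a requested
minimum number of sweeps.  The check supports gating on both Rg and A
or on Rg alone; the shipped desk-scale protocols gate on Rg, because at
50k-sweep block lengths the asphericity block means carry statistical
noise far above 1% (A is still recorded in the equilibration history).

## Initial conformations

Conformations are grown segment by segment: each segment draws a random
allowed bond b and places the intermediate at parent+b and the child at
parent+2b, rejecting placements that violate excluded volume.  Growth is
depth-first with backtracking: a segment that fails 300 consecutive
draws unwinds progressively more of its subtree (2^k segments after k
consecutive failures) before retrying, and an exhausted backtracking
budget restarts the molecule from a slightly jittered anchor.  Molecules
of a many-molecule system are placed on the regular cubic sublattice
with the largest commensurate spacing.

"Rod" initial conformations confine growth to a fixed window of 8
lattice sites along y and z (max−min span ≤ 8), which gives congested
systems open channels to interpenetrate during equilibration.  To make
such slab-confined growth reachable, bond draws are biased so each of
the four gen-0 subtrees extends along its own ±x direction (flip
probability 0.9); the bias shapes only the initial state and is erased
by equilibration.  G4 rods grow in seconds; G5 rods at the literal
8-site span sit at the random-growth jamming threshold and generally
exhaust the restart budget — the span is a parameter, and wider slabs
(or lower generations) grow reliably.

## Observables

Shape comes from the gyration tensor eigenvalues λ1 ≥ λ2 ≥ λ3:
Rg² = λ1+λ2+λ3, asphericity A = ⟨Σ_{i>j}(λi−λj)²⟩ / ⟨2(Σλi)²⟩ with
numerator and denominator ensemble-averaged separately (A = 0 for
spherical symmetry, 1 for a rod).  Rce² is the mean squared
centroid-to-outer-generation-unit distance; the reference ratios
(5/3)^1/2 = 1.29 (compact sphere) and 3^1/2 = 1.73 (unperturbed coil)
are exposed as constants.  COM mean-squared displacement is averaged
over molecules and time origins; the apparent diffusion coefficient is
one sixth of the least-squares slope over a fit window, by default the
last half of the MSD curve (the window is a parameter — the linear
regime should be inspected per system).

## Scattering and g(R)

Only box-commensurate wavevectors q = (2π/L)(h,k,l) are used,
spherically binned with δq = 2π/L (bin b collects vectors with
round(|hkl|) = b+1; dense shells can be uniformly subsampled per bin,
seeded).  The lattice intensity assigns contrast f = 1−Φ/8 to sites
holding a unit centre and −Φ/8 to empty sites; Σf = 0 exactly, and for
commensurate q ≠ 0 the full L³-site sum reduces to the sum over unit
centres, I(q) = (8/L³)|Σ_centres e^{iq·R}|².  The literal full-lattice
sum is retained as a test oracle.  A single-molecule run defines the
form factor via I = ΦN·P; the COM structure factor is
S(q) = (1/n_t)⟨|Σ_j e^{iq·R_j^cm}|²⟩, optionally smoothed by a centred
moving average (default window 3 bins) because the discrete lattice q
values make the raw S(q) oscillate around its peaks.  g(R) is the
minimum-image COM pair histogram up to L/2, normalised per configuration
by the ideal-gas expectation with *exact* spherical-shell volumes
(4π/3)(R₂³−R₁³)/L³ rather than the 4πR²δR approximation; S(q) can also
be obtained from g(R) by the standard Fourier quadrature
S = 1 + 4πρ∫(g−1)R² sinc(qR) dR (trapezoidal, truncated at L/2).

The factorization approximation I(q) = ΦN·P(q)·S(q) and its inverse
(the "apparent" structure factor I/(ΦNP), flagged NaN where P falls
below a floor) are provided as diagnostics.  In concentrated systems the
direct intensity flattens as the unit density homogenises while S(q)
keeps a sharp structural peak, so the factorized product overestimates
the peak — the package's tests reproduce this qualitative breakdown on a
concentrated G2 fixture.

## Coarse-graining pipeline

For hard (athermal) repulsion the Boltzmann factor of the
intermolecular energy is an overlap indicator, so the conformation- and
orientation-averaged Mayer function is f_M(R) = −P(overlap | R).  It is
sampled by drawing pairs of equilibrated single-molecule conformations
(COM-centred, kept in their native lattice frames — an isotropic
equilibrated library makes explicit molecular rotation redundant, and
lattice conformations cannot be rotated off-lattice), displacing one by
R along a uniformly random direction, and testing for any unit pair
within Chebyshev distance 2 in the continuum displaced frame.  Default
budgets: 1e5 tries over 200 R-bins, bins with fewer than 26 tries
flagged.  The effective potential w_eff = −ln(1+f_M) (hard-core bins
f_M = −1 are excluded from fitting); ln w_eff is fitted by least squares
against (1, R², R⁴), giving the interpolation w(R) = exp(c0+c1R²+c2R⁴),
truncated to zero where the fitted curve first drops below 1e-3 k_B T
(below sampling resolution at the default budgets).  A pure Gaussian
repulsion is the nested c2 = 0 case; higher generations need the quartic
term.

Point-particle Monte Carlo then moves n_t continuum particles under this
potential with periodic minimum-image boundaries: each move displaces
one particle along a uniform random direction by a magnitude uniform on
[0, 0.5] lattice units (a per-coordinate cube displacement is an
option), with Metropolis acceptance on the brute-force pairwise energy
change (n_t is small enough that cell lists are unnecessary).  The same
g(R)/S(q) code paths are applied to the sampled COM sets, which is the
point: the coarse model reproduces centre-of-mass structure at a tiny
fraction of the BFM cost, while unit-level intensity is outside its
reach by construction.

## Problem sizes used in the shipped checks

The packaged tests and the reproduction script run desk-scale versions
of the production protocol, chosen as the smallest sizes at which the
measured quantities are statistically stable: isolated G4 (L=96, ≥1e5
equilibration + 1e6 production sweeps, sampled every 500) and isolated
G5 (L=108, 5e5 production sweeps, ≥1000 samples) for sizes, branch
distances and asphericity; G2 systems (L=64, Φ≈0.04 dilute and L=40,
Φ≈0.2 concentrated) for the g(R)/S(q)/factorization pipeline; 4e4
Mayer tries over 60 bins for the G2 potential.  Statistical error bars
in the stochastic tests come from block averaging (typically 10 blocks)
with 3σ bounds and small multiple-comparison allowances.

## Numerical choices and degenerate inputs

* Equilibration check is inclusive at exactly 1% and errors on empty
  series.
* Asphericity of an ensemble whose configurations all have zero extent
  raises instead of silently returning 0/0; per-configuration terms are
  kept so the ratio-of-means estimator is exact.
* Bins of the Mayer estimate with f_M = −1 are reported as hard-core
  markers, never fed to the log fit; fit standard errors come from the
  unweighted least-squares covariance.
* `rdf` requires ≥2 molecules and positive bin width; distances beyond
  L/2 are not binned (minimum image).
* The q-grid refuses qmax below the first box mode 2π/L.
* Profile operations require matching |q| grids and raise otherwise.

## Known limitations

* The default athermal table undershoots published bond-energy-based
  sizes by ~6% (Rg) and branch distances by ~19%; supply a bond-energy
  table to recover chemistry-specific dimensions.
* G5 rod growth at the 8-site span is generally infeasible (see above).
* The apparent diffusion coefficient has no hydrodynamics and no
  physical-time mapping; it is a lattice-dynamics mobility index.
* The point-particle model is pairwise and density-independent: it is
  quantitative for g(R)/S(q) up to moderate overlap but cannot describe
  unit-level scattering, and many-body softening at melt-like densities
  is not represented.
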