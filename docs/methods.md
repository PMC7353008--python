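# Methods

`gnpcell` is a desk-scale stochastic model of gold-nanoparticle (GNP)
enhanced proton radiolysis in a single cell and in pairs of adjacent cells.
It follows the two-stage architecture standard in this field: a physics
stage that produces, per incident proton, the phase space of secondary
electrons escaping the nanoparticle clusters together with their energy
deposits in water, and a chemistry stage that converts deposits into
reactive species and diffuses them to 1 µs under configurable membrane
permeability. All headline outputs are per-incident-proton doses (eV) and
reactive-species yields per compartment, and the enhancement statistics
built from them.

## Geometry

The cell is a general ellipsoid with semi-axes 7.5, 7.5 and 11 µm (the
11 µm axis along the beam, Z), containing a centred 5 µm-radius spherical
nucleus; dimensions follow published HeLa-cell measurements. Both membranes
are 20 nm shells. Two conventions fix ambiguities:

* the nuclear membrane extends **outward** from the 5 µm nucleus radius
  (the nucleus keeps its 10 µm diameter);
* the cell membrane extends **inward** from the outer ellipsoid (the cell
  keeps its stated 22/15 µm outer dimensions), realised by shrinking each
  semi-axis by 20 nm. An exact constant-normal-thickness shell on an
  ellipsoid has no closed form; at these aspect ratios the thickness error
  is far below 20 nm.

The nucleus is centred in the cell. Compartments
{extracellular, cell membrane, cytoplasm, nuclear membrane, nucleus}
partition space; classification is vectorised and exact against the
analytic boundary surfaces.

Adjacent-cell layouts place a second cell along Z (beam-parallel) or X
(beam-perpendicular): *compressed* applies planar cuts at 6.1 µm (outer
boundary) and 6.08 µm (cytoplasm boundary) from the nucleus centre on the
facing sides, giving a 12.2 µm centre separation with coincident flat
20 nm membrane slabs; *touching* puts uncut cells in membrane contact
(22 µm along Z, 15 µm along X); *separated* adds a configurable water gap
(default 1 µm).

## Nanoparticle clusters

15 nm nanoparticles are packed into spherical clusters (100/200/500 nm
diameter holding 34/100/1298 particles, the measured in-vitro
compositions) by random sequential addition with rejection; requests above
a 30% volume fraction are refused (RSA jams near 38%). Clusters are placed
uniformly either in a perinuclear shell — the whole cluster within 1 µm
(or 2.25 µm) of the nuclear membrane's outer surface — or throughout the
cytoplasm, pairwise non-overlapping with contact allowed, entirely clear of
membranes and nucleus. Everything is deterministic per seed; member
packings use per-cluster child seeds.

## Secondary-electron source

The 5 MeV, 17 µm-diameter proton beam is modelled as straight
mono-directional tracks with entry points uniform on the disc (5 MeV
protons lose <0.2 MeV and scatter negligibly over the 25 µm box). For each
geometric proton-nanoparticle traversal, the electron count is
Poisson(c·chord/diameter) with c the per-material emission coefficient;
energies follow the close-collision 1/T² delta-ray spectrum truncated to
(100 eV, Tmax] with Tmax = 2mₑc²β²γ² ≈ 10.9 keV at 5 MeV; polar angles
follow the free-electron ejection kinematics cosθ = √(T/Tmax) — energetic
delta rays strongly forward, soft ones near-perpendicular — smeared by a
Gaussian of width 1/√κ (default κ=16, ≈14°). Each electron starts on the
emitting nanoparticle's surface and is attenuated along its exit ray
through every nanoparticle chord within its water range at the material's
effective loss rate (gold 100 keV/µm, water 10 keV/µm); the range cap
enforces causality — material beyond an electron's reach cannot absorb it.
Electrons emerging below 100 eV (range far below the membrane thickness)
are counted as self-absorbed. Emitted = escaped + self-absorbed energy
closes exactly per proton.

Two deliberate parameterisations:

* **Emission coefficients are effective, not first-principles.** The
  close-collision Bethe estimate for >100 eV delta rays from a 15 nm
  nanoparticle traversal is ≈0.36 (gold) and ≈0.026 (water) electrons.
  Defaults of 8.0/4.0 are ≈20× larger — a particle-splitting-style
  variance reduction that buys desk-scale precision at 10⁴-scale proton
  counts instead of the ~10⁶ primaries a cluster-level Geant4 study uses.
  Every reported statistic is a ratio or ordering and is invariant to a
  common emission scale; absolute DEF/REF magnitudes do depend on the
  gold/water coefficient ratio and are therefore reported but not asserted.
* The gold/water contrast (2× emission, 10× attenuation) is a free
  parameter of the model, config-exposed.

Primary-proton compartment doses use exact analytic chord lengths through
each boundary surface (including planar cuts) at a constant stopping power
of 8 keV/µm (published 5 MeV value: 7.91 keV/µm); they provide macroscale
context only — enhancement ratios consider nanoparticle electrons alone.

## Electron transport

Condensed random walk: each electron advances by 10% of its residual range
per step, deposits the corresponding energy loss at the step midpoint, and
deflects by a Gaussian polar angle (σ=0.45 rad per step, tuned so the
detour factor path/displacement is ≈1.5–2 for keV electrons, consistent
with published track structure). The range-energy relation R(E)=0.05·E^1.7
µm (E in keV) reproduces tabulated water ranges (≈50 nm at 1 keV, ≈2.5 µm
at 10 keV). Electrons ending below 100 eV deposit their residual energy
locally; energy leaving the simulation box is flagged escaped. Total
deposited + escaped equals initial energy exactly per electron. No
secondary generations are spawned (their ranges are sub-step at these
energies).

## Chemistry

Deposits convert to the six standard water-radiolysis species (•OH, e⁻aq,
H•, H₂, H₂O₂, H₃O⁺) with Poisson counts G·E/100 eV using published escape
yields (G = 2.7, 2.6, 0.6, 0.45, 0.7, 3.1 per 100 eV) and diffusion
coefficients (2.2, 4.9, 7.0, 4.8, 2.3, 9.46 ×10⁻⁹ m²/s); birth positions
are blurred by a 3 nm Gaussian standing in for pre-chemical thermalisation
displacement. Diffusion uses Brownian steps σ=√(2D dt) per axis on a
geometric schedule (1 ps → 1 µs in 60 log steps, resolving early gradients
cheaply).

Membranes are either transparent (100% permeable) or perfectly absorptive
(0%): a species whose step ends inside an absorptive membrane stops there
and its landing position is recorded (these positions form the hotspot
maps, binned equal-area on the spherical shell with a Gini concentration
index). Because a 20 nm shell is thinner than late-time steps, species
within 3σ of a membrane get a Brownian-bridge refinement of the step with
intermediate points ≈10 nm apart in RMS; the bridge is conditioned on the
step endpoint, so it only adds crossing detection.

Step noise comes from counter-based streams keyed by (seed, step, species
index): species i receives the same displacement sequence regardless of
the fate of other species. Runs differing only in membrane policy
therefore share trajectories exactly (common random numbers), and the
absorptive run's survivors are a strict subset of the permeable run's —
the "permeable ≥ absorptive" comparison is exact per replicate, not just
in expectation.

Recombination (single reaction radius between reactive partner pairs
•OH+e⁻aq, •OH+H•, e⁻aq+H₃O⁺) is provided but **off by default**: the
compartment comparisons of interest are ratios in which it largely
cancels, and the full reaction network is out of scope. GNPs are inert to
species. Species counts are conserved exactly:
created = alive + absorbed + recombined + escaped.

## Scoring and analytics

Scores are per incident proton: compartment dose from deposits, species
yields per compartment at every schedule time (headline numbers at exactly
1 µs), optional voxel grids (default 100 nm), adjacent/primary yield
ratios for two-cell runs. Per-proton normalisation makes scores exactly
additive over disjoint proton batches.

DEF = D_GNP/D_WNP and REF = Y_GNP/Y_WNP per region use matched-seed
GNP/water pairs (common random numbers tighten the ratio). Percent
comparisons are 100·(a/b−1) rounded half-away-from-zero at reporting
precision. The built-in benchmark table carries the reference doses,
yields and DEF/REF for the standard scenario grid; the comparison routines
reproduce its headline statistics (91%/−7% distribution effect, 117%/25%
and 153%/23% size effects, 6.7%/1.4% per-GNP reductions) exactly.

## Problem sizes and statistical choices

The reference study ran 2.7×10⁵–1.24×10⁶ primaries per scenario on a
16-core machine (6–24 h per stage). This package's test and acceptance
runs use 10⁴–2×10⁴ protons per replicate with ≥10 matched-seed replicates
per scenario — chosen together with the inflated emission coefficients so
that every asserted ordering has a Monte Carlo standard error comfortably
below its effect size. Orderings are asserted on replicate means. One
quantity remains statistically unresolvable at these sizes: the nucleus
per-nanoparticle yield constancy band (its matched-seed SE is ≈10% per
configuration, the size of the band itself); for the nucleus only the
slight monotone decline with cluster count is asserted, with the 10% band
checked on the cytoplasm and whole-cell yields where it is resolvable.

## What the generator emulates — and what it does not

The synthetic stage-1 source reproduces the features that drive the
cell-scale conclusions: per-traversal Poisson emission, the soft 1/T²
spectrum with its kinematic forward bias, material-dependent
self-absorption growing with cluster size, and exact energy bookkeeping.
It does not reproduce Geant4's condensed-history gold physics (Auger
cascades, shell structure, angular straggling inside gold), photon
transport, or LET evolution of the primaries. Consequently absolute
yields, DEF/REF magnitudes and the precise percentage effects are
parameter-dependent; directions and orderings (distribution, size, count,
membrane, layout effects) are the model's robust outputs, and those are
what passing tests demonstrate about real data.

## Known limitations

* Single mono-energetic proton energy per run; the 5 MeV defaults are the
  only configuration exercised against reference numbers.
* The membrane-absorption rule detects crossings at bridge resolution
  (~10 nm RMS); a species that dives through the 20 nm shell and back out
  between bridge points is missed — second order at this resolution.
* Recombination uses one reaction radius for all partner pairs.
* Cluster CSV reload reconstructs cluster centres as member centroids.
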