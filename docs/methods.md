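# Methods

`bfmgel` models the nanoscale network structure of starPEG–heparin
biohybrid hydrogels and reimplements the analysis chain used to study
them: coarse-grained lattice Monte Carlo simulation of network formation
and collapse, graph-based network-quality metrics, virtual-TEM projection
with automated micrograph quantification, scattering observables, and the
closed-form rubber-elasticity relations.  This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic benchmarks do and do not demonstrate.

## Coarse-grained model

**Bond Fluctuation Model (BFM).**  Each statistical monomer is a 2×2×2
cube of sites on a periodic simple-cubic lattice; bonds are restricted to
the classic allowed set {(2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0),
(3,1,0)} × signed permutations (108 vectors).  Together with excluded
volume this guarantees self-avoidance and topology preservation (chains
can never cross).  One Monte Carlo step (MCS) is one attempted move per
monomer on average.  The length mapping follows the PEG segment length:
one lattice unit is 0.3 nm.

**Molecules.**  starPEG (10 kg/mol) is a four-armed star: a
tetrafunctional central monomer plus four flexible arms of 29 monomers
(117 monomers total); the four arm termini carry the reactive thiols.
Heparin (14 kg/mol) is a bulky rigid rod built as a two-strand ladder of
2×45 monomers; the strand profile mixes (1,±2,0) zigzag steps with a
straight (2,0,0) step every sixth bond so the rod spans 51 lattice units
≈ 15.3 nm along its axis, inside the 14–17 nm window expected for the
molecule's ~15.5 nm end-to-end distance.  28 of its 90 monomers are
labelled reactive (the carboxylate positions available for maleimide
functionalization), sampled uniformly per molecule.

**Rigid-rod dynamics.**  Heparin monomers never move individually (the
rod is conformationally frozen, consistent with its high stiffness at
this scale); instead, whenever one of its monomers is drawn the whole
molecule attempts a rigid move with probability 1/90 — half unit
translations, half ±90° lattice rotations about the rod's first monomer.
Each rod therefore makes on average one rigid-body attempt per MCS and
diffuses and reorients thermally while keeping its exact shape.  An
earlier variant in which the rod was a ladder held together by
next-nearest-neighbour distance constraints turned out to freeze the
molecule completely (no single-monomer move preserves all constraints),
so the explicit rigid-body moves are used instead.  Rotations matter:
without them the crosslink bonds spread over too many distinct rods and
the network statistics (below) lose their characteristic multi-bonding.

**Solution assembly.**  The heparin concentration (default 1.5 mM) fixes
the rod count for a given box; the molar ratio γ = nPEG/nHEP fixes the
star count (rounded).  Rods are placed with random positions and random
lattice orientations, stars are grown as self-avoiding walks of stride-2
axial steps, and the solution is equilibrated athermally.  At these
conditions the occupied volume fraction is ≈ 4 %, far below the BFM
mobility bound of 0.5.

## Crosslinking

Michael-type thiol–maleimide conjugation is modelled as irreversible
collision bonding between starPEG termini and heparin reactive sites.
Two modelling choices are deliberately explicit because the notion of a
"collision" is not unique at lattice resolution:

* **Capture criterion** (`capture`): the default `"face"` requires the
  two reactive cubes to touch face-on (separation one of the six (±2,0,0)
  vectors — the closest approach excluded volume allows).  The
  alternative `"bond"` accepts any of the 108 allowed bond vectors.  Both
  produce a legal BFM bond at formation.
* **Reaction probability** (`p_react`, default 0.05): each collision
  check bonds only with this probability, an activation barrier that
  moves the reaction from the diffusion-controlled limit (every encounter
  reacts; bonds spread evenly over all nearby rods) towards the
  chemistry-controlled limit (arms explore locally before binding, so a
  star's first bond tethers it near a rod and later arms preferentially
  bind the same or a neighbouring rod).  Network statistics plateau once
  p_react ≲ 0.05; the default sits on that plateau.  The
  chemistry-controlled regime is also the physically expected one for
  thiol–maleimide addition, whose intrinsic rate is slow compared with
  monomer-scale diffusion.

Checks are event-driven (after every accepted move of an unconsumed
terminus) plus a periodic full sweep over termini (default every 2 MCS)
that also catches collisions created by rigid rod motion.  Simultaneous
candidates are tie-broken uniformly.  The reaction runs in good solvent
(no contact energy), matching the crosslink-then-deswell protocol order.
The run stops at the target extent of reaction p = crosslinks / (4·nPEG)
(default 0.90) or at an MCS cap, in which case the partial result is
flagged, never silent.

## Network metrics

Crosslinks are aggregated to a bipartite molecule-level multigraph.  The
biggest molecule cluster (BMC, the largest connected component; ties
broken by edge count, then smallest molecule id) is the gel-fraction
proxy.  Metrics: γ_BMC = nPEG,BMC/nHEP,BMC; heparin functionality
f_HEP,BMC = crosslink bonds per BMC heparin (a distinct-partner variant
is also reported, since "functionality" could arguably count either;
bonds is the default because network junctions count connections);
incorporation efficiencies per species; the defect census (dangling
starPEG arms, extra parallel bonds between one star and one rod, unbound
molecules); and the cycle rank E − V + 1 of the connected BMC.  ζ, the
cycle rank per strand, uses the BMC crosslink-edge count as the strand
count — each PEG–heparin bond anchors one elastically active arm.

A useful identity for interpretation: every bond of a BMC star lies in
the BMC, so f_HEP,BMC ≈ (mean bonds per BMC star)·γ_BMC ≈ 3.6·γ_BMC at
p = 0.9.  The two headline metrics are therefore locked together; what
the simulation really determines is how many rods the bonds concentrate
on.

**Finite-size caveat.**  The composition benchmark (γ = 0.4, f_HEP,BMC ≈
2.03, γ_BMC ≈ 0.56) sits exactly at the connectivity threshold f = 2,
where fluctuations are large.  In the scaled 128³ box (51 rods, 20
stars) individual seeds range over f ≈ 1.6–2.1 and the seed-mean lies at
the low edge of the published value; a single 256³ replicate (409 rods)
reproduces the published composition more closely.  The package default
for the composition ensemble is the 128³ box with ≥ 5 seeds, which keeps
the benchmark inside a laptop-scale budget at the cost of sitting on this
finite-size edge.

## Deswelling

Dehydration in ethanol is modelled as an attractive contact energy of
−0.30 k_BT between PEG monomers (contact = centre separation with
squared length in {4, 5, 6}, the nearest non-overlapping shells), driving
PEG self-aggregation while the charged heparin stays non-attractive.
Metropolis acceptance uses the incremental contact count over the
symmetric difference of the old and new shells (64 grid reads per PEG
move instead of 108).

Before collapse the BMC is extracted by deleting all molecules outside
the largest component.  The full-scale protocol re-centres the unwrapped
cluster in a box of twice the edge; a percolating gel winds the torus and
has no consistent unwrap, so the scaled default collapses the extracted
BMC **in place** in its original periodic box (`relocate_cluster` is
available and raises a `WindingError` when relocation is impossible).
Collapse observables: the contact-energy trajectory, radii of gyration of
unwrapped clusters, PEG aggregate sizes under the contact-shell
adjacency, and void sizes measured as the distance-to-nearest-occupied-
site at random probe points (a largest-empty-sphere statistic, computed
with a wrap-padded Euclidean distance transform; radii are exact up to
half the box edge).

## Virtual TEM and quantification

The projector emulates uranyl-acetate staining, which reveals heparin
while starPEG and resin stay bright: heparin monomers inside a slab
(default 70 nm, the section thickness; clipped to the box for small
boxes) are projected along the optical axis, column occupancy attenuates
a bright background as I = 230·exp(−0.9·columns), and Gaussian blur
(σ = 1 px) plus Poisson shot noise and Gaussian read noise are applied.
Default sampling is 0.5 nm/px so a 15 nm rod spans 30 px.

Quantification mirrors an automated micrograph-analysis macro:

1. Gaussian filter (σ = 1 px), percentile contrast stretch (1–99) and a
   global threshold; the default threshold is Otsu guarded by a
   bimodality check (Otsu splits the background mode when features cover
   a small area fraction), with a robust background sigma-clip
   (median ± 4·1.4826·MAD) as fallback; foreground = dark features (a
   polarity flag handles inverted-contrast inputs);
2. skeletonization; the skeleton is decomposed into branches between
   endpoints/junctions, measured as 8-connected path lengths with √2
   diagonal weighting, spurs shorter than 3 px pruned;
3. voids: Euclidean distance transform of the background phase, local
   maxima at least 10 px apart seed a marker watershed, and each region
   is summarized by its maximum Feret (caliper) diameter;
   border-touching regions are excluded (particle-analysis convention).

Distributions are summarized by least-squares Gaussian fits of their
histograms with Poisson count errors; a reduced-χ² above 3 flags a poor
fit (e.g. bimodal input), and degenerate/small samples raise an error
carrying the raw sample mean.  A straight rod loses roughly one to
one-and-a-half pixels per end to endpoint erosion during thinning, which
is the dominant bias in branch-length recovery (≈ 1–1.5 nm at default
sampling; planted 15.5 nm rods are measured at ≈ 14–14.5 nm).

## Scattering

The forward model is the orientation-averaged Debye sum I(q) = Σ w_i w_j
sinc(q r_ij) over a seeded subsample (default 2000 points) of scatterer
coordinates in nm.  The thin-rod form factor P(q) = 2 Si(qL)/(qL) −
4 sin²(qL/2)/(qL)², with the small-x expansion below qL = 1e-8, carries
the rod signature P ~ π/(qL) (log–log slope −1) at intermediate q.
Power-law slopes are least-squares fits of log I vs log q; peaks are
located on a 5-point moving average with parabolic sub-grid refinement
(convolution edges excluded) and converted to d-spacings via d = 2π/q.

## Physical characterization formulas

Volume swelling degree Q = (d/d₀)³ from gel-disc diameters; mesh size
ξ = (G′·N_A/(R·T))^(−1/3) from the storage modulus (CODATA constants,
SI internally, nm reported; 1 kPa ↔ 16 nm at 298.15 K), with the exact
inverse G′ = RT/(N_A ξ³); Young-to-shear conversion G = E/(2(1+ν)) with
ν = 0.5 for incompressible gels.

## Synthetic data

Generators are bit-reproducible under a fixed seed and ship ground truth
sufficient to score the corresponding analysis stage:

* **planted rod images** — dark rods (default 200 per 2048² frame,
  length 15.5 ± 0.5 nm, width 4 px at 0.5 nm/px) at uniform random
  positions/orientations on a bright background with blur and shot
  noise, non-overlapping by default;
* **planted void images** — bright discs/ellipses in a dark textured
  matrix, truth Feret = major axis;
* **synthetic scattering** — analytic power-law / rod / peak-plus-
  background curves with multiplicative log-normal noise;
* **miniature network fixtures** — five hand-laid crosslinked states
  (tree, single cycle, multi-edge pair, two components, a 4-star/3-rod
  mini-gel) whose metrics are known by hand count; they use scaled-down
  molecules (5-monomer stars, 6–10-monomer rods) but are fully valid
  lattice states.

What these benchmarks show: that every analysis stage recovers known
ground truth at realistic noise and sampling.  What they do not show:
real micrographs contain stain gradients, focus drift, section-thickness
variation and overlapping features that the planted scenes only crudely
imitate, so passing recovery tests bounds algorithmic error, not
experimental error.

## Problem sizes and determinism

Published-scale runs (256³ equilibration ≥ 1e8 MCS, 512³ deswelling
6.5e7 MCS, ≥ 20 seeds) remain available through the configuration, but
the package's test and default pipeline sizes are scaled down so the full
chain runs on one desktop core: composition ensembles use a 128³ box
with 2e4 MCS equilibration and 5 seeds; trend ensembles 64³ with
3e4 MCS deswelling; percolation comparisons 80³ with 3 seeds.  The
engine performs ~1.5e7 attempted moves per second on one core (numba,
register-held xorshift64 RNG; the single-monomer move is inlined by hand
into the kernel loop because a helper-function boundary there costs more
than the move itself).

Every stochastic operation takes an explicit seed or numpy Generator;
kernel seeds are drawn per call from the caller's Generator, so entire
pipelines are reproducible bit-for-bit given the configuration.

## Known limitations

* No electrostatics, explicit solvent or hydrodynamics; the deswelling
  attraction is an effective surrogate for PEG aggregation in ethanol.
* Heparin is conformationally frozen (rigid rod); real heparin has ~3
  Kuhn segments of flexibility.
* Rod rotations are 90° lattice rotations about a monomer anchor, so
  orientational relaxation is coarse.
* The composition benchmark sits at a connectivity threshold; at the
  scaled box size its seed-mean lies at the lower edge of the published
  tolerance (see the finite-size caveat above).
* Virtual TEM ignores electron optics (defocus, CTF) and stain
  chemistry; projections are geometric with a simple noise model.
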