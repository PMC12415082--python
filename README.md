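# bfmgel

Simulation and nanoscale structural analysis of starPEG–heparin
biohybrid hydrogels.

These hydrogels — four-armed poly(ethylene glycol) stars covalently
crosslinked by the rod-like glycosaminoglycan heparin via Michael-type
thiol–maleimide addition — are widely used cell-instructive matrices, but
their functional properties are set by a polymer network too fine for
conventional microscopy.  `bfmgel` provides, as one reusable Python
package, the computational toolchain needed to characterize that network:

* a **Bond Fluctuation Model (BFM)** lattice Monte Carlo engine
  (numba-accelerated) with excluded volume, the classic 108-vector bond
  set, rigid-rod heparin and attractive PEG–PEG contacts;
* **network formation**: solution assembly at molar ratio γ = nPEG/nHEP,
  collision-triggered irreversible crosslinking to an extent of reaction
  p, and extraction of the biggest molecule cluster (BMC, the gel
  fraction);
* **network-quality metrics**: γ_BMC, heparin junction functionality
  f_HEP,BMC, incorporation efficiencies, cycle rank ζ, and the census of
  primitive defects (dangling arms, multi-bonds, unbound molecules);
* **deswelling** in poor solvent (ε = −0.30 k_BT PEG–PEG attraction)
  with aggregate and void statistics;
* **virtual TEM** projection of ~70 nm slabs and the automated
  micrograph quantification it feeds: skeleton branch lengths of the
  stained heparin and watershed/Feret analysis of the voids, summarized
  by Gaussian fits;
* **scattering**: Debye forward model, thin-rod form factor
  P(q) = 2 Si(qL)/(qL) − 4 sin²(qL/2)/(qL)², power-law slopes, peak
  positions and d-spacings d = 2π/q;
* **rubber-elasticity formulas**: mesh size ξ = (G′ N_A / R T)^(−1/3),
  G = E/(2(1+ν)), and the volume swelling degree Q = (d/d₀)³;
* **synthetic data generators** with ground truth for every stage.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/` holds one short script per capability.  For instance,
elasticity characterization (`examples/04_elasticity.py`):

```text
E =   0.6 kPa  ->  G =  0.20 kPa, mesh size xi =  27.4 nm
E =   3.0 kPa  ->  G =  1.00 kPa, mesh size xi =  16.0 nm
E =  17.5 kPa  ->  G =  5.83 kPa, mesh size xi =   8.9 nm
disc swelling 9.0 -> 11.7 mm: volume swelling degree Q = 2.20
```

Softer gels (lower γ) have larger rubber-elasticity mesh sizes; the
stiffest gels reach ξ below 10 nm.  And scattering analysis
(`examples/03_scattering.py`):

```text
thin-rod (L = 15 nm) log-log slope over q in [1, 4]: -0.979 +- 0.000
peak at q = 14.19 nm^-1 -> d-spacing 0.443 nm
Debye sum vs analytic rod form factor: 0.48 % RMS
```

The ≈ −1 slope is the signature of rod-like scatterers (the heparin
building block); a diffraction peak at q = 14.2 nm⁻¹ corresponds to a
0.44 nm periodicity (crystalline-PEG-like short-range order in the
dehydrated state).

`examples/01_simulate_gel.py` runs the full formation pipeline in a
small box (γ = 1, 64³ lattice):

```text
assembled {'PEG': 702, 'HEP': 540} monomers (12 molecules, volume fraction 0.038)
extent of reaction p = 0.92 after 128026 MCS
gamma_BMC = 1.00   (molar ratio inside the gel)
f_HEP,BMC = 3.67   (crosslinks per heparin junction; > 2 sustains a network against 4-arm stars)
cycle rank = 11, zeta = 0.500 (independent cycles; the elasticity-relevant invariant)
defects: {'dangling_peg_arms': 2, 'multi_edges': 7, 'unbound_peg': 0, 'unbound_hep': 0}
```

At this high crosslinker ratio every molecule is incorporated and each
heparin junction carries well over two bonds — a robust network.
`examples/02_quantify_micrograph.py` measures planted 15.5 nm rods with
the TEM quantification chain and recovers a Gaussian-fit mean of
14.2 nm, the small deficit being skeleton endpoint erosion.

A thin CLI wraps the shell-friendly entry points:

```bash
bfmgel pipeline --config config.yaml --outdir results/
bfmgel synth-rods --n-rods 200 --seed 1 --out rods.tif
bfmgel quantify --image rods.tif --pixel-size-nm 0.5
bfmgel scatter-fit --profile curve.txt --q-min 1 --q-max 4
```

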