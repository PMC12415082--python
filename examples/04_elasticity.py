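"""Closed-form physical characterization of hydrogel networks.

Converts AFM Young's moduli to shear moduli (Poisson's ratio 0.5),
estimates rubber-elasticity mesh sizes from storage moduli, and computes
a volume swelling degree from gel-disc diameters.
"""

from bfmgel.physchem import (mesh_size_from_modulus, swelling_degree,
                             young_to_shear)

# the experimentally accessible stiffness range of these gels
for E_kPa in (0.6, 3.0, 17.5):
    G = young_to_shear(E_kPa * 1e3, nu=0.5)
    xi = mesh_size_from_modulus(G)
    print(f"E = {E_kPa:5.1f} kPa  ->  G = {G / 1e3:5.2f} kPa, "
          f"mesh size xi = {xi:5.1f} nm")

Q = swelling_degree(d=11.7, d0=9.0)
print(f"disc swelling 9.0 -> 11.7 mm: volume swelling degree Q = {Q:.2f}")
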