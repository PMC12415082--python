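"""Measure molecular lengths and void sizes in a synthetic micrograph.

Plants 120 dark rods of true length 15.5 nm (the heparin end-to-end
distance) in a bright 1024 x 1024 px frame at 0.5 nm/px, then runs the
full quantification pipeline: binarize -> skeletonize -> branch lengths,
and distance transform -> watershed -> void Feret diameters.
"""

from bfmgel.imaging import quantify
from bfmgel.synthetic import planted_rod_image

img, truth = planted_rod_image(n_rods=120, length_mean_nm=15.5,
                               length_sd_nm=0.5, pixel_size_nm=0.5,
                               image_px=1024, seed=42)
print(f"planted {len(truth)} rods, true mean length "
      f"{truth.length_nm.mean():.2f} nm")

res = quantify(img)
fit = res.fit_branch
print(f"measured {len(res.branch_lengths_nm)} skeleton branches")
print(f"Gaussian-fit mean branch length = {fit.mean:.2f} +- {fit.sd:.2f} nm")
print("(slightly below truth: skeleton thinning erodes just over a "
      "pixel per rod end)")
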