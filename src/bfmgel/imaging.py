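"""Virtual TEM projection and automated micrograph quantification.

The projector emulates uranyl-acetate stained sections: heparin monomers
inside a ~70 nm slab are projected along the optical axis and rendered
dark on a bright background (starPEG and resin are essentially unstained),
with Beer-Lambert-style occupancy darkening, Gaussian blur and shot/read
noise.

Quantification mirrors the automated micrograph analysis workflow:
contrast stretch + Gaussian filter + global threshold; skeletonization of
the stained features with per-branch path lengths (8-connected, diagonal
steps weighted sqrt 2) for molecular lengths; and Euclidean distance
transform + local maxima + marker watershed for the voids, each region
summarized by its maximum Feret (caliper) diameter.  Distributions are
summarized by least-squares Gaussian fits of their histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import exposure, filters, measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.transform import resize

from .builders import LATTICE_UNIT_NM
from .lattice import SPECIES_HEP, LatticeState, _normalize_rng

#: section thickness of the emulated ultrathin slices (nm)
DEFAULT_SLAB_THICKNESS_NM = 70.0


@dataclass
class GrayImage:
    """8-bit grayscale image with a physical pixel size."""

    pixels: np.ndarray        # (H, W) uint8
    pixel_size_nm: float
    provenance: str = "external"   # virtual_tem | planted | external

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0,
                                  255).astype(np.uint8)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            tifffile.imwrite(path, self.pixels,
                             resolution=(1.0 / self.pixel_size_nm,
                                         1.0 / self.pixel_size_nm))
        else:
            import imageio.v3 as iio
            iio.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path, pixel_size_nm: float,
             provenance: str = "external") -> "GrayImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            px = tifffile.imread(path)
        else:
            import imageio.v3 as iio
            px = iio.imread(path)
        if px.ndim == 3:
            px = px[..., 0]
        return cls(pixels=px, pixel_size_nm=pixel_size_nm,
                   provenance=provenance)


@dataclass
class GaussianFit:
    mean: float
    sd: float
    amplitude: float
    reduced_chi2: float
    n: int
    ok: bool


class GaussianFitError(RuntimeError):
    """Gaussian fit failed; carries the raw sample mean as a fallback."""

    def __init__(self, message, sample_mean=None):
        super().__init__(message)
        self.sample_mean = sample_mean


@dataclass
class QuantResult:
    """Branch-length and void-Feret distributions with Gaussian-fit means."""

    branch_lengths_nm: np.ndarray
    feret_diameters_nm: np.ndarray
    fit_branch: GaussianFit | None
    fit_feret: GaussianFit | None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fit_d(f):
            return None if f is None else {
                "mean": float(f.mean), "sd": float(f.sd),
                "reduced_chi2": float(f.reduced_chi2),
                "n": int(f.n), "ok": bool(f.ok)}
        return {"branch_lengths_nm": list(map(float,
                                              self.branch_lengths_nm)),
                "feret_diameters_nm": list(map(float,
                                               self.feret_diameters_nm)),
                "fit_branch": fit_d(self.fit_branch),
                "fit_feret": fit_d(self.fit_feret),
                "settings": dict(self.settings)}


# ---------------------------------------------------------------------------
# virtual TEM


def virtual_tem(state: LatticeState, slab_origin: int = 0,
                slab_thickness_nm: float = DEFAULT_SLAB_THICKNESS_NM,
                pixel_size_nm: float = 0.5, blur_sigma_px: float = 1.0,
                noise_level: float = 0.03, attenuation: float = 0.9,
                axis: int = 2, seed=None) -> GrayImage:
    """Project heparin monomers of a slab into a dark-on-bright image.

    The slab spans ``slab_origin .. slab_origin + thickness`` lattice
    sites along ``axis`` (periodic).  Column occupancy attenuates a bright
    background I0 = 230 as ``I = I0 exp(-attenuation * columns)``;
    Gaussian blur and Poisson-like shot noise plus Gaussian read noise are
    applied on top.
    """
    L = state.box_edge
    if pixel_size_nm > 2 * LATTICE_UNIT_NM:
        raise ValueError(
            f"pixel size {pixel_size_nm} nm undersamples the monomer "
            f"footprint ({2 * LATTICE_UNIT_NM:.1f} nm)")
    t_sites = int(round(slab_thickness_nm / LATTICE_UNIT_NM))
    if t_sites > L:
        raise ValueError(f"slab of {t_sites} sites does not fit in box {L}")
    rng = _normalize_rng(seed)

    pos = state.positions[state.species == SPECIES_HEP]
    # a monomer occupies axis coordinates {a, a+1}
    a = pos[:, axis]
    lo = slab_origin % L
    ina = (a - lo) % L < t_sites
    inb = (a + 1 - lo) % L < t_sites
    keep = pos[ina | inb]
    ax_img = [i for i in range(3) if i != axis]

    acc = np.zeros((L, L), dtype=np.float64)
    for du in (0, 1):
        for dv in (0, 1):
            u = (keep[:, ax_img[0]] + du) % L
            v = (keep[:, ax_img[1]] + dv) % L
            np.add.at(acc, (u, v), 1.0)

    npx = max(8, int(round(L * LATTICE_UNIT_NM / pixel_size_nm)))
    sites_per_px = (L / npx) ** 2
    dens = resize(acc, (npx, npx), order=1, anti_aliasing=True,
                  preserve_range=True) * sites_per_px
    img = 230.0 * np.exp(-attenuation * dens / 2.0)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px, mode="wrap")
    if noise_level > 0:
        gain = max(noise_level * 64.0, 1e-6)
        img = rng.poisson(np.clip(img, 0, None) / gain) * gain
        img = img + rng.normal(0.0, noise_level * 16.0, img.shape)
    return GrayImage(pixels=img, pixel_size_nm=pixel_size_nm,
                     provenance="virtual_tem")


# ---------------------------------------------------------------------------
# preprocessing / binarization


def binarize_preprocess(image: GrayImage, gauss_sigma_px: float = 1.0,
                        contrast_percentiles=(1.0, 99.0),
                        threshold_method: str = "auto",
                        polarity: str = "dark") -> np.ndarray:
    """Gaussian smoothing, contrast stretch and global thresholding.

    Smoothing runs before the percentile stretch so that the stretch does
    not amplify single-pixel noise when the features cover only a small
    area fraction.  ``threshold_method='auto'`` (default) applies Otsu
    and falls back to the triangle threshold when Otsu selects an
    implausibly large foreground -- Otsu's two-class criterion is known
    to split the background mode instead of separating sparse features.
    Explicit choices: ``otsu``, ``triangle``, ``mean``.

    Returns a boolean mask in which True marks the stained (dark by
    default) features; pass ``polarity='bright'`` for inverted-contrast
    inputs.
    """
    px = image.pixels.astype(np.float64)
    if np.ptp(px) == 0:
        raise ValueError("constant image cannot be thresholded")
    if gauss_sigma_px > 0:
        px = ndimage.gaussian_filter(px, gauss_sigma_px)
    lo, hi = np.percentile(px, contrast_percentiles)
    if hi <= lo:
        raise ValueError("degenerate contrast percentiles")
    px = exposure.rescale_intensity(px, in_range=(lo, hi),
                                    out_range=(0.0, 255.0))

    def _mask(thr):
        return px < thr if polarity == "dark" else px > thr

    if polarity not in ("dark", "bright"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if threshold_method == "auto":
        thr = filters.threshold_otsu(px)
        a = px[px < thr]
        b = px[px >= thr]
        separated = (len(a) > 0 and len(b) > 0
                     and (b.mean() - a.mean()) ** 2
                     > 4.0 * (a.var() + b.var()))
        if not separated:
            med = np.median(px)
            mad = 1.4826 * np.median(np.abs(px - med))
            thr = med - 4.0 * mad if polarity == "dark" \
                else med + 4.0 * mad
        return _mask(thr)
    if threshold_method == "otsu":
        return _mask(filters.threshold_otsu(px))
    if threshold_method == "triangle":
        return _mask(filters.threshold_triangle(px))
    if threshold_method == "mean":
        return _mask(px.mean())
    raise ValueError(f"unknown threshold method {threshold_method!r}")


# ---------------------------------------------------------------------------
# skeleton branch lengths

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_branches(skel: np.ndarray):
    """Decompose an 8-connected skeleton into branches.

    Returns a list of path lengths in pixels (diagonal steps sqrt 2),
    each branch running between endpoints and/or junctions; isolated
    cycles count as one closed branch.
    """
    pts = set(map(tuple, np.argwhere(skel)))
    if not pts:
        return []
    nbrs = {}
    for p in pts:
        nbrs[p] = [(p[0] + dr, p[1] + dc) for dr, dc in _N8
                   if (p[0] + dr, p[1] + dc) in pts]
    deg = {p: len(v) for p, v in nbrs.items()}

    def steplen(a, b):
        return 1.4142135623730951 if (a[0] != b[0] and a[1] != b[1]) else 1.0

    visited = set()   # directed half-edges
    lengths = []
    nodes = [p for p in pts if deg[p] != 2]
    for start in nodes:
        for nxt in nbrs[start]:
            if (start, nxt) in visited:
                continue
            length = steplen(start, nxt)
            visited.add((start, nxt))
            visited.add((nxt, start))
            prev, cur = start, nxt
            while deg[cur] == 2:
                a, b = nbrs[cur]
                nxt2 = b if a == prev else a
                if (cur, nxt2) in visited:
                    break
                visited.add((cur, nxt2))
                visited.add((nxt2, cur))
                length += steplen(cur, nxt2)
                prev, cur = cur, nxt2
            lengths.append(length)
    # isolated cycles: every pixel degree 2, none visited yet
    for p in pts:
        if deg[p] != 2:
            continue
        for nxt in nbrs[p]:
            if (p, nxt) in visited:
                continue
            length = steplen(p, nxt)
            visited.add((p, nxt))
            visited.add((nxt, p))
            prev, cur = p, nxt
            while cur != p:
                a, b = nbrs[cur]
                nxt2 = b if a == prev else a
                visited.add((cur, nxt2))
                visited.add((nxt2, cur))
                length += steplen(cur, nxt2)
                prev, cur = cur, nxt2
            lengths.append(length)
            break
    return lengths


def branch_length_analysis(binary: np.ndarray, pixel_size_nm: float,
                           prune_px: float = 3.0,
                           min_object_px: int = 8) -> np.ndarray:
    """Skeletonize the feature mask and measure branch lengths in nm.

    Branches shorter than ``prune_px`` (spur artefacts of thinning) are
    discarded; small specks below ``min_object_px`` pixels are removed
    before thinning.  Returns an array of branch lengths in nm (empty for
    an empty mask).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return np.empty(0)
    clean = morphology.remove_small_objects(
        binary, max_size=min_object_px - 1)
    skel = morphology.skeletonize(clean)
    lengths_px = np.array(_skeleton_branches(skel), dtype=float)
    lengths_px = lengths_px[lengths_px >= prune_px]
    return lengths_px * pixel_size_nm


# ---------------------------------------------------------------------------
# void Feret diameters


def void_feret_analysis(binary: np.ndarray, pixel_size_nm: float,
                        min_distance_px: int = 10,
                        exclude_border: bool = True,
                        min_area_px: int = 16):
    """Segment the voids (background of the polymer mask) and measure each
    region's maximum Feret diameter in nm.

    Euclidean distance transform of the void phase, local maxima at least
    ``min_distance_px`` apart as markers, watershed segmentation; regions
    touching the image border are excluded by default (particle-analysis
    convention).  Returns ``(diameters_nm, flags)``.
    """
    binary = np.asarray(binary, dtype=bool)
    voids = ~binary
    flags = {}
    if not voids.any():
        flags["fully_foreground"] = True
        return np.empty(0), flags
    dist = ndimage.distance_transform_edt(voids)
    peaks = peak_local_max(dist, min_distance=min_distance_px,
                           labels=voids, exclude_border=False)
    if len(peaks) == 0:
        flags["no_maxima"] = True
        return np.empty(0), flags
    markers = np.zeros(voids.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=voids)
    diams = []
    h, w = voids.shape
    for r in measure.regionprops(labels):
        if r.area < min_area_px:
            continue
        if exclude_border:
            rmin, cmin, rmax, cmax = r.bbox
            if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
                continue
        diams.append(r.feret_diameter_max * pixel_size_nm)
    return np.array(diams, dtype=float), flags


# ---------------------------------------------------------------------------
# Gaussian summary fits


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def gaussian_fit(values, bins: int = 30,
                 chi2_flag_threshold: float = 3.0) -> GaussianFit:
    """Least-squares Gaussian fit of a histogram of ``values``.

    Returns the fitted mean and sd with a reduced chi-square diagnostic
    (Poisson errors on the counts); ``ok`` is False when the fit is poor.
    Raises :class:`GaussianFitError` (carrying the sample mean) for n < 20,
    degenerate samples, or non-convergence.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 20:
        raise GaussianFitError(
            f"need at least 20 values, got {len(v)}",
            sample_mean=float(v.mean()) if len(v) else None)
    if np.std(v) == 0:
        raise GaussianFitError("degenerate sample (zero spread)",
                               sample_mean=float(v.mean()))
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (counts.max(), float(v.mean()), float(v.std()))
    try:
        popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise GaussianFitError(f"fit did not converge: {exc}",
                               sample_mean=float(v.mean())) from exc
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    resid = counts - _gauss(centers, *popt)
    err2 = np.maximum(counts, 1.0)
    dof = max(len(counts) - 3, 1)
    chi2 = float((resid ** 2 / err2).sum() / dof)
    ok = bool(chi2 < chi2_flag_threshold) and bool(v.min() <= mu <= v.max())
    return GaussianFit(mean=float(mu), sd=sigma, amplitude=float(a),
                       reduced_chi2=chi2, n=len(v), ok=ok)


def quantify(image: GrayImage, gauss_sigma_px: float = 1.0,
             contrast_percentiles=(1.0, 99.0),
             threshold_method: str = "otsu", prune_px: float = 3.0,
             min_distance_px: int = 10, bins: int = 30) -> QuantResult:
    """Full micrograph quantification: binarize, then branch lengths of
    the stained features and Feret diameters of the voids, each with a
    Gaussian-fit summary (fits are None when a distribution is too small
    or degenerate)."""
    binary = binarize_preprocess(image, gauss_sigma_px,
                                 contrast_percentiles, threshold_method)
    branches = branch_length_analysis(binary, image.pixel_size_nm,
                                      prune_px=prune_px)
    ferets, flags = void_feret_analysis(binary, image.pixel_size_nm,
                                        min_distance_px=min_distance_px)
    fits = []
    for arr in (branches, ferets):
        try:
            fits.append(gaussian_fit(arr, bins=bins))
        except GaussianFitError:
            fits.append(None)
    settings = {"gauss_sigma_px": gauss_sigma_px,
                "contrast_percentiles": tuple(contrast_percentiles),
                "threshold_method": threshold_method,
                "prune_px": prune_px, "min_distance_px": min_distance_px,
                "bins": bins, "pixel_size_nm": image.pixel_size_nm,
                "void_flags": flags}
    return QuantResult(branch_lengths_nm=branches,
                       feret_diameters_nm=ferets,
                       fit_branch=fits[0], fit_feret=fits[1],
                       settings=settings)
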