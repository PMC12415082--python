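"""Ground-truthed synthetic inputs for every pipeline stage.

Generators are bit-reproducible under a fixed seed and return truth tables
sufficient to score the corresponding analysis stage: planted rod images
(emulating UA-stained heparin rods, dark on bright), planted void images
(bright pores in a dark matrix), analytic scattering curves with optional
noise, and miniature crosslinked network fixtures whose metrics are known
by hand count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import GrayImage
from .lattice import (BOND_CROSSLINK, BOND_INTRA, SPECIES_CODES,
                      LatticeState, _normalize_rng)
from .scatter import ScatteringProfile, rod_form_factor


class PlacementError(RuntimeError):
    """Non-overlapping placement failed at the requested density."""


# ---------------------------------------------------------------------------
# planted rod micrographs


def _rod_mask(shape, x0, y0, x1, y1, half_width):
    """Boolean mask of pixels within ``half_width`` of segment (x0,y0)-(x1,y1)."""
    xmin = max(0, int(np.floor(min(x0, x1) - half_width - 2)))
    xmax = min(shape[1] - 1, int(np.ceil(max(x0, x1) + half_width + 2)))
    ymin = max(0, int(np.floor(min(y0, y1) - half_width - 2)))
    ymax = min(shape[0] - 1, int(np.ceil(max(y0, y1) + half_width + 2)))
    yy, xx = np.mgrid[ymin:ymax + 1, xmin:xmax + 1]
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / seg2, 0.0, 1.0)
    d2 = (xx - (x0 + t * dx)) ** 2 + (yy - (y0 + t * dy)) ** 2
    return (ymin, xmin), d2 <= half_width ** 2


def planted_rod_image(n_rods: int, length_mean_nm: float = 15.5,
                      length_sd_nm: float = 0.5,
                      pixel_size_nm: float = 0.5, image_px: int = 2048,
                      width_px: float = 4.0, blur_sigma_px: float = 1.0,
                      noise_level: float = 0.03,
                      allow_overlap: bool = False, seed=None):
    """Dark rods of Gaussian-distributed length on a bright background.

    Returns ``(GrayImage, truth)`` where truth is a DataFrame with one row
    per rod (centre, angle, true length in nm).  Without ``allow_overlap``
    rods keep a 2 px clearance from each other; placement failure raises
    :class:`PlacementError` naming the achievable density.
    """
    rng = _normalize_rng(seed)
    canvas = np.full((image_px, image_px), 230.0)
    occupied = np.zeros((image_px, image_px), dtype=bool)
    rows = []
    margin = 4 + width_px
    clearance = int(np.ceil(width_px / 2 + 2))
    placed = 0
    for k in range(n_rods):
        ok = False
        for _try in range(200):
            length_nm = rng.normal(length_mean_nm, length_sd_nm)
            length_px = max(length_nm / pixel_size_nm, 1.0)
            angle = rng.uniform(0, np.pi)
            cx = rng.uniform(margin + length_px / 2,
                             image_px - margin - length_px / 2)
            cy = rng.uniform(margin + length_px / 2,
                             image_px - margin - length_px / 2)
            # the stroke is a capsule: round caps add width/2 at each
            # end, so shorten the segment to make the visible tip-to-tip
            # extent equal the planted length
            seg_px = max(length_px - width_px, 1.0)
            dx = 0.5 * seg_px * np.cos(angle)
            dy = 0.5 * seg_px * np.sin(angle)
            (oy, ox), mask = _rod_mask(canvas.shape, cx - dx, cy - dy,
                                       cx + dx, cy + dy, width_px / 2)
            sl = (slice(oy, oy + mask.shape[0]),
                  slice(ox, ox + mask.shape[1]))
            if not allow_overlap:
                grown = ndimage.binary_dilation(mask, iterations=clearance)
                if (occupied[sl] & grown).any():
                    continue
            canvas[sl][mask] = 40.0
            occupied[sl] |= mask
            rows.append({"center_x_px": cx, "center_y_px": cy,
                         "angle_rad": angle, "length_nm": length_nm})
            placed += 1
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"placed only {placed}/{n_rods} rods without overlap; "
                f"reduce the count or image density")
    if blur_sigma_px > 0:
        canvas = ndimage.gaussian_filter(canvas, blur_sigma_px)
    if noise_level > 0:
        gain = max(noise_level * 64.0, 1e-6)
        canvas = rng.poisson(np.clip(canvas, 0, None) / gain) * gain
        canvas = canvas + rng.normal(0, noise_level * 16.0, canvas.shape)
    img = GrayImage(pixels=canvas, pixel_size_nm=pixel_size_nm,
                    provenance="planted")
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted void micrographs


def planted_void_image(n_voids: int, diameter_dist=("constant", 40.0),
                       aspect: float = 1.0, matrix_texture: float = 8.0,
                       pixel_size_nm: float = 1.0, image_px: int = 1024,
                       blur_sigma_px: float = 1.0, seed=None):
    """Bright elliptical voids in a dark textured matrix.

    ``diameter_dist`` is ``("constant", d_px)`` or
    ``("lognormal", mean_of_log_px, sigma_of_log)`` for the major-axis
    diameter in pixels; ``aspect`` is the minor/major ratio (1 = discs).
    Truth lists each void's maximum Feret diameter (= major axis) in nm.
    """
    rng = _normalize_rng(seed)
    canvas = np.full((image_px, image_px), 60.0)
    rows = []
    centers = []
    for k in range(n_voids):
        ok = False
        for _try in range(500):
            kind = diameter_dist[0]
            if kind == "constant":
                dmaj = float(diameter_dist[1])
            elif kind == "lognormal":
                dmaj = float(np.exp(rng.normal(np.log(diameter_dist[1]),
                                               diameter_dist[2])))
            else:
                raise ValueError(f"unknown diameter distribution {kind!r}")
            rmaj = dmaj / 2.0
            rmin_ax = rmaj * aspect
            theta = rng.uniform(0, np.pi)
            cx = rng.uniform(rmaj + 4, image_px - rmaj - 4)
            cy = rng.uniform(rmaj + 4, image_px - rmaj - 4)
            if any((cx - px) ** 2 + (cy - py) ** 2 < (rmaj + pr + 6) ** 2
                   for px, py, pr in centers):
                continue
            yy, xx = np.mgrid[int(cy - rmaj - 2):int(cy + rmaj + 3),
                              int(cx - rmaj - 2):int(cx + rmaj + 3)]
            xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            mask = (xr / rmaj) ** 2 + (yr / max(rmin_ax, 1e-9)) ** 2 <= 1.0
            canvas[yy[mask], xx[mask]] = 220.0
            centers.append((cx, cy, rmaj))
            rows.append({"center_x_px": cx, "center_y_px": cy,
                         "angle_rad": theta,
                         "feret_nm": dmaj * pixel_size_nm})
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"placed only {len(rows)}/{n_voids} voids without merging")
    if matrix_texture > 0:
        canvas = canvas + rng.normal(0, matrix_texture, canvas.shape)
    if blur_sigma_px > 0:
        canvas = ndimage.gaussian_filter(canvas, blur_sigma_px)
    img = GrayImage(pixels=canvas, pixel_size_nm=pixel_size_nm,
                    provenance="planted")
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic scattering curves


def synthetic_scattering(kind: str, params: dict, q_grid,
                         noise: float = 0.0, seed=None):
    """Analytic curve plus multiplicative log-normal noise.

    kinds: ``power_law`` (params: slope, amplitude), ``rod`` (params:
    length_nm, amplitude), ``peak_background`` (params: q_peak, width,
    peak_amplitude, bg_amplitude, bg_slope).  Returns ``(profile, truth)``.
    """
    rng = _normalize_rng(seed)
    q = np.asarray(q_grid, dtype=float)
    truth = {"kind": kind, **params}
    if kind == "power_law":
        i = params.get("amplitude", 1.0) * q ** params["slope"]
    elif kind == "rod":
        i = params.get("amplitude", 1.0) * rod_form_factor(
            q, params["length_nm"])
        truth["asymptotic_slope"] = -1.0
    elif kind == "peak_background":
        q0 = params["q_peak"]
        w = params.get("width", 0.4)
        i = (params.get("bg_amplitude", 1.0)
             * q ** params.get("bg_slope", -2.0)
             + params.get("peak_amplitude", 5.0)
             * np.exp(-0.5 * ((q - q0) / w) ** 2))
        truth["d_spacing"] = 2.0 * np.pi / q0
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    if noise > 0:
        i = i * np.exp(rng.normal(0.0, noise, size=q.shape))
    return ScatteringProfile(q=q, intensity=i, label=kind), truth


# ---------------------------------------------------------------------------
# miniature network fixtures

_FIXTURE_BOX = 40


def _mini_star(center):
    """5-monomer star: centre plus 4 reactive termini at +-2 along x, y."""
    cx, cy, cz = center
    coords = [(cx, cy, cz), (cx + 2, cy, cz), (cx - 2, cy, cz),
              (cx, cy + 2, cz), (cx, cy - 2, cz)]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4)]
    return "PEG", coords, bonds, [1, 2, 3, 4]


def _mini_rod(start, n=6, axis=0):
    """Straight rigid rod of ``n`` monomers at spacing 2; all reactive."""
    sx, sy, sz = start
    step = [0, 0, 0]
    step[axis] = 2
    coords = [(sx + k * step[0], sy + k * step[1], sz + k * step[2])
              for k in range(n)]
    bonds = [(k, k + 1) for k in range(n - 1)]
    return "HEP", coords, bonds, list(range(n))


def _build_fixture(molecules, crosslinks):
    """Assemble a LatticeState from (species, coords, bonds, reactive)
    molecule tuples and coordinate-addressed crosslinks."""
    pos, species, mol_id, reactive = [], [], [], []
    bonds, kinds = [], []
    coord_to_idx = {}
    off = 0
    for mid, (sp, coords, mbonds, ridx) in enumerate(molecules):
        for k, c in enumerate(coords):
            coord_to_idx[tuple(c)] = off + k
        pos.extend(coords)
        species.extend([SPECIES_CODES[sp]] * len(coords))
        mol_id.extend([mid] * len(coords))
        r = np.zeros(len(coords), dtype=bool)
        r[ridx] = True
        reactive.extend(r.tolist())
        for a, b in mbonds:
            bonds.append((off + a, off + b))
            kinds.append(BOND_INTRA)
        off += len(coords)
    consumed = np.zeros(off, dtype=bool)
    for ca, cb in crosslinks:
        ia, ib = coord_to_idx[tuple(ca)], coord_to_idx[tuple(cb)]
        bonds.append((ia, ib))
        kinds.append(BOND_CROSSLINK)
        consumed[ia] = True
        consumed[ib] = True
    state = LatticeState(
        box_edge=_FIXTURE_BOX,
        positions=np.array(pos, dtype=np.int64),
        species=np.array(species, dtype=np.uint8),
        molecule_id=np.array(mol_id, dtype=np.int32),
        bonds=np.array(bonds, dtype=np.int32),
        bond_kind=np.array(kinds, dtype=np.uint8),
        reactive=np.array(reactive, dtype=bool),
        consumed=consumed)
    return state


def fixture_network(preset: str):
    """Miniature crosslinked states with hand-countable metrics.

    Returns ``(state, expected)`` where ``expected`` holds the known
    metric values for oracle tests.  Presets: tree, single_cycle,
    multi_edge_pair, two_components, mini_gel.
    """
    if preset == "multi_edge_pair":
        mols = [_mini_star((10, 10, 10)), _mini_rod((6, 11, 12))]
        cross = [((12, 10, 10), (12, 11, 12)),
                 ((8, 10, 10), (8, 11, 12))]
        expected = {"n_nodes_bmc": 2, "n_edges_bmc": 2, "cycle_rank": 1,
                    "f_hep_bmc": 2.0, "multi_edges": 1,
                    "dangling_peg_arms": 2, "unbound": 0}
    elif preset == "tree":
        mols = [_mini_star((10, 10, 10)), _mini_rod((14, 10, 10)),
                _mini_rod((6, 10, 10), axis=1)]
        cross = [((12, 10, 10), (14, 10, 10)),
                 ((8, 10, 10), (6, 10, 10))]
        expected = {"n_nodes_bmc": 3, "n_edges_bmc": 2, "cycle_rank": 0,
                    "f_hep_bmc": 1.0, "multi_edges": 0,
                    "dangling_peg_arms": 2, "unbound": 0}
    elif preset == "single_cycle":
        mols = [_mini_star((10, 10, 10)), _mini_star((22, 10, 10)),
                _mini_rod((12, 11, 12)), _mini_rod((10, 9, 8))]
        cross = [((12, 10, 10), (12, 11, 12)),
                 ((20, 10, 10), (20, 11, 12)),
                 ((10, 8, 10), (10, 9, 8)),
                 ((22, 8, 10), (20, 9, 8))]
        expected = {"n_nodes_bmc": 4, "n_edges_bmc": 4, "cycle_rank": 1,
                    "f_hep_bmc": 2.0, "multi_edges": 0,
                    "dangling_peg_arms": 4, "unbound": 0}
    elif preset == "two_components":
        mols = [_mini_star((10, 10, 10)), _mini_rod((14, 10, 10)),
                _mini_rod((6, 10, 10), axis=1),
                _mini_star((10, 10, 30)), _mini_rod((6, 11, 32))]
        cross = [((12, 10, 10), (14, 10, 10)),
                 ((8, 10, 10), (6, 10, 10)),
                 ((12, 10, 30), (12, 11, 32)),
                 ((8, 10, 30), (8, 11, 32))]
        expected = {"n_nodes_bmc": 3, "n_edges_bmc": 2, "cycle_rank": 0,
                    "f_hep_bmc": 1.0, "multi_edges": 1,
                    "dangling_peg_arms": 2, "unbound": 2}
    elif preset == "mini_gel":
        rod_n = 10
        mols = [_mini_star((8, 10, 10)), _mini_star((16, 10, 10)),
                _mini_star((12, 12, 10)), _mini_star((20, 14, 10)),
                _mini_rod((4, 11, 12), n=rod_n),
                _mini_rod((4, 13, 12), n=rod_n),
                _mini_rod((4, 15, 12), n=rod_n)]
        cross = [
            # S1 (centre 8,10,10): 2x R1 (y=11), 1x R2 (y=13)
            ((10, 10, 10), (10, 11, 12)), ((6, 10, 10), (6, 11, 12)),
            ((8, 12, 10), (8, 13, 12)),
            # S4 (centre 16,10,10): 2x R1, 1x R2
            ((18, 10, 10), (18, 11, 12)), ((14, 10, 10), (14, 11, 12)),
            ((16, 12, 10), (16, 13, 12)),
            # S2 (centre 12,12,10): 2x R2, 1x R3 (y=15)
            ((14, 12, 10), (14, 13, 12)), ((10, 12, 10), (10, 13, 12)),
            ((12, 14, 10), (12, 15, 12)),
            # S3 (centre 20,14,10): 2x R3, 1x R1 via the -y terminus
            ((22, 14, 10), (22, 15, 12)), ((18, 14, 10), (18, 15, 12)),
            ((20, 12, 10), (20, 11, 12)),
        ]
        expected = {"n_nodes_bmc": 7, "n_edges_bmc": 12, "cycle_rank": 6,
                    "f_hep_bmc": 4.0, "multi_edges": 4,
                    "dangling_peg_arms": 4, "unbound": 0}
    else:
        raise ValueError(f"unknown preset {preset!r}")
    state = _build_fixture(mols, cross)
    return state, expected
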