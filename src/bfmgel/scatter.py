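"""Scattering analysis: Debye profiles, rod form factor, power-law slopes,
peak positions and d-spacings.

The forward model is the orientation-averaged Debye sum
``I(q) = sum_ij w_i w_j sin(q r_ij) / (q r_ij)`` over (a seeded subsample
of) scatterer positions, which links simulation snapshots to measured
SAXS/WAXS-style curves.  The thin-rod form factor
``P(q) = 2 Si(qL)/(qL) - 4 sin^2(qL/2)/(qL)^2`` carries the rod signature
``I ~ q^-1`` at intermediate q; a Bragg-like peak at q maps to the
real-space periodicity d = 2 pi / q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sici
from scipy.stats import linregress


@dataclass
class ScatteringProfile:
    """Paired grids of scattering vector q (nm^-1, strictly increasing)
    and intensity (arbitrary units)."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


def write_profile(profile: ScatteringProfile, path) -> None:
    header = "units: nm^-1, a.u."
    if profile.label:
        header += f"\nlabel: {profile.label}"
    np.savetxt(path, np.column_stack([profile.q, profile.intensity]),
               header=header)


def read_profile(path) -> ScatteringProfile:
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "label:" in line:
                label = line.split("label:", 1)[1].strip()
    data = np.loadtxt(path).reshape(-1, 2)
    return ScatteringProfile(q=data[:, 0], intensity=data[:, 1], label=label)


def intensity_profile(positions_nm, q_grid, weights=None,
                      n_subsample: int = 2000, seed=0,
                      label: str = "") -> ScatteringProfile:
    """Orientation-averaged Debye sum over a seeded subsample of points.

    ``positions_nm``: (N, 3) coordinates in nm.  The i = j terms contribute
    ``sum w_i^2`` (a single point gives the constant w^2).  Deterministic
    for a fixed seed.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q grid must be positive")
    pos = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n < 1:
        raise ValueError("need at least one position")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if n > n_subsample:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n, n_subsample, replace=False)
        pos, w = pos[keep], w[keep]
        n = n_subsample
    iq = np.full(len(q), float(np.sum(w ** 2)))
    if n > 1:
        from scipy.spatial.distance import pdist
        d = pdist(pos)
        iu, ju = np.triu_indices(n, k=1)
        ww = w[iu] * w[ju]
        for k, qk in enumerate(q):
            iq[k] += 2.0 * float((ww * np.sinc(qk * d / np.pi)).sum())
    return ScatteringProfile(q=q, intensity=iq, label=label)


def rod_form_factor(q, L: float):
    """Orientation-averaged thin-rod form factor of rod length ``L``.

    P(q) = (2/(qL)) Si(qL) - 4 sin^2(qL/2) / (qL)^2, with P -> 1 as
    qL -> 0; at large qL, P ~ pi/(qL) (log-log slope -1).
    """
    if L <= 0:
        raise ValueError("rod length must be positive")
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    x = q * L
    p = np.ones_like(x)
    nz = x > 1e-8
    si, _ci = sici(x[nz])
    p[nz] = 2.0 * si / x[nz] - 4.0 * np.sin(x[nz] / 2.0) ** 2 / x[nz] ** 2
    small = ~nz
    p[small] = 1.0 - x[small] ** 2 / 36.0
    return float(p[0]) if scalar else p


def powerlaw_slope(profile: ScatteringProfile, q_min: float, q_max: float):
    """Least-squares slope of log I vs log q on [q_min, q_max].

    Returns ``(slope, stderr)``; requires at least 5 in-range points with
    positive intensity.
    """
    sel = (profile.q >= q_min) & (profile.q <= q_max)
    if np.count_nonzero(sel) < 5:
        raise ValueError("need at least 5 points in the fit window")
    i = profile.intensity[sel]
    if np.any(i <= 0):
        raise ValueError("intensities must be positive for a log-log fit")
    res = linregress(np.log(profile.q[sel]), np.log(i))
    return float(res.slope), float(res.stderr)


def d_spacing(q_peak: float) -> float:
    """Real-space periodicity d = 2 pi / q of a scattering peak."""
    if q_peak <= 0:
        raise ValueError("peak position must be positive")
    return 2.0 * np.pi / q_peak


def peak_and_dspacing(profile: ScatteringProfile, q_window=None,
                      smooth_points: int = 5):
    """Locate the intensity peak inside ``q_window`` and its d-spacing.

    The intensity is smoothed by a short moving average and the argmax
    refined to sub-grid precision by a parabola through the three points
    around it.  Returns ``(q_peak, d_spacing)``.
    """
    q, inten = profile.q, profile.intensity
    if q_window is not None:
        lo, hi = q_window
        sel = (q >= lo) & (q <= hi)
        if np.count_nonzero(sel) < 3:
            raise ValueError("q window holds fewer than 3 grid points")
        q, inten = q[sel], inten[sel]
    if smooth_points > 1 and len(inten) >= 3 * smooth_points:
        kern = np.ones(smooth_points) / smooth_points
        sm = np.convolve(inten, kern, mode="same")
        edge = smooth_points // 2  # convolution edge effects are invalid
    else:
        sm = inten
        edge = 0
    lo_k, hi_k = edge, len(sm) - 1 - edge
    k = lo_k + int(np.argmax(sm[lo_k:hi_k + 1]))
    if k <= lo_k or k >= hi_k:
        raise ValueError("no interior maximum inside the window")
    y0, y1, y2 = sm[k - 1], sm[k], sm[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    # parabolic refinement on an (assumed locally uniform) grid
    dq = q[k + 1] - q[k] if shift >= 0 else q[k] - q[k - 1]
    q_peak = float(q[k] + shift * dq)
    return q_peak, d_spacing(q_peak)
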