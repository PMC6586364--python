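"""Analysis of simulated 3D chromatin ensembles.

Radius-of-gyration scaling of chromatin domains (compaction exponents),
loop end-to-end distance statistics in physical units (1 reduced unit =
30 nm), the distance-contact power law P = P_o r^beta, and diffusion-map
spectral embedding of conformations into slow collective coordinates with
a free-energy surface on the leading pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import EnsembleTrajectory
from .polymer_model import contact_function

logger = logging.getLogger(__name__)

__all__ = [
    "NM_PER_UNIT",
    "PowerLawFit",
    "DiffusionMapResult",
    "radius_of_gyration",
    "fit_power_law",
    "domain_scaling",
    "loop_end_to_end",
    "distance_probability_fit",
    "frame_contact_map",
    "diffusion_map",
    "free_energy_projection",
    "region_mean_maps",
]

NM_PER_UNIT = 30.0  # one bead diameter (5 kb of chromatin)


# ---------------------------------------------------------------------------
# Radius of gyration and power laws
# ---------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray, bead_range=None) -> float:
    """Root-mean-square distance of the selected beads from their centroid."""
    x = np.asarray(coords, dtype=float)
    if bead_range is not None:
        lo, hi = bead_range
        x = x[lo:hi]
    if len(x) < 2:
        raise ValueError("need at least 2 beads")
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


@dataclass
class PowerLawFit:
    """y = prefactor * x^exponent fitted by least squares on log-log axes."""

    prefactor: float
    exponent: float
    residual: float       # RMS residual of the log-log linear fit
    x_range: tuple
    n_points: int


def fit_power_law(x, y) -> PowerLawFit:
    """Least-squares power-law fit on (log x, log y); x, y must be positive
    with at least 3 points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive data")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return PowerLawFit(prefactor=float(np.exp(intercept)),
                       exponent=float(slope),
                       residual=float(np.sqrt(np.mean(resid**2))),
                       x_range=(float(x.min()), float(x.max())),
                       n_points=len(x))


def domain_scaling(traj: EnsembleTrajectory, domains) -> dict:
    """Power-law fit of mean Rg versus genomic length per domain class.

    ``domains`` is a list of ((lo, hi), class_label); lengths are bead
    counts.  Classes with fewer than 3 distinct sizes are skipped with a
    warning.  Returns {class: (PowerLawFit, lengths, mean_rg, std_rg)}.
    """
    by_class: dict = {}
    for (lo, hi), label in domains:
        rgs = np.array([radius_of_gyration(frame, (lo, hi))
                        for frame in traj.frames])
        by_class.setdefault(label, []).append(
            (hi - lo, rgs.mean(), rgs.std()))
    out = {}
    for label, rows in by_class.items():
        rows.sort()
        lengths = np.array([r[0] for r in rows], dtype=float)
        if len(np.unique(lengths)) < 3:
            logger.warning("domain class %r has < 3 sizes; skipped", label)
            continue
        means = np.array([r[1] for r in rows])
        stds = np.array([r[2] for r in rows])
        out[label] = (fit_power_law(lengths, means), lengths, means, stds)
    return out


def loop_end_to_end(traj: EnsembleTrajectory, pair, n_bins: int = 30,
                    bin_width_nm: float | None = None) -> dict:
    """Anchor-anchor distance distribution across frames, in nm.

    Returns histogram (probability mass per bin, summing to 1), bin edges,
    mean, and variance.  A single-frame trajectory is flagged.
    """
    i, j = int(pair[0]), int(pair[1])
    if not (0 <= i < traj.n_beads and 0 <= j < traj.n_beads):
        raise ValueError("loop pair indices out of range")
    d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)
    d_nm = d * NM_PER_UNIT
    if traj.n_frames == 1:
        logger.warning("loop_end_to_end: single-frame trajectory")
    if bin_width_nm is not None:
        hi = max(d_nm.max(), bin_width_nm)
        edges = np.arange(0.0, hi + bin_width_nm, bin_width_nm)
    else:
        edges = np.linspace(0.0, max(d_nm.max(), 1e-9), n_bins + 1)
    counts, edges = np.histogram(d_nm, bins=edges)
    mass = counts / counts.sum()
    return {"distances_nm": d_nm, "hist": mass, "bin_edges": edges,
            "mean_nm": float(d_nm.mean()), "var_nm2": float(d_nm.var())}


def distance_probability_fit(traj: EnsembleTrajectory, cmap,
                             sample_pairs) -> PowerLawFit:
    """Power law P = P_o r^beta between contact probability and mean
    spatial distance over the sampled pairs."""
    m = cmap.matrix if hasattr(cmap, "matrix") else np.asarray(cmap)
    dists, probs = [], []
    for (i, j) in sample_pairs:
        i, j = int(i), int(j)
        r = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j],
                           axis=1).mean()
        dists.append(r)
        probs.append(m[i, j])
    dists = np.asarray(dists)
    probs = np.asarray(probs)
    if np.ptp(dists) == 0:
        raise ValueError("degenerate (constant) distances")
    return fit_power_law(dists, probs)


# ---------------------------------------------------------------------------
# Per-frame contact maps and diffusion maps
# ---------------------------------------------------------------------------

def frame_contact_map(coords: np.ndarray, r_c: float = 1.76,
                      sigma: float = 3.72) -> np.ndarray:
    """Instantaneous contact map f(r_ij) of one configuration."""
    x = np.asarray(coords, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return contact_function(r, r_c, sigma)


@dataclass
class DiffusionMapResult:
    """Spectral embedding of sampled configurations."""

    frame_indices: np.ndarray
    distances: np.ndarray      # pairwise d_ij between frames
    epsilons: np.ndarray       # local kernel scales
    eigenvalues: np.ndarray    # of the Markov-normalized kernel, descending
    coordinates: np.ndarray    # (n_frames, n_components), trivial mode dropped


def diffusion_map(frames, k_scale: int = 10, n_components: int = 2,
                  r_c: float = 1.76, sigma: float = 3.72,
                  distance: str = "absolute",
                  max_frames: int = 2000) -> DiffusionMapResult:
    """Diffusion-map embedding of chromatin configurations.

    Pairwise distances are the mean absolute (or squared, via ``distance``)
    difference between per-frame contact maps over off-diagonal pairs.
    Each frame gets a self-tuned kernel scale eps_i (median distance to its
    ``k_scale`` nearest neighbors) and the locally scaled Gaussian kernel

        K_ij = exp(-d_ij^2 / (eps_i eps_j))

    is density-normalized (alpha = 1: divide by the outer product of row
    sums) and then row-normalized to a Markov matrix whose top eigenvalue
    is 1 with a constant right eigenvector; the next ``n_components``
    eigenvectors are the slow collective coordinates.  Frames beyond
    ``max_frames`` are strided down before the dense eigenproblem.
    """
    if isinstance(frames, EnsembleTrajectory):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    nf = len(frames)
    if nf < n_components + 2:
        raise ValueError("need at least n_components + 2 frames")
    stride = max(1, int(np.ceil(nf / max_frames)))
    idx = np.arange(0, nf, stride)
    frames = frames[idx]
    nf = len(frames)
    nb = frames.shape[1]
    iu = np.triu_indices(nb, k=1)
    cm = np.array([frame_contact_map(f, r_c, sigma)[iu] for f in frames])
    # pairwise distance between frames' contact maps
    if distance == "absolute":
        d = np.array([[np.mean(np.abs(cm[a] - cm[b])) for b in range(nf)]
                      for a in range(nf)])
    elif distance == "squared":
        d = np.array([[np.mean((cm[a] - cm[b]) ** 2) for b in range(nf)]
                      for a in range(nf)])
    else:
        raise ValueError("distance must be 'absolute' or 'squared'")
    # self-tuned local scales
    k = min(k_scale, nf - 1)
    eps = np.empty(nf)
    for a in range(nf):
        nn = np.sort(d[a])[1: k + 1]
        eps[a] = np.median(nn)
    floor = np.finfo(float).eps * max(d.max(), 1.0)
    if np.any(eps <= 0):
        logger.warning("diffusion_map: zero local scale floored "
                       "(duplicate frames)")
        eps = np.maximum(eps, floor)
    K = np.exp(-(d**2) / np.outer(eps, eps))
    # alpha = 1 density normalization, then Markov row normalization
    q = K.sum(axis=1)
    K_tilde = K / np.outer(q, q)
    dvec = K_tilde.sum(axis=1)
    # symmetric conjugate: S = D^-1/2 K~ D^-1/2 shares eigenvalues with M
    inv_sqrt = 1.0 / np.sqrt(dvec)
    S = K_tilde * np.outer(inv_sqrt, inv_sqrt)
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of the Markov matrix
    psi = vecs * inv_sqrt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True) * np.sign(
        psi[0] + (psi[0] == 0))
    # drop the trivial constant mode (index 0 after sorting)
    const = psi[:, 0]
    if np.ptp(const) > 1e-6 * max(1.0, np.abs(const).max()):
        logger.warning("diffusion_map: leading eigenvector deviates from "
                       "constant (ptp %.3g)", np.ptp(const))
    coords = psi[:, 1: 1 + n_components]
    return DiffusionMapResult(frame_indices=idx, distances=d, epsilons=eps,
                              eigenvalues=vals, coordinates=coords)


def free_energy_projection(coords: np.ndarray, bins: int = 30) -> dict:
    """2D free-energy surface -ln(density) over the first two coordinates,
    shifted so the global minimum is exactly 0; empty bins are +inf."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ValueError("need at least two coordinate columns")
    H, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins)
    total = H.sum()
    with np.errstate(divide="ignore"):
        F = -np.log(H / total)
    if np.isfinite(F).sum() <= 1:
        logger.warning("free_energy_projection: all frames in one bin")
    F -= F[np.isfinite(F)].min()
    return {"free_energy": F, "x_edges": xe, "y_edges": ye}


def region_mean_maps(frames, coords: np.ndarray, intervals,
                     axis: int = 0, r_c: float = 1.76,
                     sigma: float = 3.72) -> list[np.ndarray]:
    """Mean contact map of the frames whose coordinate (column ``axis``)
    falls in each half-open interval [lo, hi) -- the per-region maps used
    to interpret the reaction coordinates."""
    if isinstance(frames, EnsembleTrajectory):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    out = []
    for lo, hi in intervals:
        sel = (coords[:, axis] >= lo) & (coords[:, axis] < hi)
        if not sel.any():
            out.append(None)
            continue
        maps = [frame_contact_map(f, r_c, sigma) for f in frames[sel]]
        out.append(np.mean(maps, axis=0))
    return out
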