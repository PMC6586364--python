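"""Contact-map IO, normalization, and comparison metrics.

Covers the quantitative map-level validation toolkit: conversion of
balanced Hi-C counts to contact probabilities, global and
distance-stratified Pearson correlation, the stratum-adjusted correlation
coefficient (SCC), insulation profiles and TAD-boundary detection,
matching scores between ranked pair lists, local contact enhancement with
separation-matched random backgrounds, eigen-analysis of log contact maps,
and inspection of trained state-interaction matrices (clustering,
eigenvectors, spectral complexity).

Masked bins (failed normalization) propagate: any window or stratum drops
its masked bins, not the whole window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .polymer_model import EnergyParameters

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "InsulationProfile",
    "read_contact_matrix",
    "write_contact_matrix",
    "apply_normalization",
    "to_probability",
    "pcc_maps",
    "scc",
    "insulation_profile",
    "detect_boundaries",
    "matching_score",
    "contact_enhancement",
    "random_pair_background",
    "top_pairs",
    "log_eigen_analysis",
    "eigenvector_similarity",
    "interaction_matrix_analysis",
]

DEFAULT_C_DIAG = 1035.0  # genome-averaged 5kb diagonal of KR-balanced counts


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric non-negative contact matrix with genomic placement.

    ``mask`` marks valid bins; invalid bins are excluded from every metric.
    """

    matrix: np.ndarray
    bin_size: int = 5000
    chrom: str = "chr"
    start_bp: int = 0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        finite = np.isfinite(self.matrix)
        if not np.allclose(np.where(finite, self.matrix, 0.0),
                           np.where(finite.T, self.matrix.T, 0.0),
                           atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(self.matrix) < -1e-12:
            raise ValueError("contact matrix must be non-negative")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class InsulationProfile:
    """Sliding-square insulation scores along the diagonal."""

    scores: np.ndarray
    window_bins: int
    bin_size: int = 5000
    valid: np.ndarray = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.scores)
        self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------------
# IO and normalization
# ---------------------------------------------------------------------------

def read_contact_matrix(path, format: str = "dense_tsv",
                        n_bins: int | None = None) -> np.ndarray:
    """Raw symmetric matrix from dense TSV or (i, j, count) triplet text."""
    if format == "dense_tsv":
        mat = np.loadtxt(path, ndmin=2)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("dense matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-6 * max(1.0, np.abs(mat).max())):
            raise ValueError("asymmetric dense input")
        return 0.5 * (mat + mat.T)
    if format == "triplet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"malformed triplet at line {ln}")
                try:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"malformed triplet at line {ln}") from exc
                rows.append((i, j, v))
        if not rows:
            raise ValueError("empty triplet file")
        dim = n_bins if n_bins is not None else \
            max(max(i, j) for i, j, _ in rows) + 1
        mat = np.zeros((dim, dim))
        for i, j, v in rows:
            if i < 0 or j < 0 or i >= dim or j >= dim:
                raise ValueError(f"triplet index ({i}, {j}) out of range")
            mat[i, j] += v
            if i != j:
                mat[j, i] += v
        return mat
    raise ValueError(f"unknown format: {format}")


def write_contact_matrix(matrix, path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def apply_normalization(raw: np.ndarray, norm_vector) -> tuple[np.ndarray, np.ndarray]:
    """KR-style balancing: M_ij = raw_ij / (v_i v_j).

    Returns (balanced, mask); bins with missing / non-positive vector
    entries are masked (rows and columns set to NaN) with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    v = np.asarray(norm_vector, dtype=float)
    if len(v) != raw.shape[0]:
        raise ValueError("normalization vector length mismatch")
    bad = ~np.isfinite(v) | (v <= 0)
    if bad.any():
        logger.warning("apply_normalization: %d bin(s) masked "
                       "(non-positive norm entries)", int(bad.sum()))
    v_safe = np.where(bad, 1.0, v)
    out = raw / np.outer(v_safe, v_safe)
    out[bad, :] = np.nan
    out[:, bad] = np.nan
    return out, ~bad


def to_probability(balanced: np.ndarray, c_diag: float | None = None,
                   mask: np.ndarray | None = None, bin_size: int = 5000,
                   chrom: str = "chr", start_bp: int = 0) -> ContactMap:
    """Convert a balanced matrix to contact probabilities.

    Divides by the short-range diagonal level ``c_diag`` (genome-wide 5 kb
    average 1035 for the reference dataset; when omitted, the mean of the
    main diagonal over unmasked bins), so loci within one bin (spatially
    within ~30 nm) have probability ~1.  Values above 1 are capped with the
    cap count logged.
    """
    balanced = np.asarray(balanced, dtype=float)
    n = balanced.shape[0]
    if mask is None:
        mask = ~np.all(np.isnan(balanced), axis=0)
    if c_diag is None:
        diag = np.diag(balanced)[mask]
        diag = diag[np.isfinite(diag)]
        if len(diag) == 0:
            raise ValueError("all-masked diagonal; supply c_diag")
        c_diag = float(diag.mean())
    if c_diag <= 0:
        raise ValueError("c_diag must be positive")
    prob = balanced / c_diag
    n_cap = int(np.sum(prob[np.isfinite(prob)] > 1.0))
    if n_cap:
        logger.info("to_probability: %d entries capped at 1", n_cap)
    prob = np.minimum(prob, 1.0)
    prob = np.where(np.isfinite(prob), prob, 0.0)
    prob[~mask, :] = 0.0
    prob[:, ~mask] = 0.0
    return ContactMap(prob, bin_size=bin_size, chrom=chrom,
                      start_bp=start_bp, mask=mask)


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------

def _joint_mask(a: ContactMap, b: ContactMap) -> np.ndarray:
    if a.n_bins != b.n_bins:
        raise ValueError("maps must have equal dimensions")
    return a.mask & b.mask


def pcc_maps(map_a: ContactMap, map_b: ContactMap, mode: str = "global"):
    """Pearson correlation over unmasked off-diagonal upper-triangle
    entries; ``mode='by_distance'`` returns one PCC per separation (NaN and
    a flag where a stratum has < 3 valid entries)."""
    mask = _joint_mask(map_a, map_b)
    n = map_a.n_bins
    iu = np.triu_indices(n, k=1)
    valid = mask[iu[0]] & mask[iu[1]]
    x = map_a.matrix[iu][valid]
    y = map_b.matrix[iu][valid]
    if mode == "global":
        if len(x) < 3:
            raise ValueError("fewer than 3 valid entries")
        return float(pearsonr(x, y).statistic)
    if mode == "by_distance":
        sep = (iu[1] - iu[0])[valid]
        out = np.full(n, np.nan)
        for s in range(1, n):
            sel = sep == s
            if sel.sum() < 3 or np.std(x[sel]) == 0 or np.std(y[sel]) == 0:
                continue
            out[s] = pearsonr(x[sel], y[sel]).statistic
        return out
    raise ValueError(f"unknown mode: {mode}")


def _mean_filter(mat: np.ndarray, mask: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 moving-average smoothing that drops masked bins."""
    if h == 0:
        return mat.copy()
    w = np.outer(mask, mask).astype(float)
    vals = np.where(w > 0, mat, 0.0)
    from scipy.ndimage import uniform_filter

    size = 2 * h + 1
    num = uniform_filter(vals, size=size, mode="constant")
    den = uniform_filter(w, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def scc(map_a: ContactMap, map_b: ContactMap, h: int = 2,
        max_separation: int = 400) -> float:
    """Stratum-adjusted correlation coefficient.

    Both maps are smoothed with a (2h+1)-bin mean filter, entries are
    stratified by genomic separation, and the per-stratum Pearson
    coefficients are combined with weights N_s * sqrt(var_s(a) var_s(b))
    (stratum size times score spread).  The magnitude is sensitive to
    ``h``, which is therefore exposed.  Empty or constant strata are
    skipped.
    """
    mask = _joint_mask(map_a, map_b)
    sa = _mean_filter(map_a.matrix, mask, h)
    sb = _mean_filter(map_b.matrix, mask, h)
    n = map_a.n_bins
    num = 0.0
    den = 0.0
    for s in range(1, min(max_separation, n - 1) + 1):
        i = np.arange(n - s)
        j = i + s
        sel = mask[i] & mask[j]
        if sel.sum() < 3:
            continue
        x = sa[i[sel], j[sel]]
        y = sb[i[sel], j[sel]]
        vx, vy = np.var(x), np.var(y)
        if vx == 0 or vy == 0:
            continue
        rho = pearsonr(x, y).statistic
        w = len(x) * np.sqrt(vx * vy)
        num += w * rho
        den += w
    if den == 0:
        raise ValueError("no usable strata")
    return float(num / den)


# ---------------------------------------------------------------------------
# Insulation and boundaries
# ---------------------------------------------------------------------------

def insulation_profile(cmap: ContactMap,
                       window_bp: int = 500_000) -> InsulationProfile:
    """Mean contact in a sliding window_bp x window_bp square whose corner
    tracks the diagonal: score(b) = mean over [b-w, b) x [b, b+w).

    The first and last w bins are masked (NaN) and excluded from minima
    search downstream; masked bins are dropped from each window's mean.
    """
    if window_bp % cmap.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window_bp // cmap.bin_size
    n = cmap.n_bins
    if n <= 2 * w:
        raise ValueError("matrix too small for this window")
    scores = np.full(n, np.nan)
    m = cmap.matrix
    mask = cmap.mask
    for b in range(w, n - w + 1):
        rows = np.arange(b - w, b)
        cols = np.arange(b, b + w)
        sub = m[np.ix_(rows, cols)]
        sub_mask = np.outer(mask[rows], mask[cols])
        if sub_mask.any():
            scores[b] = sub[sub_mask].mean()
    return InsulationProfile(scores, window_bins=w, bin_size=cmap.bin_size)


def detect_boundaries(profile: InsulationProfile,
                      prominence: float = 0.0) -> np.ndarray:
    """TAD boundaries = local minima of the insulation profile with at
    least the given prominence; plateau minima report their left-most bin."""
    scores = profile.scores
    valid = profile.valid & np.isfinite(scores)
    idx = np.flatnonzero(valid)
    if len(idx) < 3:
        return np.array([], dtype=int)
    seg = -scores[idx]  # minima -> peaks
    peaks, props = find_peaks(seg, prominence=prominence if prominence > 0
                              else None, plateau_size=1)
    left = props.get("left_edges", peaks)
    return idx[left].astype(int)


# ---------------------------------------------------------------------------
# Pair-list comparison
# ---------------------------------------------------------------------------

def matching_score(list_a, list_b, tolerance_bins: int = 10) -> float:
    """Fraction of A's items with an unmatched B item within tolerance.

    Items are boundary bins (ints) or (i, j) pairs; for pairs both
    coordinates must be within tolerance.  Matching is greedy one-to-one in
    A's rank order, each A item taking its nearest eligible B item.
    """
    items_a = list(list_a)
    items_b = list(list_b)
    if not items_a:
        raise ValueError("empty reference list")
    is_pair = np.ndim(items_a[0]) > 0
    used = np.zeros(len(items_b), dtype=bool)
    matched = 0
    for a in items_a:
        best_k, best_d = -1, None
        for k, b in enumerate(items_b):
            if used[k]:
                continue
            if is_pair:
                d = max(abs(int(a[0]) - int(b[0])), abs(int(a[1]) - int(b[1])))
            else:
                d = abs(int(a) - int(b))
            if d <= tolerance_bins and (best_d is None or d < best_d):
                best_k, best_d = k, d
        if best_k >= 0:
            used[best_k] = True
            matched += 1
    return matched / len(items_a)


def top_pairs(cmap: ContactMap, n: int, min_separation: int = 2) -> list:
    """Default significant-pair extraction: the n highest-probability
    unmasked pairs at separations >= min_separation, rank ordered.
    External ranked lists (e.g. from dedicated significance callers) can be
    supplied to :func:`matching_score` in the same (i, j, score) form."""
    m = cmap.matrix
    nb = cmap.n_bins
    iu = np.triu_indices(nb, k=min_separation)
    valid = cmap.mask[iu[0]] & cmap.mask[iu[1]]
    ii, jj = iu[0][valid], iu[1][valid]
    vals = m[ii, jj]
    order = np.argsort(-vals, kind="stable")[:n]
    return [(int(ii[k]), int(jj[k]), float(vals[k])) for k in order]


# ---------------------------------------------------------------------------
# Contact enhancement
# ---------------------------------------------------------------------------

def contact_enhancement(cmap: ContactMap, pair,
                        background_half_width: int = 5) -> float:
    """Ratio of P_ij to the mean of its local background: the
    (2h+1) x (2h+1) square centered on (i, j), center cell excluded,
    clipped at matrix edges, masked bins dropped."""
    i, j = int(pair[0]), int(pair[1])
    n = cmap.n_bins
    h = background_half_width
    r0, r1 = max(i - h, 0), min(i + h + 1, n)
    c0, c1 = max(j - h, 0), min(j + h + 1, n)
    if (r1 - r0) < 2 * h + 1 or (c1 - c0) < 2 * h + 1:
        logger.debug("contact_enhancement: window clipped at matrix edge")
    sub = cmap.matrix[r0:r1, c0:c1].copy()
    sub_mask = np.outer(cmap.mask[r0:r1], cmap.mask[c0:c1])
    sub_mask[i - r0, j - c0] = False  # exclude the center cell
    if not sub_mask.any():
        return np.nan
    bg = sub[sub_mask].mean()
    if bg == 0:
        logger.warning("contact_enhancement: zero background at (%d, %d)",
                       i, j)
        return np.nan
    return float(cmap.matrix[i, j] / bg)


def random_pair_background(cmap: ContactMap, reference_pairs, n: int,
                           seed: int = 0, percentile: float = 90.0,
                           background_half_width: int = 5):
    """Enhancement distribution for random pairs with separations matched
    to the reference pairs (separation drawn uniformly from the reference
    multiset, position uniform among valid placements).

    Returns (enhancements, threshold) where threshold is the requested
    percentile of the distribution.
    """
    ref = [(int(p[0]), int(p[1])) for p in reference_pairs]
    if not ref:
        raise ValueError("reference pair list is empty")
    seps = np.array([j - i for i, j in ref])
    rng = np.random.default_rng(seed)
    nb = cmap.n_bins
    vals = []
    while len(vals) < n:
        s = int(rng.choice(seps))
        if s >= nb:
            continue
        i = int(rng.integers(0, nb - s))
        e = contact_enhancement(cmap, (i, i + s), background_half_width)
        if np.isfinite(e):
            vals.append(e)
    vals = np.array(vals)
    return vals, float(np.percentile(vals, percentile))


# ---------------------------------------------------------------------------
# Eigen-analysis
# ---------------------------------------------------------------------------

@dataclass
class LogEigenResult:
    eigenvalues: np.ndarray   # ordered by |lambda|, descending
    eigenvectors: np.ndarray  # columns aligned with eigenvalues
    reconstruction: np.ndarray
    pseudocount: float
    mask: np.ndarray = field(default=None)


def log_eigen_analysis(cmap: ContactMap, k: int = 5,
                       pseudocount: float | None = None) -> LogEigenResult:
    """Symmetric eigendecomposition of log(P + pseudocount) restricted to
    unmasked bins; vectors ordered by |eigenvalue|; returns the rank-k
    reconstruction (full-size, masked rows zero).

    Default pseudocount = smallest positive matrix entry.
    """
    m = cmap.matrix
    mask = cmap.mask
    sub = m[np.ix_(mask, mask)]
    if pseudocount is None:
        pos = sub[sub > 0]
        if len(pos) == 0:
            raise ValueError("matrix has no positive entries")
        pseudocount = float(pos.min())
    logm = np.log(sub + pseudocount)
    if not np.all(np.isfinite(logm)):
        raise ValueError("non-finite entries in log map")
    vals, vecs = np.linalg.eigh(logm)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    kk = min(k, len(vals))
    recon_sub = (vecs[:, :kk] * vals[:kk]) @ vecs[:, :kk].T
    recon = np.zeros_like(m)
    recon[np.ix_(mask, mask)] = recon_sub
    full_vecs = np.zeros((len(mask), len(vals)))
    full_vecs[mask, :] = vecs
    return LogEigenResult(vals, full_vecs, recon, pseudocount, mask=mask)


def eigenvector_similarity(res_a: LogEigenResult, res_b: LogEigenResult,
                           k: int = 5) -> np.ndarray:
    """|PCC| between the top-k eigenvectors of two maps (sign-aligned)."""
    out = np.empty(k)
    for c in range(k):
        va = res_a.eigenvectors[:, c]
        vb = res_b.eigenvectors[:, c]
        out[c] = abs(pearsonr(va, vb).statistic)
    return out


# ---------------------------------------------------------------------------
# Interaction-matrix inspection
# ---------------------------------------------------------------------------

def interaction_matrix_analysis(params: EnergyParameters,
                                separations_beads) -> dict:
    """Inspect trained state-pair interaction matrices at given bead
    separations.

    For each separation: the 15 x 15 energy matrix (and a mean-subtracted
    display copy), average-linkage hierarchical clustering of its rows, the
    eigenvector of the largest-magnitude eigenvalue, and the spectral
    complexity curve complexity(n) = sum_{top n} |lambda| / sum |lambda|.
    Also returns the pairwise Pearson correlation between the matrices of
    different separations.
    """
    seps = [int(s) for s in separations_beads]
    mats = []
    per_sep = {}
    for s in seps:
        b = int(params.separation_bin(s))
        if b < 0:
            raise ValueError(f"separation {s} below the model's binning")
        mat = params.alpha_cs[b].copy()
        vals, vecs = np.linalg.eigh(mat)
        order = np.argsort(-np.abs(vals), kind="stable")
        vals, vecs = vals[order], vecs[:, order]
        abs_sum = np.abs(vals).sum()
        complexity = (np.cumsum(np.abs(vals)) / abs_sum if abs_sum > 0
                      else np.full(len(vals), np.nan))
        try:
            link = linkage(mat, method="average")
        except ValueError:
            link = None
        per_sep[s] = {
            "matrix": mat,
            "display_matrix": mat - mat.mean(),
            "linkage": link,
            "eigenvalues": vals,
            "leading_eigenvector": vecs[:, 0],
            "complexity": complexity,
        }
        mats.append(mat)
    npairs = len(seps)
    pcc = np.eye(npairs)
    iu = np.triu_indices(params.n_states, k=0)
    for a in range(npairs):
        for c in range(a + 1, npairs):
            x, y = mats[a][iu], mats[c][iu]
            if np.std(x) == 0 or np.std(y) == 0:
                val = np.nan
            else:
                val = pearsonr(x, y).statistic
            pcc[a, c] = pcc[c, a] = val
    return {"separations": seps, "per_separation": per_sep,
            "matrix_pcc": pcc}
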