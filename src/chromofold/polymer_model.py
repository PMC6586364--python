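"""Chromatin energy function over bead coordinates.

The chromosome is a bead-spring polymer (one bead = 5 kb = 30 nm; all
lengths in reduced units of 30 nm, energies in units of k_B T).  The total
potential is

    U_chrom(r) = U(r) + U_CS(r) + U_CTCF(r)

where ``U`` is a generic confined-polymer potential (harmonic bonds, soft
repulsive excluded volume, spherical confinement), ``U_CS`` couples pairs of
beads through chromatin-state specific contact energies that depend on the
genomic separation |j - i|, and ``U_CTCF`` condenses the segment enclosed by
a pair of convergent CTCF binding sites, mimicking cohesin-mediated loop
formation.  Both specific terms are linear in the adjustable energies
``alpha`` multiplying a smooth contact indicator ``f(r)``, which is what
makes maximum-entropy parameterization against a target contact map
tractable (see :mod:`chromofold.maxent`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CTCF_NONE",
    "CTCF_FORWARD",
    "CTCF_REVERSE",
    "CTCF_BOTH",
    "EnergyParameters",
    "LoopPair",
    "ChromatinEnergyModel",
    "contact_function",
    "contact_function_derivative",
    "enumerate_loop_pairs",
    "compute_energy",
    "compute_forces",
    "count_parameters",
    "confinement_radius_for",
]

# CTCF bead flags (shared with genome_annotation.CTCFTrack)
CTCF_NONE = 0
CTCF_FORWARD = 1
CTCF_REVERSE = 2
CTCF_BOTH = 3

DEFAULT_R_C = 1.76
DEFAULT_SIGMA = 3.72


# ---------------------------------------------------------------------------
# Contact function
# ---------------------------------------------------------------------------

def contact_function(r, r_c: float = DEFAULT_R_C, sigma: float = DEFAULT_SIGMA):
    """Smooth contact indicator f(r) in (0, 1].

    f(r) = 1/2 [1 + tanh(sigma (r_c - r))]   for r <= r_c
    f(r) = 1/2 (r_c / r)^4                   for r >  r_c

    The two branches agree at ``r_c`` (both equal 1/2) and the power-law
    tail encodes the empirical power-law relation between spatial distance
    and contact probability.  Accepts scalars or arrays; negative ``r``
    raises ``ValueError``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    short = 0.5 * (1.0 + np.tanh(sigma * (r_c - r)))
    with np.errstate(divide="ignore"):
        long_ = 0.5 * (r_c / np.where(r > 0, r, np.inf)) ** 4
    out = np.where(r <= r_c, short, long_)
    return out if out.ndim else float(out)


def contact_function_derivative(r, r_c: float = DEFAULT_R_C,
                                sigma: float = DEFAULT_SIGMA):
    """df/dr, using the short-range branch at exactly r = r_c.

    Both branches of f agree in value at r_c; the derivative is one-sided
    there and the short-range branch is used, a measure-zero convention
    fixed for bit-reproducibility.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    short = -0.5 * sigma / np.cosh(sigma * (r_c - r)) ** 2
    with np.errstate(divide="ignore"):
        long_ = -2.0 * r_c**4 / np.where(r > 0, r, np.inf) ** 5
    out = np.where(r <= r_c, short, long_)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _log_bin_edges(n_bins: int, lo: int, hi: int) -> np.ndarray:
    """Log-spaced separation-bin edges over [lo, hi] beads (n_bins + 1 edges)."""
    return np.geomspace(lo, hi, n_bins + 1)


def confinement_radius_for(n_beads: int, volume_fraction: float = 0.1) -> float:
    """Sphere radius (reduced units) at the given bead volume fraction.

    Beads are unit-diameter spheres; N (1/2)^3 / R^3 = phi.
    """
    return 0.5 * (n_beads / volume_fraction) ** (1.0 / 3.0)


@dataclass
class EnergyParameters:
    """Adjustable energies and fixed constants of the chromatin model.

    ``alpha_cs[b, I, J]`` is the state-pair contact energy for states
    (I+1, J+1) at separation bin ``b`` (symmetric in I, J).  ``alpha_ideal``
    is a homogeneous per-separation energy added to every pair at the
    separations in ``ideal_seps`` irrespective of state.  ``alpha_ctcf``
    holds the loop-term triple (alpha_CC, alpha_CCh, alpha_ChCh).

    Under the defaults (15 states, 15 separation bins, ideal separations
    2..81) the adjustable-parameter count is 120*15 + 80 + 3 = 1883.
    """

    n_states: int = 15
    sep_bin_edges: np.ndarray = field(
        default_factory=lambda: _log_bin_edges(15, 2, 2000))
    alpha_cs: np.ndarray = None  # (NB, n_states, n_states)
    ideal_seps: np.ndarray = field(
        default_factory=lambda: np.arange(2, 82))
    alpha_ideal: np.ndarray = None  # (len(ideal_seps),)
    alpha_ctcf: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_c: float = DEFAULT_R_C
    sigma: float = DEFAULT_SIGMA
    bond_k: float = 20.0
    bond_r0: float = 1.0
    ev_epsilon: float = 10.0
    ev_range: float = 1.0
    confinement_k: float = 20.0
    confinement_radius: float | None = None  # None -> volume fraction 0.1
    volume_fraction: float = 0.1

    def __post_init__(self):
        self.sep_bin_edges = np.asarray(self.sep_bin_edges, dtype=float)
        self.ideal_seps = np.asarray(self.ideal_seps, dtype=int)
        nb = self.n_sep_bins
        if self.alpha_cs is None:
            self.alpha_cs = np.zeros((nb, self.n_states, self.n_states))
        self.alpha_cs = np.asarray(self.alpha_cs, dtype=float)
        if self.alpha_cs.shape != (nb, self.n_states, self.n_states):
            raise ValueError("alpha_cs shape mismatch")
        if not np.allclose(self.alpha_cs, np.swapaxes(self.alpha_cs, 1, 2)):
            raise ValueError("alpha_cs must be symmetric in (I, J)")
        if self.alpha_ideal is None:
            self.alpha_ideal = np.zeros(len(self.ideal_seps))
        self.alpha_ideal = np.asarray(self.alpha_ideal, dtype=float)
        if self.alpha_ideal.shape != (len(self.ideal_seps),):
            raise ValueError("alpha_ideal length mismatch")
        self.alpha_ctcf = np.asarray(self.alpha_ctcf, dtype=float)
        if self.alpha_ctcf.shape != (3,):
            raise ValueError("alpha_ctcf must have 3 entries (CC, CCh, ChCh)")
        if self.r_c <= 0 or self.sigma <= 0:
            raise ValueError("r_c and sigma must be positive")

    @property
    def n_sep_bins(self) -> int:
        return len(self.sep_bin_edges) - 1

    def separation_bin(self, sep) -> np.ndarray:
        """Bin index for bead separations; -1 for separations below the
        first edge (bonded / self pairs carry no state-pair energy).
        Separations beyond the last edge use the last bin."""
        sep = np.asarray(sep, dtype=float)
        idx = np.searchsorted(self.sep_bin_edges, sep, side="right") - 1
        idx = np.minimum(idx, self.n_sep_bins - 1)
        idx = np.where(sep < self.sep_bin_edges[0], -1, idx)
        return idx

    def resolved_confinement_radius(self, n_beads: int) -> float:
        if self.confinement_radius is not None:
            return self.confinement_radius
        return confinement_radius_for(n_beads, self.volume_fraction)

    def copy(self) -> "EnergyParameters":
        return replace(
            self,
            sep_bin_edges=self.sep_bin_edges.copy(),
            alpha_cs=self.alpha_cs.copy(),
            ideal_seps=self.ideal_seps.copy(),
            alpha_ideal=self.alpha_ideal.copy(),
            alpha_ctcf=self.alpha_ctcf.copy(),
        )

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "n_states": self.n_states,
            "sep_bin_edges": self.sep_bin_edges.tolist(),
            "alpha_cs": self.alpha_cs.tolist(),
            "ideal_seps": self.ideal_seps.tolist(),
            "alpha_ideal": self.alpha_ideal.tolist(),
            "alpha_ctcf": self.alpha_ctcf.tolist(),
            "r_c": self.r_c,
            "sigma": self.sigma,
            "bond_k": self.bond_k,
            "bond_r0": self.bond_r0,
            "ev_epsilon": self.ev_epsilon,
            "ev_range": self.ev_range,
            "confinement_k": self.confinement_k,
            "confinement_radius": self.confinement_radius,
            "volume_fraction": self.volume_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EnergyParameters":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("sep_bin_edges", "alpha_cs", "ideal_seps",
                    "alpha_ideal", "alpha_ctcf"):
            payload[key] = np.asarray(payload[key])
        return cls(**payload)


def count_parameters(params: EnergyParameters) -> int:
    """Number of adjustable energies: unordered state pairs x separation
    bins, plus the ideal-separation energies, plus the CTCF triple."""
    n_pairs = params.n_states * (params.n_states + 1) // 2
    return n_pairs * params.n_sep_bins + len(params.alpha_ideal) + 3


# ---------------------------------------------------------------------------
# CTCF loop pairs
# ---------------------------------------------------------------------------

class LoopPair(NamedTuple):
    anchor_i: int
    anchor_j: int


def enumerate_loop_pairs(ctcf_flags: np.ndarray,
                         max_intervening: int = 4) -> list[LoopPair]:
    """Convergent CTCF anchor pairs eligible for the loop potential.

    A pair (i, j), i < j, qualifies when bead i carries a forward (or dual)
    flag, bead j carries a reverse (or dual) flag, and strictly between them
    there are at most ``max_intervening`` forward-oriented beads AND at most
    ``max_intervening`` reverse-oriented beads (dual beads count toward both
    tallies) -- a finite-processivity surrogate for cohesin extrusion.
    """
    flags = _as_flag_array(ctcf_flags)
    if flags.ndim != 1 or len(flags) < 2:
        raise ValueError("CTCF track must be 1-D with length >= 2")
    is_fwd = (flags == CTCF_FORWARD) | (flags == CTCF_BOTH)
    is_rev = (flags == CTCF_REVERSE) | (flags == CTCF_BOTH)
    cum_f = np.concatenate([[0], np.cumsum(is_fwd)])
    cum_r = np.concatenate([[0], np.cumsum(is_rev)])
    fwd_idx = np.flatnonzero(is_fwd)
    rev_idx = np.flatnonzero(is_rev)
    pairs = []
    for i in fwd_idx:
        for j in rev_idx[rev_idx > i]:
            n_f_between = cum_f[j] - cum_f[i + 1]
            n_r_between = cum_r[j] - cum_r[i + 1]
            if n_f_between <= max_intervening and n_r_between <= max_intervening:
                pairs.append(LoopPair(int(i), int(j)))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

def _as_state_array(states) -> np.ndarray:
    arr = np.asarray(getattr(states, "states", states), dtype=int)
    if arr.ndim != 1:
        raise ValueError("states must be a 1-D sequence")
    return arr


def _as_flag_array(ctcf_flags) -> np.ndarray:
    """Accept a CTCFTrack-like object or a plain array of flag codes."""
    if isinstance(ctcf_flags, (np.ndarray, list, tuple)):
        return np.asarray(ctcf_flags, dtype=int)
    return np.asarray(getattr(ctcf_flags, "flags", ctcf_flags), dtype=int)


class ChromatinEnergyModel:
    """Precomputed pair-coefficient view of U_chrom for one annotation.

    Because every specific term is alpha * f(r), the whole of
    U_CS + U_CTCF collapses to sum_{i<j} W_ij f(r_ij) with a coefficient
    matrix W that depends only on states, CTCF flags, loop pairs, and the
    parameters -- precomputed once, so per-step cost is the pair geometry.
    """

    def __init__(self, params: EnergyParameters, states,
                 ctcf_flags=None, loop_pairs: Sequence[LoopPair] | None = None):
        self.params = params
        self.states = _as_state_array(states)
        n = len(self.states)
        self.n_beads = n
        if np.any((self.states < 1) | (self.states > params.n_states)):
            raise ValueError("states out of range [1, n_states]")
        if ctcf_flags is None:
            flags = np.zeros(n, dtype=int)
        else:
            flags = _as_flag_array(ctcf_flags)
        if len(flags) != n:
            raise ValueError("CTCF track length must match state sequence")
        self.ctcf_flags = flags
        if loop_pairs is None:
            loop_pairs = enumerate_loop_pairs(flags) if flags.any() else []
        self.loop_pairs = list(loop_pairs)
        self.radius = params.resolved_confinement_radius(n)
        self.W = self._pair_coefficients()
        iu = np.triu_indices(n, k=1)
        self._full_pairs = (np.ascontiguousarray(iu[0], dtype=np.int64),
                            np.ascontiguousarray(iu[1], dtype=np.int64))

    def _pair_coefficients(self) -> np.ndarray:
        p = self.params
        n = self.n_beads
        s0 = self.states - 1
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        b = p.separation_bin(sep)
        W = np.zeros((n, n))
        valid = b >= 0
        W[valid] = p.alpha_cs[b[valid], s0[:, None].repeat(n, 1)[valid],
                              s0[None, :].repeat(n, 0)[valid]]
        # homogeneous ideal-separation energies
        if len(p.ideal_seps):
            ideal = dict(zip(p.ideal_seps.tolist(), p.alpha_ideal.tolist()))
            for s_val, a in ideal.items():
                if a != 0.0 and s_val < n:
                    off = np.arange(n - s_val)
                    W[off, off + s_val] += a
                    W[off + s_val, off] += a
        # CTCF loop condensation: every pair inside each convergent span
        a_cc, a_cch, a_chch = p.alpha_ctcf
        is_ctcf = self.ctcf_flags != CTCF_NONE
        for (K, L) in self.loop_pairs:
            span = np.arange(K, L + 1)
            sub_flag = is_ctcf[span]
            n_flag = sub_flag[:, None].astype(int) + sub_flag[None, :].astype(int)
            coeff = np.where(n_flag == 1, a_cch, a_chch)
            block = np.zeros((len(span), len(span)))
            iu = np.triu_indices(len(span), k=1)
            block[iu] = coeff[iu]
            block[0, -1] = a_cc  # the anchor pair itself
            block = block + block.T
            W[np.ix_(span, span)] += block
        np.fill_diagonal(W, 0.0)
        return W

    # -- geometry helpers ---------------------------------------------------
    def _check_coords(self, coords) -> np.ndarray:
        x = np.asarray(coords, dtype=float)
        if x.shape != (self.n_beads, 3):
            raise ValueError("coordinates must be (n_beads, 3)")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        return x

    def energy(self, coords, r_cut: float | None = None) -> float:
        """Total potential energy.  With ``r_cut`` the alpha*f terms are
        truncated and shifted to zero at the cutoff (the dynamics path)."""
        x = self._check_coords(coords)
        p = self.params
        diff = x[:, None, :] - x[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        iu = np.triu_indices(self.n_beads, k=1)
        r_u = r[iu]
        # specific terms
        f_u = contact_function(r_u, p.r_c, p.sigma)
        if r_cut is not None:
            f_shift = contact_function(r_cut, p.r_c, p.sigma)
            f_u = np.where(r_u < r_cut, f_u - f_shift, 0.0)
        u_spec = float(np.sum(self.W[iu] * f_u))
        # bonds
        rb = r[np.arange(self.n_beads - 1), np.arange(1, self.n_beads)]
        u_bond = float(np.sum(p.bond_k * (rb - p.bond_r0) ** 2))
        # soft-core excluded volume, all pairs
        inside = r_u < p.ev_range
        u_ev = float(np.sum(
            p.ev_epsilon * (1.0 - (r_u[inside] / p.ev_range) ** 2) ** 2))
        # spherical confinement
        rho = np.sqrt(np.einsum("ij,ij->i", x, x))
        over = np.maximum(rho - self.radius, 0.0)
        u_conf = float(np.sum(p.confinement_k * over**2))
        return u_spec + u_bond + u_ev + u_conf

    def forces(self, coords, r_cut: float | None = None,
               pairs: np.ndarray | None = None) -> np.ndarray:
        """-grad U_chrom.  ``pairs`` optionally restricts the non-bonded
        terms to a precomputed (M, 2) neighbor list (the alpha*f terms must
        then be truncated at ``r_cut`` <= list cutoff)."""
        from ._kernels import pair_forces

        x = self._check_coords(coords)
        p = self.params
        n = self.n_beads
        if pairs is None:
            ii, jj = self._full_pairs
        else:
            ii = np.ascontiguousarray(pairs[:, 0], dtype=np.int64)
            jj = np.ascontiguousarray(pairs[:, 1], dtype=np.int64)
        cut = np.inf if r_cut is None else float(r_cut)
        F = pair_forces(x, self.W, ii, jj, p.r_c, p.sigma, cut,
                        p.ev_epsilon, p.ev_range)
        # bonds (always dense, chain only)
        bi = np.arange(n - 1)
        db = x[bi] - x[bi + 1]
        with np.errstate(invalid="ignore", over="ignore"):
            rb = np.sqrt(np.einsum("ij,ij->i", db, db))
            rb_safe = np.maximum(rb, 1e-12)
            dudr_b = 2.0 * p.bond_k * (rb - p.bond_r0)
            fb = (-dudr_b / rb_safe)[:, None] * db
        np.add.at(F, bi, fb)
        np.add.at(F, bi + 1, -fb)
        # confinement
        rho = np.sqrt(np.einsum("ij,ij->i", x, x))
        over = rho > self.radius
        if np.any(over):
            # overflowing coordinates yield NaN forces here; the integrator
            # detects and reports the divergence on the next step
            with np.errstate(invalid="ignore", over="ignore"):
                coef = (-2.0 * p.confinement_k
                        * (rho[over] - self.radius) / rho[over])
            F[over] += coef[:, None] * x[over]
        return F


def compute_energy(coords, params: EnergyParameters, states,
                   ctcf_flags=None, loop_pairs=None,
                   r_cut: float | None = None) -> float:
    """Convenience wrapper; see :class:`ChromatinEnergyModel.energy`."""
    model = ChromatinEnergyModel(params, states, ctcf_flags, loop_pairs)
    return model.energy(coords, r_cut=r_cut)


def compute_forces(coords, params: EnergyParameters, states,
                   ctcf_flags=None, loop_pairs=None,
                   r_cut: float | None = None) -> np.ndarray:
    """Convenience wrapper; see :class:`ChromatinEnergyModel.forces`."""
    model = ChromatinEnergyModel(params, states, ctcf_flags, loop_pairs)
    return model.forces(coords, r_cut=r_cut)
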