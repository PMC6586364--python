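"""1D inputs of the chromatin model: chromatin states and oriented CTCF beads.

Chromatin states are discrete labels for 5 kb genomic bins inferred from the
combinatorial pattern of binarized histone marks with a multivariate hidden
Markov model (independent Bernoulli emission per mark), trained by
Baum-Welch in log space and decoded by per-bin posterior maximization.

CTCF anchor beads are compiled from ChIP-seq peak lists: a CTCF peak is
loop-forming when a Rad21 (cohesin) peak center lies within 50 bp of its
binding center; its orientation comes from the nearest CTCF motif within
100 bp when one exists, otherwise from the position of the nearest Rad21
center relative to the CTCF center (downstream -> forward 5'-3', upstream
-> reverse 3'-5').  Sites are then binned onto 5 kb beads; a bead whose
sites all share one orientation takes it, mixed beads take dual orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import poisson

from .polymer_model import CTCF_BOTH, CTCF_FORWARD, CTCF_NONE, CTCF_REVERSE

logger = logging.getLogger(__name__)

__all__ = [
    "MarkSignalMatrix",
    "StateHMM",
    "StateSequence",
    "CTCFTrack",
    "OrientedCTCFSite",
    "fit_state_hmm",
    "decode_states",
    "posterior_probabilities",
    "call_ctcf_sites",
    "bin_ctcf_sites",
    "binarize_signal",
    "read_bed_peaks",
    "read_bed_motifs",
    "read_mark_matrix",
]

DEFAULT_BIN_SIZE = 5000
RAD21_MAX_DIST = 50
MOTIF_MAX_DIST = 100


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class MarkSignalMatrix:
    """Binary histone-mark presence matrix, bins x marks."""

    values: np.ndarray
    marks: list[str]
    bin_size: int = DEFAULT_BIN_SIZE
    chrom: str = "chr"
    start_bp: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x marks)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mark values must be binary")
        if self.values.shape[1] != len(self.marks):
            raise ValueError("number of mark names must match columns")
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("mark names must be unique")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = self.values.astype(np.uint8)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class StateHMM:
    """Hidden Markov model with independent Bernoulli emissions per mark."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray  # (n_states, n_marks), P(mark present | state)
    marks: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if np.any((self.emission < 0) | (self.emission > 1)):
            raise ValueError("emission probabilities must be in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)


@dataclass
class StateSequence:
    """Per-bin chromatin state labels (1-based, in [1, n_states])."""

    states: np.ndarray
    chrom: str = "chr"
    start_bp: int = 0
    bin_size: int = DEFAULT_BIN_SIZE
    n_states: int = 15

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1 or len(self.states) < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if np.any((self.states < 1) | (self.states > self.n_states)):
            raise ValueError("state labels out of [1, n_states]")

    def __len__(self) -> int:
        return len(self.states)

    def to_tsv(self, path) -> None:
        starts = self.start_bp + self.bin_size * np.arange(len(self))
        pd.DataFrame({
            "chrom": self.chrom, "start": starts,
            "end": starts + self.bin_size, "state": self.states,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_states: int = 15) -> "StateSequence":
        df = pd.read_csv(path, sep="\t")
        bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
        return cls(df["state"].to_numpy(), chrom=str(df["chrom"].iloc[0]),
                   start_bp=int(df["start"].iloc[0]), bin_size=bin_size,
                   n_states=n_states)


_FLAG_NAMES = {CTCF_NONE: "none", CTCF_FORWARD: "forward",
               CTCF_REVERSE: "reverse", CTCF_BOTH: "both"}
_FLAG_CODES = {v: k for k, v in _FLAG_NAMES.items()}


@dataclass
class CTCFTrack:
    """Per-bead CTCF orientation flag aligned to a StateSequence."""

    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=int)
        if not np.isin(self.flags, list(_FLAG_NAMES)).all():
            raise ValueError("invalid CTCF flag code")

    def __len__(self) -> int:
        return len(self.flags)

    def to_tsv(self, path, frame: StateSequence) -> None:
        if len(self) != len(frame):
            raise ValueError("track length must match frame")
        starts = frame.start_bp + frame.bin_size * np.arange(len(self))
        pd.DataFrame({
            "chrom": frame.chrom, "start": starts,
            "end": starts + frame.bin_size,
            "ctcf_flag": [_FLAG_NAMES[f] for f in self.flags],
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CTCFTrack":
        df = pd.read_csv(path, sep="\t")
        return cls(np.array([_FLAG_CODES[f] for f in df["ctcf_flag"]]))


@dataclass(frozen=True)
class OrientedCTCFSite:
    """Single-base CTCF binding center with an assigned orientation."""

    position_bp: int
    orientation: str  # "forward" (5'-3') or "reverse" (3'-5')
    evidence: str     # "motif" or "rad21_relative"

    def __post_init__(self):
        if self.position_bp < 0:
            raise ValueError("position must be non-negative")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward/reverse")
        if self.evidence not in ("motif", "rad21_relative"):
            raise ValueError("evidence must be motif/rad21_relative")


# ---------------------------------------------------------------------------
# HMM: Baum-Welch fitting and posterior decoding
# ---------------------------------------------------------------------------

def _emission_loglik(model_emission: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """log P(obs_t | state) for every bin, (T, n_states)."""
    e = np.clip(model_emission, 1e-12, 1 - 1e-12)
    log_e = np.log(e)
    log_1me = np.log1p(-e)
    return obs.astype(float) @ log_e.T + (1 - obs).astype(float) @ log_1me.T


def _forward_backward(log_init, log_trans, log_b):
    """Log-space forward-backward; returns (log_alpha, log_beta, loglik)."""
    T, n = log_b.shape
    log_alpha = np.empty((T, n))
    log_alpha[0] = log_init + log_b[0]
    for t in range(1, T):
        log_alpha[t] = log_b[t] + logsumexp(
            log_alpha[t - 1][:, None] + log_trans, axis=0)
    loglik = float(logsumexp(log_alpha[-1]))
    log_beta = np.zeros((T, n))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(
            log_trans + (log_b[t + 1] + log_beta[t + 1])[None, :], axis=1)
    return log_alpha, log_beta, loglik


def _as_obs_list(marks) -> tuple[list[np.ndarray], list[str]]:
    if isinstance(marks, MarkSignalMatrix):
        marks = [marks]
    obs = [m.values for m in marks]
    names = marks[0].marks
    for m in marks[1:]:
        if m.marks != names:
            raise ValueError("all sequences must share the same mark set")
    return obs, list(names)


def fit_state_hmm(marks, n_states: int = 15, seed: int = 0,
                  max_iter: int = 100, tol: float = 1e-6) -> StateHMM:
    """Baum-Welch EM fit of the Bernoulli-emission state HMM.

    ``marks`` may be one :class:`MarkSignalMatrix` or a list of them (e.g.
    one per cell type); sequences are modeled independently with shared
    parameters, so a single set of states is learned jointly.  The
    log-likelihood is monotone non-decreasing across iterations (asserted);
    EM stops when the relative change drops below ``tol``.  Emission
    probabilities are initialized uniform in [0.2, 0.8] from ``seed`` and
    transitions near-diagonal, so identical seeds give bit-identical fits.
    """
    obs_list, names = _as_obs_list(marks)
    total_bins = sum(len(o) for o in obs_list)
    if total_bins == 0:
        raise ValueError("empty mark matrix")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > total_bins:
        raise ValueError("n_states exceeds number of bins")
    all_obs = np.vstack(obs_list)
    col_means = all_obs.mean(axis=0)
    for k, m in enumerate(col_means):
        if m in (0.0, 1.0):
            warnings.warn(f"mark '{names[k]}' is constant (uninformative)")

    if n_states == 1:
        return StateHMM(np.ones(1), np.ones((1, 1)),
                        col_means[None, :], marks=names)

    rng = np.random.default_rng(seed)
    n_marks = all_obs.shape[1]
    emission = rng.uniform(0.2, 0.8, size=(n_states, n_marks))
    transition = np.full((n_states, n_states),
                         0.1 / (n_states - 1))
    np.fill_diagonal(transition, 0.9)
    initial = np.full(n_states, 1.0 / n_states)

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_init = np.log(np.clip(initial, 1e-300, None))
        log_trans = np.log(np.clip(transition, 1e-300, None))
        new_init = np.zeros(n_states)
        trans_num = np.zeros((n_states, n_states))
        emit_num = np.zeros((n_states, n_marks))
        emit_den = np.zeros(n_states)
        ll = 0.0
        for obs in obs_list:
            log_b = _emission_loglik(emission, obs)
            la, lb, seq_ll = _forward_backward(log_init, log_trans, log_b)
            ll += seq_ll
            log_gamma = la + lb - seq_ll
            gamma = np.exp(log_gamma)
            new_init += gamma[0]
            if len(obs) > 1:
                # xi_t(i,j) summed over t, in log space then exponentiated
                log_xi = (la[:-1, :, None] + log_trans[None, :, :]
                          + (log_b[1:] + lb[1:])[:, None, :] - seq_ll)
                trans_num += np.exp(logsumexp(log_xi, axis=0))
            emit_num += gamma.T @ obs
            emit_den += gamma.sum(axis=0)
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), \
            "EM log-likelihood decreased"
        if np.isfinite(prev_ll) and \
                abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            prev_ll = ll
            break
        prev_ll = ll
        initial = new_init / new_init.sum()
        row = trans_num.sum(axis=1, keepdims=True)
        transition = np.where(row > 0, trans_num / np.where(row > 0, row, 1),
                              1.0 / n_states)
        transition /= transition.sum(axis=1, keepdims=True)
        emission = emit_num / np.maximum(emit_den[:, None], 1e-300)
        emission = np.clip(emission, 0.0, 1.0)
    return StateHMM(initial, transition, emission, marks=names)


def posterior_probabilities(model: StateHMM,
                            marks: MarkSignalMatrix) -> np.ndarray:
    """Per-bin posterior state probabilities, (n_bins, n_states)."""
    if model.marks and model.marks != marks.marks:
        raise ValueError("mark sets of model and data differ")
    if model.emission.shape[1] != marks.values.shape[1]:
        raise ValueError("mark dimension mismatch")
    log_b = _emission_loglik(model.emission, marks.values)
    log_init = np.log(np.clip(model.initial, 1e-300, None))
    log_trans = np.log(np.clip(model.transition, 1e-300, None))
    la, lb, ll = _forward_backward(log_init, log_trans, log_b)
    return np.exp(la + lb - ll)


def decode_states(model: StateHMM, marks: MarkSignalMatrix) -> StateSequence:
    """Posterior (forward-backward) decoding: argmax state per bin, ties
    broken toward the lowest state index.  Returns 1-based labels."""
    gamma = posterior_probabilities(model, marks)
    states = np.argmax(gamma, axis=1) + 1  # argmax returns lowest on ties
    return StateSequence(states, chrom=marks.chrom, start_bp=marks.start_bp,
                         bin_size=marks.bin_size, n_states=model.n_states)


# ---------------------------------------------------------------------------
# CTCF site calling
# ---------------------------------------------------------------------------

def _nearest_downstream_preferred(pos: int, candidates: np.ndarray) -> int:
    """Index of the candidate nearest to pos; exact distance ties (and the
    zero-distance case) resolve to the downstream candidate."""
    dist = np.abs(candidates - pos)
    best = np.min(dist)
    tied = np.flatnonzero(dist == best)
    # among tied candidates prefer the greater (downstream) coordinate
    return int(tied[np.argmax(candidates[tied])])


def call_ctcf_sites(ctcf_peaks, rad21_peaks,
                    motifs=None) -> list[OrientedCTCFSite]:
    """Loop-forming oriented CTCF sites from peak centers.

    ``ctcf_peaks`` / ``rad21_peaks``: 1-D integer peak-center coordinates
    (single chromosome).  ``motifs``: optional sequence of
    (position, strand) with strand '+' (forward) or '-' (reverse).

    A CTCF peak is kept when some Rad21 center lies within 50 bp
    (inclusive).  Orientation comes from the nearest motif within 100 bp
    (inclusive) when present, else from the nearest Rad21 center:
    downstream (greater coordinate) -> forward, upstream -> reverse.
    Equidistant ties resolve downstream.  Output is sorted by position and
    independent of input ordering.
    """
    ctcf = np.sort(np.asarray(ctcf_peaks, dtype=int))
    rad21 = np.sort(np.asarray(rad21_peaks, dtype=int))
    if np.any(ctcf < 0) or np.any(rad21 < 0):
        raise ValueError("peak coordinates must be non-negative")
    if len(rad21) == 0:
        warnings.warn("empty Rad21 peak list; no loop-forming sites called")
        return []
    if motifs is None:
        motifs = []
    motif_pos = np.array([int(p) for p, _ in motifs], dtype=int)
    motif_strand = np.array([s for _, s in motifs], dtype=object)
    order = np.argsort(motif_pos, kind="stable")
    motif_pos, motif_strand = motif_pos[order], motif_strand[order]

    sites = []
    for pos in ctcf:
        d_rad = np.abs(rad21 - pos)
        if d_rad.min() > RAD21_MAX_DIST:
            continue
        orientation = None
        evidence = "rad21_relative"
        if len(motif_pos):
            k = _nearest_downstream_preferred(pos, motif_pos)
            if abs(int(motif_pos[k]) - int(pos)) <= MOTIF_MAX_DIST:
                orientation = ("forward" if motif_strand[k] == "+"
                               else "reverse")
                evidence = "motif"
        if orientation is None:
            k = _nearest_downstream_preferred(pos, rad21)
            orientation = "forward" if rad21[k] >= pos else "reverse"
            evidence = "rad21_relative"
        sites.append(OrientedCTCFSite(int(pos), orientation, evidence))
    return sites


def bin_ctcf_sites(sites: Sequence[OrientedCTCFSite],
                   frame: StateSequence) -> CTCFTrack:
    """Assign oriented sites to the frame's 5 kb beads.

    A bead takes ``forward`` / ``reverse`` when all its sites agree and
    ``both`` (dual orientation) when mixed; beads without sites are
    ``none``.  Sites outside the frame are ignored (count logged).
    """
    n = len(frame)
    has_f = np.zeros(n, dtype=bool)
    has_r = np.zeros(n, dtype=bool)
    dropped = 0
    for site in sites:
        bead = (site.position_bp - frame.start_bp) // frame.bin_size
        if bead < 0 or bead >= n:
            dropped += 1
            continue
        if site.orientation == "forward":
            has_f[bead] = True
        else:
            has_r[bead] = True
    if dropped:
        logger.info("bin_ctcf_sites: %d site(s) outside frame ignored",
                    dropped)
    flags = np.full(n, CTCF_NONE, dtype=int)
    flags[has_f & ~has_r] = CTCF_FORWARD
    flags[~has_f & has_r] = CTCF_REVERSE
    flags[has_f & has_r] = CTCF_BOTH
    return CTCFTrack(flags)


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_peaks(path, chrom: str | None = None) -> np.ndarray:
    """Peak centers (midpoint of [start, end), floored) from a BED file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED6_COLS[: df.shape[1]]
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(int)


def read_bed_motifs(path, chrom: str | None = None) -> list[tuple[int, str]]:
    """Oriented motif (center, strand) pairs from a BED6 file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED6_COLS[: df.shape[1]]
    if "strand" not in df.columns:
        raise ValueError("motif BED must have 6 columns including strand")
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    centers = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(int)
    return list(zip(centers.tolist(), df["strand"].tolist()))


def read_mark_matrix(path, bin_size: int = DEFAULT_BIN_SIZE,
                     chrom: str = "chr", start_bp: int = 0) -> MarkSignalMatrix:
    """Binary mark matrix from a TSV with a header row of mark names."""
    df = pd.read_csv(path, sep="\t")
    return MarkSignalMatrix(df.to_numpy(), list(df.columns),
                            bin_size=bin_size, chrom=chrom, start_bp=start_bp)


def binarize_signal(counts, p_threshold: float = 1e-4):
    """Binarize a real-valued signal track against a Poisson background.

    A bin is called present when its count exceeds the (1 - p) quantile of
    a Poisson with the track's genome-wide mean -- a pre-step for mark
    tracks delivered as read counts rather than binary calls.
    """
    counts = np.asarray(counts, dtype=float)
    lam = max(counts.mean(), 1e-12)
    threshold = poisson.ppf(1.0 - p_threshold, lam)
    return (counts > threshold).astype(np.uint8)
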