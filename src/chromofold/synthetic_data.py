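"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here without downloads:
Markov-sampled chromatin-state sequences with CTCF placements, Bernoulli
mark tracks emitted from a known HMM (to test state inference), toy Hi-C
probability maps with planted TADs, compartments and loop peaks (to test
the map metrics), and small polymer ensembles simulated under planted
energy parameters (ground truth for maximum-entropy recovery).

Every generator is a pure function of its spec and seed.  The default toy
alphabet groups the 15 states into 3 classes of 5 (mirroring the
active / repressive / inactive partition of chromatin) so state-pair
constraint classes stay populated at toy scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (EnsembleTrajectory, SimulationConfig,
                       ensemble_contact_map, initialize_configuration,
                       run_langevin)
from .genome_annotation import (CTCFTrack, MarkSignalMatrix, StateSequence)
from .hic_metrics import ContactMap
from .polymer_model import (CTCF_FORWARD, CTCF_NONE, CTCF_REVERSE,
                            EnergyParameters)

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "default_state_kernel",
    "generate_annotation",
    "generate_marks",
    "generate_toy_hic",
    "generate_reference_ensemble",
    "toy_recovery_system",
    "recovery_experiment",
]


def default_state_kernel(n_states: int = 15, n_classes: int = 3,
                         stay: float = 0.95) -> np.ndarray:
    """Blocky transition kernel: sticky state classes, uniform within.

    With probability ``stay`` the chain remains in the current class
    (uniform over its states, including the current one), otherwise it
    jumps to a uniform state of another class -- produces the contiguous
    domains of like chromatin that real genomes show.
    """
    if n_states % n_classes != 0:
        raise ValueError("n_states must be divisible by n_classes")
    per = n_states // n_classes
    T = np.empty((n_states, n_states))
    for s in range(n_states):
        c = s // per
        for t in range(n_states):
            if t // per == c:
                T[s, t] = stay / per
            else:
                T[s, t] = (1.0 - stay) / (n_states - per)
    return T


@dataclass
class FixtureSpec:
    """Declarative description of a planted fixture."""

    n_beads: int = 200
    n_states: int = 15
    n_state_classes: int = 3
    transition: np.ndarray | None = None  # None -> default_state_kernel
    ctcf_placements: list = field(default_factory=list)  # (bead, "forward"/"reverse")
    tad_boundaries: list = field(default_factory=list)   # interior boundary bins
    loop_anchors: list = field(default_factory=list)     # (i, j) peak positions
    decay_exponent: float = 1.0
    tad_strength: float = 4.0
    compartment_strength: float = 1.6
    loop_amplitude: float = 6.0
    loop_width_bins: float = 1.0
    noise_level: float = 0.0   # sd of multiplicative log-normal noise
    base_probability: float = 0.6
    bin_size: int = 5000
    seed: int = 0

    def __post_init__(self):
        for bead, _ in self.ctcf_placements:
            if not 0 <= bead < self.n_beads:
                raise ValueError("CTCF placement outside [0, n_beads)")
        for b in self.tad_boundaries:
            if not 0 < b < self.n_beads:
                raise ValueError("TAD boundary outside (0, n_beads)")
        for i, j in self.loop_anchors:
            if not (0 <= i < j < self.n_beads):
                raise ValueError("loop anchors must satisfy 0 <= i < j < n")

    def state_class(self, state: int) -> int:
        """Class index (0-based) of a 1-based state label."""
        per = self.n_states // self.n_state_classes
        return (state - 1) // per


def generate_annotation(spec: FixtureSpec) -> tuple[StateSequence, CTCFTrack]:
    """Markov-sampled state sequence plus CTCF flags at the stated beads."""
    rng = np.random.default_rng(spec.seed)
    T = (spec.transition if spec.transition is not None
         else default_state_kernel(spec.n_states, spec.n_state_classes))
    T = np.asarray(T, dtype=float)
    states = np.empty(spec.n_beads, dtype=int)
    states[0] = rng.integers(spec.n_states)
    for t in range(1, spec.n_beads):
        states[t] = rng.choice(spec.n_states, p=T[states[t - 1]])
    seq = StateSequence(states + 1, bin_size=spec.bin_size,
                        n_states=spec.n_states)
    flags = np.full(spec.n_beads, CTCF_NONE, dtype=int)
    for bead, orient in spec.ctcf_placements:
        code = CTCF_FORWARD if orient == "forward" else CTCF_REVERSE
        if flags[bead] not in (CTCF_NONE, code):
            flags[bead] = 3  # both
        else:
            flags[bead] = code
    return seq, CTCFTrack(flags)


def generate_marks(states: StateSequence, emission: np.ndarray,
                   seed: int = 0, marks: list[str] | None = None
                   ) -> MarkSignalMatrix:
    """Bernoulli-sample binary mark presence per bin from a per-state
    emission matrix (the generative inverse of the state HMM)."""
    emission = np.asarray(emission, dtype=float)
    if emission.shape[0] < states.n_states and \
            emission.shape[0] < states.states.max():
        raise ValueError("emission rows must cover the state alphabet")
    rng = np.random.default_rng(seed)
    probs = emission[states.states - 1]
    values = (rng.random(probs.shape) < probs).astype(np.uint8)
    if marks is None:
        marks = [f"mark{k}" for k in range(emission.shape[1])]
    return MarkSignalMatrix(values, marks, bin_size=states.bin_size,
                            chrom=states.chrom, start_bp=states.start_bp)


def generate_toy_hic(spec: FixtureSpec) -> tuple[ContactMap, dict]:
    """Toy Hi-C probability map with planted structure and truth records.

    P_ij = base * s^(-gamma) * TAD factor * compartment factor
           + Gaussian loop peaks, all times multiplicative log-normal
    noise, clipped to (0, 1].  The TAD factor boosts pairs inside one
    planted block; the compartment factor is a checkerboard over the state
    classes of the Markov annotation; loop peaks are planted at the stated
    anchors with amplitude chosen to exceed the local background.

    Returns the map and {"boundaries", "loops", "compartment_vector",
    "states"}.
    """
    seq, _ = generate_annotation(spec)
    n = spec.n_beads
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore"):
        decay = np.where(sep > 0, sep.astype(float) ** -spec.decay_exponent,
                         1.0)
    P = spec.base_probability * decay
    # planted TAD blocks
    bounds = sorted(spec.tad_boundaries)
    edges = [0] + bounds + [n]
    block_id = np.zeros(n, dtype=int)
    for k in range(len(edges) - 1):
        block_id[edges[k]: edges[k + 1]] = k
    same_block = block_id[:, None] == block_id[None, :]
    if bounds:
        P *= np.where(same_block, spec.tad_strength, 1.0)
    # compartment checkerboard from state classes
    classes = np.array([spec.state_class(s) for s in seq.states])
    comp_vec = np.where(classes == 0, 1.0, -1.0)  # class 0 = "A"-like
    same_class = classes[:, None] == classes[None, :]
    if spec.compartment_strength != 1.0:
        P *= np.where(same_class, spec.compartment_strength,
                      1.0 / spec.compartment_strength)
    # loop peaks
    for (i, j) in spec.loop_anchors:
        gi = np.exp(-0.5 * ((idx - i) / spec.loop_width_bins) ** 2)
        gj = np.exp(-0.5 * ((idx - j) / spec.loop_width_bins) ** 2)
        peak = spec.loop_amplitude * P[i, j] * np.outer(gi, gj)
        P += peak + peak.T
    # multiplicative noise (symmetric)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed + 1)
        logn = rng.normal(0.0, spec.noise_level, size=(n, n))
        logn = 0.5 * (logn + logn.T)
        P *= np.exp(logn)
    np.fill_diagonal(P, 1.0)
    n_clip = int((P > 1.0).sum())
    if n_clip:
        logger.info("generate_toy_hic: %d entries clipped at 1", n_clip)
    P = np.clip(P, 1e-12, 1.0)
    P = 0.5 * (P + P.T)
    truth = {"boundaries": bounds, "loops": list(spec.loop_anchors),
             "compartment_vector": comp_vec, "states": seq}
    return ContactMap(P, bin_size=spec.bin_size), truth


def generate_reference_ensemble(states, ctcf_flags,
                                planted_params: EnergyParameters,
                                sim: SimulationConfig | None = None,
                                seed: int = 0
                                ) -> tuple[EnsembleTrajectory, ContactMap]:
    """Simulate a small system under planted parameters and return its
    trajectory and ensemble contact map -- the 'experimental' target for
    maximum-entropy recovery tests."""
    s_arr = np.asarray(getattr(states, "states", states))
    n = len(s_arr)
    if n > 100:
        raise ValueError("reference ensembles are for small systems (<= 100)")
    if sim is None:
        sim = SimulationConfig(n_steps=30_000, save_interval=15,
                               equilibration_steps=3_000, seed=seed)
    radius = planted_params.resolved_confinement_radius(n)
    x0 = initialize_configuration(n, radius, seed=seed)
    traj = run_langevin(x0, planted_params, states, ctcf_flags, None, sim)
    cmap = ensemble_contact_map(traj, planted_params.r_c,
                                planted_params.sigma)
    return traj, cmap


# ---------------------------------------------------------------------------
# Maximum-entropy self-consistency experiment
# ---------------------------------------------------------------------------

def toy_recovery_system() -> tuple[np.ndarray, np.ndarray, EnergyParameters]:
    """Fixed 60-bead, 3-state toy with planted interaction energies.

    States alternate in blocks of 10 (two repeats of classes 1/2/3), one
    convergent CTCF pair spans beads 5-50, and the planted energies hold
    within-state attraction (-0.5), cross-class repulsion (+0.3 between
    classes 1 and 3) weakening with separation bin, plus an attractive
    CTCF triple -- enough structure to populate every class kind while
    staying fluid enough to equilibrate at desk scale.
    """
    states = np.array(([1] * 10 + [2] * 10 + [3] * 10) * 2)
    flags = np.zeros(60, dtype=int)
    flags[5] = CTCF_FORWARD
    flags[50] = CTCF_REVERSE
    base = np.array([[-0.5, 0.0, 0.3],
                     [0.0, -0.5, 0.0],
                     [0.3, 0.0, -0.5]])
    alpha = np.stack([base * (1.0 - 0.25 * b) for b in range(3)])
    planted = EnergyParameters(
        n_states=3, sep_bin_edges=np.geomspace(2, 59, 4), alpha_cs=alpha,
        ideal_seps=np.arange(0), alpha_ideal=np.zeros(0),
        alpha_ctcf=np.array([-1.0, -0.2, -0.05]))
    return states, flags, planted


def recovery_experiment(seed: int = 1) -> dict:
    """Full maximum-entropy self-consistency experiment on the toy system.

    Generates an 'experimental' target map by long simulation of the
    planted parameters, trains from zero energies in two phases (short
    noisy rounds to approach the optimum, then long low-rate rounds for an
    accurate residual), re-simulates the trained model, and reports the
    best per-class residual max-norm, the target/re-simulated map Pearson
    correlation, and the correlation between trained and planted energies
    over well-populated classes (>= 10 member pairs).
    """
    from .maxent import _param_ref, build_constraint_classes, train

    states, flags, planted = toy_recovery_system()
    target_sim = SimulationConfig(n_steps=200_000, save_interval=25,
                                  equilibration_steps=5_000, seed=seed)
    _, target = generate_reference_ensemble(states, flags, planted,
                                            target_sim, seed=seed)
    p0 = planted.copy()
    p0.alpha_cs[:] = 0.0
    p0.alpha_ctcf[:] = 0.0
    phase1_sim = SimulationConfig(n_steps=12_000, save_interval=10,
                                  equilibration_steps=2_000, seed=seed + 1)
    p1, _ = train(target, states, flags, params0=p0, sim=phase1_sim,
                  eta=1.0, max_rounds=20, tol=0.0, seed=seed + 1)
    phase2_sim = SimulationConfig(n_steps=120_000, save_interval=20,
                                  equilibration_steps=8_000, seed=seed + 2)
    trained, state = train(target, states, flags, params0=p1,
                           sim=phase2_sim, eta=0.5, max_rounds=8, tol=0.02,
                           seed=seed + 2)
    resim_cfg = SimulationConfig(n_steps=60_000, save_interval=20,
                                 equilibration_steps=4_000, seed=seed + 3)
    _, resim_map = generate_reference_ensemble(states, flags, trained,
                                               resim_cfg, seed=seed + 3)
    from .hic_metrics import pcc_maps

    classes = build_constraint_classes(planted, states, flags)
    a_true, a_fit = [], []
    for key in classes.keys:
        if len(classes.members[key]) >= 10:
            kind, loc = _param_ref(planted, key)
            src = {"cs": (planted.alpha_cs, trained.alpha_cs),
                   "ctcf": (planted.alpha_ctcf, trained.alpha_ctcf),
                   "ideal": (planted.alpha_ideal, trained.alpha_ideal)}[kind]
            a_true.append(src[0][loc])
            a_fit.append(src[1][loc])
    return {
        "trained": trained,
        "state": state,
        "target_map": target,
        "resim_map": resim_map,
        "best_residual": float(min(state.residual_max)),
        "map_pcc": float(pcc_maps(target, resim_map)),
        "alpha_correlation": float(np.corrcoef(a_true, a_fit)[0, 1]),
    }
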