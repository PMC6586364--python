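"""Iterative maximum-entropy parameterization against a target contact map.

Every adjustable energy of the model has exactly one experimental
constraint: the mean contact probability over the pairs it multiplies
(state pair (I, J) at a separation bin; all pairs at one ideal separation;
the three CTCF loop classes).  The least-biased ensemble consistent with
those constraints is the Boltzmann ensemble of the model with suitably
chosen alphas, found by alternating Langevin sampling with the gradient
update

    alpha_c  <-  alpha_c + eta * (<f>_sim,c - <f>_target,c)

so classes whose simulated contacts exceed the target become more
repulsive.  Iteration stops when the max-norm of the class residuals drops
below tolerance or the round budget is exhausted; the best-residual
parameters are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (EnsembleTrajectory, SimulationConfig,
                       SimulationDiverged, ensemble_contact_map,
                       initialize_configuration, run_langevin)
from .hic_metrics import ContactMap
from .polymer_model import (ChromatinEnergyModel, EnergyParameters, LoopPair,
                            contact_function, count_parameters,
                            enumerate_loop_pairs)

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintClasses",
    "MaxEntState",
    "build_constraint_classes",
    "class_averages",
    "update_parameters",
    "train",
]


@dataclass
class ConstraintClasses:
    """Member pair sets for every adjustable energy.

    ``keys`` are ('state_pair', I, J, b) with I <= J (1-based states),
    ('ideal', s), or ('ctcf', kind) with kind in {'cc', 'cch', 'chch'};
    ``members[key]`` is an (M, 2) array of upper-triangle pair indices
    (possibly empty).  One class per adjustable parameter, so
    len(keys) == count_parameters(params).
    """

    keys: list
    members: dict
    n_beads: int

    def n_classes(self) -> int:
        return len(self.keys)


def build_constraint_classes(params: EnergyParameters, states,
                             ctcf_flags=None,
                             loop_pairs: list[LoopPair] | None = None
                             ) -> ConstraintClasses:
    """Enumerate the constraint class of every adjustable energy for one
    annotation.  Classes may be empty (their parameters are then frozen)."""
    model = ChromatinEnergyModel(params, states, ctcf_flags, loop_pairs)
    s = model.states
    n = model.n_beads
    iu = np.triu_indices(n, k=1)
    ii, jj = iu
    sep = jj - ii
    b = params.separation_bin(sep)
    s_lo = np.minimum(s[ii], s[jj])
    s_hi = np.maximum(s[ii], s[jj])

    keys: list = []
    members: dict = {}
    # state-pair x separation-bin classes
    for I in range(1, params.n_states + 1):
        for J in range(I, params.n_states + 1):
            pair_sel = (s_lo == I) & (s_hi == J) & (b >= 0)
            for bb in range(params.n_sep_bins):
                key = ("state_pair", I, J, bb)
                sel = pair_sel & (b == bb)
                keys.append(key)
                members[key] = np.column_stack([ii[sel], jj[sel]])
    # homogeneous ideal-separation classes
    for s_val in params.ideal_seps:
        key = ("ideal", int(s_val))
        sel = sep == s_val
        keys.append(key)
        members[key] = np.column_stack([ii[sel], jj[sel]])
    # CTCF loop classes (pairs inside convergent spans, by contact class)
    is_ctcf = model.ctcf_flags != 0
    cc, cch, chch = set(), set(), set()
    for (K, L) in model.loop_pairs:
        for k in range(K, L + 1):
            for l in range(k + 1, L + 1):
                if (k, l) == (K, L):
                    cc.add((k, l))
                elif int(is_ctcf[k]) + int(is_ctcf[l]) == 1:
                    cch.add((k, l))
                else:
                    chch.add((k, l))
    for kind, pair_set in (("cc", cc), ("cch", cch), ("chch", chch)):
        key = ("ctcf", kind)
        keys.append(key)
        members[key] = (np.array(sorted(pair_set), dtype=int).reshape(-1, 2))
    assert len(keys) == count_parameters(params), \
        "class enumeration out of sync with parameter count"
    return ConstraintClasses(keys, members, n)


def class_averages(cmap: ContactMap | np.ndarray,
                   classes: ConstraintClasses) -> dict:
    """Mean contact probability per constraint class; empty classes map to
    NaN.  Raises when every class is empty."""
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap)
    if m.shape[0] != classes.n_beads:
        raise ValueError("map dimension does not match annotation length")
    out = {}
    any_nonempty = False
    for key in classes.keys:
        mem = classes.members[key]
        if len(mem) == 0:
            out[key] = np.nan
        else:
            any_nonempty = True
            out[key] = float(m[mem[:, 0], mem[:, 1]].mean())
    if not any_nonempty:
        raise ValueError("all constraint classes are empty")
    return out


def _param_ref(params: EnergyParameters, key):
    """(array, index) locating the adjustable energy for a class key."""
    if key[0] == "state_pair":
        _, I, J, b = key
        return "cs", (b, I - 1, J - 1)
    if key[0] == "ideal":
        idx = int(np.flatnonzero(params.ideal_seps == key[1])[0])
        return "ideal", idx
    kind_idx = {"cc": 0, "cch": 1, "chch": 2}[key[1]]
    return "ctcf", kind_idx


def update_parameters(params: EnergyParameters, sim_avgs: dict,
                      target_avgs: dict, eta: float) -> EnergyParameters:
    """One maximum-entropy gradient step; empty classes (NaN averages)
    are untouched.  Raises on mismatched class sets."""
    if set(sim_avgs) != set(target_avgs):
        raise ValueError("simulated and target class sets differ")
    new = params.copy()
    for key, sim_val in sim_avgs.items():
        tgt = target_avgs[key]
        if not (np.isfinite(sim_val) and np.isfinite(tgt)):
            continue
        delta = eta * (sim_val - tgt)
        kind, loc = _param_ref(new, key)
        if kind == "cs":
            b, i, j = loc
            new.alpha_cs[b, i, j] += delta
            if i != j:
                new.alpha_cs[b, j, i] += delta
        elif kind == "ideal":
            new.alpha_ideal[loc] += delta
        else:
            new.alpha_ctcf[loc] += delta
    return new


@dataclass
class MaxEntState:
    """Training record: per-round residuals and the best parameters."""

    classes: ConstraintClasses
    target_avgs: dict
    params_history: list = field(default_factory=list)
    sim_avgs_history: list = field(default_factory=list)
    residual_max: list = field(default_factory=list)
    residual_rms: list = field(default_factory=list)
    eta_history: list = field(default_factory=list)
    best_round: int = -1

    @property
    def n_rounds(self) -> int:
        return len(self.residual_max)

    def log_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "round": np.arange(self.n_rounds),
            "eta": self.eta_history,
            "residual_max": self.residual_max,
            "residual_rms": self.residual_rms,
        })


def _residuals(sim_avgs: dict, target_avgs: dict) -> np.ndarray:
    vals = [sim_avgs[k] - target_avgs[k] for k in sim_avgs
            if np.isfinite(sim_avgs[k]) and np.isfinite(target_avgs[k])]
    return np.asarray(vals)


def train(target: ContactMap, states, ctcf_flags=None,
          loop_pairs: list[LoopPair] | None = None,
          params0: EnergyParameters | None = None,
          sim: SimulationConfig | None = None,
          eta: float = 0.5, max_rounds: int = 30, tol: float = 0.02,
          seed: int = 0, max_retries: int = 3,
          ) -> tuple[EnergyParameters, MaxEntState]:
    """Parameterize the model against a target probability map.

    Target probabilities above f(0) (the contact model's ceiling) are
    clipped with a warning.  Each round re-equilibrates from the previous
    round's last frame; a diverging round halves eta and retries (bounded).
    Deterministic for a given seed.  Returns the best-residual parameters
    and the full training state.
    """
    if params0 is None:
        raise ValueError("supply an EnergyParameters template (e.g. zeros)")
    params = params0.copy()
    if sim is None:
        sim = SimulationConfig(n_steps=8000, save_interval=10,
                               equilibration_steps=1000, seed=seed)
    if ctcf_flags is not None and loop_pairs is None:
        from .polymer_model import _as_flag_array

        flags = _as_flag_array(ctcf_flags)
        loop_pairs = enumerate_loop_pairs(flags) if flags.any() else []
    classes = build_constraint_classes(params, states, ctcf_flags, loop_pairs)

    f0 = contact_function(0.0, params.r_c, params.sigma)
    tmat = np.asarray(target.matrix, dtype=float)
    n_clip = int((tmat > f0).sum())
    if n_clip:
        logger.warning("train: %d target entries above f(0)=%.4f clipped",
                       n_clip, f0)
    target_clipped = ContactMap(np.minimum(tmat, f0), bin_size=target.bin_size,
                                chrom=target.chrom, start_bp=target.start_bp,
                                mask=target.mask)
    target_avgs = class_averages(target_clipped, classes)
    state = MaxEntState(classes=classes, target_avgs=target_avgs)

    n = classes.n_beads
    radius = params.resolved_confinement_radius(n)
    x0 = initialize_configuration(n, radius, seed=seed)
    best = np.inf
    best_params = params.copy()
    for rnd in range(max_rounds):
        traj = None
        for attempt in range(max_retries + 1):
            round_sim = SimulationConfig(
                n_steps=sim.n_steps, timestep=sim.timestep,
                friction=sim.friction, temperature=sim.temperature,
                save_interval=sim.save_interval,
                equilibration_steps=sim.equilibration_steps,
                seed=sim.seed, run_index=rnd * (max_retries + 1) + attempt,
                force_cutoff=sim.force_cutoff,
                neighbor_cutoff=sim.neighbor_cutoff,
                neighbor_rebuild=sim.neighbor_rebuild,
                divergence_threshold=sim.divergence_threshold)
            try:
                traj = run_langevin(x0, params, states, ctcf_flags,
                                    loop_pairs, round_sim)
                break
            except SimulationDiverged as exc:
                eta *= 0.5
                logger.warning("round %d diverged (%s); eta halved to %g",
                               rnd, exc, eta)
        if traj is None:
            raise RuntimeError("simulation kept diverging; training aborted")
        x0 = traj.frames[-1].copy()
        sim_map = ensemble_contact_map(traj, params.r_c, params.sigma,
                                       bin_size=target.bin_size)
        sim_avgs = class_averages(sim_map, classes)
        res = _residuals(sim_avgs, target_avgs)
        res_max = float(np.max(np.abs(res)))
        res_rms = float(np.sqrt(np.mean(res**2)))
        state.params_history.append(params.copy())
        state.sim_avgs_history.append(sim_avgs)
        state.residual_max.append(res_max)
        state.residual_rms.append(res_rms)
        state.eta_history.append(eta)
        logger.info("maxent round %d: max residual %.4f rms %.4f",
                    rnd, res_max, res_rms)
        if res_max < best:
            best = res_max
            best_params = params.copy()
            state.best_round = rnd
        if res_max < tol:
            break
        params = update_parameters(params, sim_avgs, target_avgs, eta)
    return best_params, state
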