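"""Shared fixtures and independent oracle implementations.

The oracles here re-derive quantities by brute force (naive double loops,
exhaustive path enumeration, direct eigendecomposition) and must stay
independent of the package code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import chromofold as cf


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def contact_f(r, r_c=1.76, sigma=3.72):
    """Contact indicator re-derived from its definition (scalar math)."""
    if r <= r_c:
        return 0.5 * (1.0 + math.tanh(sigma * (r_c - r)))
    return 0.5 * (r_c / r) ** 4


def naive_energy(coords, params, states, flags=None, loop_pairs=None,
                 radius=None):
    """O(N^2) double-loop reference for the full chromatin energy."""
    coords = np.asarray(coords, float)
    states = np.asarray(states, int)
    n = len(states)
    if flags is None:
        flags = np.zeros(n, int)
    flags = np.asarray(flags, int)
    if loop_pairs is None:
        loop_pairs = []
    if radius is None:
        radius = params.resolved_confinement_radius(n)
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sep = j - i
            # state-pair term
            b = int(params.separation_bin(sep))
            if b >= 0:
                u += params.alpha_cs[b, states[i] - 1, states[j] - 1] \
                    * contact_f(r, params.r_c, params.sigma)
            # ideal term
            hits = np.flatnonzero(params.ideal_seps == sep)
            if len(hits):
                u += params.alpha_ideal[hits[0]] \
                    * contact_f(r, params.r_c, params.sigma)
            # excluded volume
            if r < params.ev_range:
                u += params.ev_epsilon * (1 - (r / params.ev_range) ** 2) ** 2
        # confinement
        rho = float(np.linalg.norm(coords[i]))
        if rho > radius:
            u += params.confinement_k * (rho - radius) ** 2
    # bonds
    for i in range(n - 1):
        r = float(np.linalg.norm(coords[i] - coords[i + 1]))
        u += params.bond_k * (r - params.bond_r0) ** 2
    # CTCF loop term
    a_cc, a_cch, a_chch = params.alpha_ctcf
    for (K, L) in loop_pairs:
        for k in range(K, L + 1):
            for l in range(k + 1, L + 1):
                r = float(np.linalg.norm(coords[k] - coords[l]))
                if (k, l) == (K, L):
                    a = a_cc
                elif (flags[k] != 0) != (flags[l] != 0):
                    a = a_cch
                else:
                    a = a_chch
                u += a * contact_f(r, params.r_c, params.sigma)
    return u


def brute_force_posterior(initial, transition, emission, obs):
    """Exact per-bin posteriors by enumerating every state path."""
    T = len(obs)
    n = len(initial)
    post = np.zeros((T, n))
    total = 0.0
    for path in itertools.product(range(n), repeat=T):
        p = initial[path[0]]
        for t in range(1, T):
            p *= transition[path[t - 1], path[t]]
        for t in range(T):
            for m in range(obs.shape[1]):
                e = emission[path[t], m]
                p *= e if obs[t, m] else (1 - e)
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def reference_diffusion_coords(d, k_scale, n_components):
    """Dense diffusion-map embedding computed directly from the distance
    matrix with numpy's general eigensolver (non-symmetric route)."""
    nf = d.shape[0]
    k = min(k_scale, nf - 1)
    eps = np.array([np.median(np.sort(d[a])[1:k + 1]) for a in range(nf)])
    eps = np.maximum(eps, np.finfo(float).eps)
    K = np.exp(-(d ** 2) / np.outer(eps, eps))
    q = K.sum(1)
    Kt = K / np.outer(q, q)
    M = Kt / Kt.sum(1, keepdims=True)
    vals, vecs = np.linalg.eig(M)
    order = np.argsort(-vals.real)
    vals, vecs = vals[order].real, vecs[:, order].real
    return vals, vecs[:, 1:1 + n_components]


@pytest.fixture(scope="session")
def oracles():
    return {
        "contact_f": contact_f,
        "naive_energy": naive_energy,
        "brute_force_posterior": brute_force_posterior,
        "reference_diffusion_coords": reference_diffusion_coords,
    }


# ---------------------------------------------------------------------------
# Planted HMM data
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_hmm():
    """3-state Bernoulli HMM with well-separated emissions and the mark
    data sampled from it (2000 bins, seed 7)."""
    emission = np.array([
        [0.9, 0.9, 0.1, 0.1, 0.1, 0.1],
        [0.1, 0.1, 0.9, 0.9, 0.1, 0.1],
        [0.1, 0.1, 0.1, 0.1, 0.9, 0.9],
    ])
    transition = np.array([[0.9, 0.05, 0.05],
                           [0.05, 0.9, 0.05],
                           [0.05, 0.05, 0.9]])
    initial = np.full(3, 1 / 3)
    rng = np.random.default_rng(7)
    T = 2000
    z = np.empty(T, int)
    z[0] = rng.integers(3)
    for t in range(1, T):
        z[t] = rng.choice(3, p=transition[z[t - 1]])
    obs = (rng.random((T, 6)) < emission[z]).astype(np.uint8)
    marks = cf.MarkSignalMatrix(obs, [f"m{k}" for k in range(6)])
    return {"initial": initial, "transition": transition,
            "emission": emission, "hidden": z, "marks": marks}


@pytest.fixture(scope="session")
def fitted_hmm(planted_hmm):
    """Converged EM fit of the planted-HMM mark data."""
    return cf.fit_state_hmm(planted_hmm["marks"], n_states=3, seed=7,
                            max_iter=200, tol=1e-8)


# ---------------------------------------------------------------------------
# Toy Hi-C fixture with planted structure
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_hic():
    spec = cf.FixtureSpec(
        n_beads=500, tad_boundaries=[150, 300],
        loop_anchors=[(60, 120), (200, 270), (330, 420)],
        tad_strength=4.0, compartment_strength=1.3,
        loop_amplitude=6.0, loop_width_bins=0.7,
        noise_level=0.05, seed=5)
    cmap, truth = cf.generate_toy_hic(spec)
    return {"spec": spec, "map": cmap, "truth": truth}


# ---------------------------------------------------------------------------
# Expensive sampling fixtures (shared between module and acceptance tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def dimer_run():
    """Harmonic dimer sampled for 1e5 steps; returns bond lengths."""
    params = cf.EnergyParameters(
        n_states=1, sep_bin_edges=np.array([2.0, 3.0]),
        alpha_cs=np.zeros((1, 1, 1)), ideal_seps=np.arange(0),
        alpha_ideal=np.zeros(0), ev_epsilon=0.0,
        confinement_radius=1e6)
    states = np.array([1, 1])
    x0 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    sim = cf.SimulationConfig(n_steps=100_000, save_interval=100,
                              equilibration_steps=2_000, friction=2.0,
                              seed=42)
    traj = cf.run_langevin(x0, params, states, None, None, sim)
    bonds = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)
    return {"params": params, "bond_lengths": bonds}


@pytest.fixture(scope="session")
def free_particle_run():
    """100 non-interacting beads (zero bond stiffness) for diffusion
    checks; returns frames and the simulation config."""
    params = cf.EnergyParameters(
        n_states=1, sep_bin_edges=np.array([2.0, 3.0]),
        alpha_cs=np.zeros((1, 1, 1)), ideal_seps=np.arange(0),
        alpha_ideal=np.zeros(0), bond_k=0.0, ev_epsilon=0.0,
        confinement_radius=1e9)
    n = 100
    states = np.ones(n, int)
    rng = np.random.default_rng(3)
    x0 = rng.uniform(-5, 5, (n, 3))
    sim = cf.SimulationConfig(n_steps=100_000, save_interval=100,
                              equilibration_steps=0, friction=0.5, seed=9)
    traj = cf.run_langevin(x0, params, states, None, None, sim)
    return {"traj": traj, "sim": sim}


@pytest.fixture(scope="session")
def recovery_results():
    """Maximum-entropy self-consistency experiment on the 60-bead toy."""
    return cf.recovery_experiment(seed=1)


@pytest.fixture(scope="session")
def two_cluster_frames():
    """Two well-separated conformation clusters (2 x 50 frames around two
    distinct 20-bead templates) for diffusion-map tests."""
    rng = np.random.default_rng(17)
    t1 = cf.initialize_configuration(20, 10.0, seed=1)
    t2 = cf.initialize_configuration(20, 10.0, seed=2)
    frames = []
    labels = []
    for _ in range(50):
        frames.append(t1 + rng.normal(0, 0.3, t1.shape))
        labels.append(0)
    for _ in range(50):
        frames.append(t2 + rng.normal(0, 0.3, t2.shape))
        labels.append(1)
    return np.array(frames), np.array(labels)
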