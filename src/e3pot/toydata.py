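"""Analytic toy potential and configuration samplers.

Stands in for ab-initio reference data: a smoothly truncated Lennard-Jones
pair potential with exact analytic forces.  Labels generated here are
energy-conserving by construction (forces are the exact gradient of the
energy), so any failure of the model-side force/finite-difference checks
isolates a model bug, not a data bug.  The cutoff uses the same polynomial
envelope family as the network's radial basis, keeping the target function
smooth at the model's own cutoff radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .radial import envelope
from .structures import AtomicStructure, build_neighbor_graph

__all__ = [
    "ToyPotentialParams",
    "toy_energy_forces",
    "sample_dataset",
    "brownian_trajectory",
    "simple_cubic_structure",
]


@dataclass
class ToyPotentialParams:
    """Lennard-Jones well depth (eV), length scale (Å) and smooth cutoff (Å).

    ``species_params`` optionally maps atomic number -> (epsilon, sigma);
    pair parameters then follow Lorentz-Berthelot combination (geometric
    mean for epsilon, arithmetic mean for sigma).

    ``angular_strength`` (eV, default 0 = pure pair potential) adds a
    Stillinger-Weber-style three-body term
    ``eps3 (cos th_jik - cos0)^2 g(r_ij) g(r_ik)`` over neighbor pairs of
    every center atom, with the same smooth envelope ``g``; it gives the
    target genuine many-body (angular) character, which a sum of radial pair
    terms cannot represent.
    """

    epsilon: float = 0.2
    sigma: float = 2.2
    cutoff: float = 4.0
    envelope_p: int = 6
    species_params: Optional[dict] = None
    angular_strength: float = 0.0
    angular_cos0: float = -1.0 / 3.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma <= 0 or self.cutoff <= 0:
            raise ValueError("epsilon, sigma and cutoff must be positive")
        if self.angular_strength < 0:
            raise ValueError("angular strength must be non-negative")

    def pair(self, z1: int, z2: int):
        if not self.species_params:
            return self.epsilon, self.sigma
        e1, s1 = self.species_params.get(z1, (self.epsilon, self.sigma))
        e2, s2 = self.species_params.get(z2, (self.epsilon, self.sigma))
        return float(np.sqrt(e1 * e2)), 0.5 * (s1 + s2)


def _envelope_deriv(u: np.ndarray, p: int) -> np.ndarray:
    a = (p + 1.0) * (p + 2.0) / 2.0
    b = p * (p + 2.0)
    c = p * (p + 1.0) / 2.0
    d = -a * p * u ** (p - 1) + b * (p + 1) * u**p - c * (p + 2) * u ** (p + 1)
    return np.where(u < 1.0, d, 0.0)


def toy_energy_forces(structure: AtomicStructure, params: ToyPotentialParams = None):
    """Total energy (eV) and analytic forces (eV/Å) of the toy potential.

    Pairwise ``4 eps [(sigma/r)^12 - (sigma/r)^6] * f_env(r / cutoff)`` summed
    over all neighbor pairs (periodic images included).  Atoms closer than
    ``0.1 sigma`` are rejected as overlapping.
    """
    if params is None:
        params = ToyPotentialParams()
    g = build_neighbor_graph(structure, params.cutoff)
    n = structure.n_atoms
    forces = np.zeros((n, 3))
    if g.n_edges == 0:
        return 0.0, forces
    eps = np.empty(g.n_edges)
    sig = np.empty(g.n_edges)
    if params.species_params:
        for k in range(g.n_edges):
            eps[k], sig[k] = params.pair(
                structure.species[g.edge_i[k]], structure.species[g.edge_j[k]]
            )
    else:
        eps[:] = params.epsilon
        sig[:] = params.sigma
    r = g.distances
    if np.any(r < 0.1 * sig):
        raise ValueError("overlapping atoms: pair distance below 0.1 sigma")
    u = r / params.cutoff
    x6 = (sig / r) ** 6
    lj = 4.0 * eps * (x6 * x6 - x6)
    dlj = 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / r
    env = envelope(u, params.envelope_p)
    denv = _envelope_deriv(u, params.envelope_p) / params.cutoff
    phi = lj * env
    dphi = dlj * env + lj * denv
    energy = 0.5 * float(phi.sum())
    # dE/dr_i for edge (i -> j): phi'(r) * (-r_hat_ij); force is the negative
    rhat = g.vectors / r[:, None]
    np.add.at(forces, g.edge_i, dphi[:, None] * rhat)
    if params.angular_strength > 0:
        e3, f3 = _three_body(structure, g, params)
        energy += e3
        forces += f3
    return energy, forces


def _three_body(structure, g, params):
    """Angular term: eps3 (cos th - cos0)^2 g(r_ij) g(r_ik) over neighbor
    pairs (j, k) of each center i, with hand-derived analytic forces."""
    eps3, c0 = params.angular_strength, params.angular_cos0
    n = structure.n_atoms
    forces = np.zeros((n, 3))
    energy = 0.0
    r = g.distances
    u_all = g.vectors / r[:, None]
    env = envelope(r / params.cutoff, params.envelope_p)
    denv = _envelope_deriv(r / params.cutoff, params.envelope_p) / params.cutoff
    for i in range(n):
        sel = np.nonzero(g.edge_i == i)[0]
        if len(sel) < 2:
            continue
        a, b = np.triu_indices(len(sel), k=1)
        ja, jb = sel[a], sel[b]
        u, v = u_all[ja], u_all[jb]
        c = (u * v).sum(axis=1)
        dc = c - c0
        gj, gk = env[ja], env[jb]
        energy += float(eps3 * (dc**2 * gj * gk).sum())
        # grad of c w.r.t. the two neighbor endpoints
        dcdj = (v - c[:, None] * u) / r[ja][:, None]
        dcdk = (u - c[:, None] * v) / r[jb][:, None]
        grad_j = eps3 * (2 * dc * gj * gk)[:, None] * dcdj \
            + eps3 * (dc**2 * gk * denv[ja])[:, None] * u
        grad_k = eps3 * (2 * dc * gj * gk)[:, None] * dcdk \
            + eps3 * (dc**2 * gj * denv[jb])[:, None] * v
        np.add.at(forces, g.edge_j[ja], -grad_j)
        np.add.at(forces, g.edge_j[jb], -grad_k)
        forces[i] += (grad_j + grad_k).sum(axis=0)
    return energy, forces


def simple_cubic_structure(n_cells: int = 2, spacing: float = 2.47, z: int = 18,
                           periodic: bool = True) -> AtomicStructure:
    """A simple-cubic arrangement used as the sampling template."""
    pts = np.array([(i, j, k)
                    for i in range(n_cells)
                    for j in range(n_cells)
                    for k in range(n_cells)], dtype=float) * spacing
    species = np.full(len(pts), z)
    if periodic:
        cell = np.eye(3) * (n_cells * spacing)
        return AtomicStructure(pts, species, cell=cell, pbc=[True] * 3)
    return AtomicStructure(pts, species)


def sample_dataset(template: AtomicStructure, n_frames: int, displacement: float,
                   seed: int, params: ToyPotentialParams = None) -> list:
    """Gaussian-perturbed copies of the template labeled by the toy oracle.

    Deterministic given the seed; frames with overlapping atoms are rejected
    and resampled.  A rejection rate above 90% aborts with a suggestion to
    lower the displacement scale.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if params is None:
        params = ToyPotentialParams()
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < n_frames:
        attempts += 1
        if attempts > 10 * n_frames and len(out) < 0.1 * attempts:
            raise RuntimeError(
                "rejection rate above 90%; reduce the displacement scale"
            )
        s = template.copy()
        s.positions = s.positions + rng.normal(scale=displacement, size=s.positions.shape)
        try:
            e, f = toy_energy_forces(s, params)
        except ValueError:
            continue
        s.energy = e
        s.forces = f
        out.append(s)
    return out


def brownian_trajectory(n_atoms: int, n_steps: int, step_std: float, dt: float,
                        seed: int):
    """Synthetic Brownian walk (oracle for the diffusivity estimator).

    Independent Gaussian displacements per step and component, so the true
    diffusion coefficient is ``step_std**2 / (2 dt)`` in Å²/fs.
    """
    from .dynamics import Trajectory

    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=step_std, size=(n_steps, n_atoms, 3))
    pos = np.concatenate([np.zeros((1, n_atoms, 3)), np.cumsum(steps, axis=0)])
    species = np.full(n_atoms, 18)
    return Trajectory(
        positions=pos.copy(),
        unwrapped=pos,
        velocities=np.zeros_like(pos),
        dt=dt,
        temperatures=np.zeros(len(pos)),
        cell=None,
        species=species,
    )
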