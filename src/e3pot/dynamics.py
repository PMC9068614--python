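"""NVT molecular dynamics and trajectory observables (RDF, ADF, MSD, D).

The integrator is velocity Verlet with a single Nosé-Hoover thermostat
variable; with the thermostat disabled it reduces exactly to NVE, which is
the energy-conservation test of the force field (forces must be true
gradients and smooth at the cutoff for the drift to stay small).

Units: positions Å, time fs, energy eV, masses amu, temperature K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .structures import ATOMIC_MASSES, AtomicStructure, build_neighbor_graph

__all__ = [
    "Trajectory",
    "ThermostatParams",
    "run_nvt",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
    "msd",
    "diffusivity",
    "rdf",
    "adf",
    "KB_EV",
]

KB_EV = 8.617333262e-5          # Boltzmann constant, eV/K
EV_PER_AMU_A2_FS2 = 103.642697  # 1 amu Å²/fs² in eV


@dataclass
class Trajectory:
    """Time-ordered frames produced by the MD driver."""

    positions: np.ndarray     # wrapped, (T, N, 3) Å
    unwrapped: np.ndarray     # continuous, (T, N, 3) Å
    velocities: np.ndarray    # (T, N, 3) Å/fs
    dt: float                 # fs (between stored frames)
    temperatures: np.ndarray  # (T,) K
    cell: Optional[np.ndarray]
    species: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def total_time(self) -> float:
        return self.n_frames * self.dt


@dataclass
class ThermostatParams:
    """Nosé-Hoover target temperature (K) and coupling constant Q.

    Q has units of eV·fs²; larger Q couples more weakly.  A rule-of-thumb
    default is ``3 N kB T tau**2`` with a coupling time tau of ~50 fs.
    """

    temperature: float
    Q: float

    def __post_init__(self):
        if self.temperature <= 0 or self.Q <= 0:
            raise ValueError("temperature and Q must be positive")

    @classmethod
    def with_tau(cls, temperature: float, n_atoms: int, tau_fs: float = 50.0):
        Q = 3 * n_atoms * KB_EV * temperature * tau_fs**2
        return cls(temperature=temperature, Q=Q)


def _masses(species: np.ndarray) -> np.ndarray:
    return ATOMIC_MASSES[species]


def kinetic_temperature(velocities: np.ndarray, species: np.ndarray) -> float:
    """Instantaneous temperature from equipartition over 3N degrees of freedom."""
    m = _masses(species)
    ke = 0.5 * EV_PER_AMU_A2_FS2 * float((m[:, None] * velocities**2).sum())
    return 2.0 * ke / (3.0 * len(species) * KB_EV)


def maxwell_boltzmann_velocities(species: np.ndarray, temperature: float,
                                 rng) -> np.ndarray:
    """Velocities sampled from the Maxwell-Boltzmann distribution (Å/fs),
    with the center-of-mass drift removed."""
    m = _masses(species)
    sigma = np.sqrt(KB_EV * temperature / (EV_PER_AMU_A2_FS2 * m))
    v = rng.normal(size=(len(species), 3)) * sigma[:, None]
    v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def run_nvt(force_fn: Callable, start: AtomicStructure, temperature: float,
            dt: float, n_steps: int, thermostat: Optional[ThermostatParams] = None,
            seed: int = 0, sample_every: int = 1,
            initial_velocities: Optional[np.ndarray] = None) -> Trajectory:
    """Velocity-Verlet MD with an optional single Nosé-Hoover variable.

    ``force_fn(structure) -> (energy eV, forces eV/Å)``.  With
    ``thermostat=None`` the run is plain NVE (the friction variable stays
    zero).  Initial velocities are Maxwell-Boltzmann at ``temperature``
    unless given explicitly; the run is deterministic given the seed.
    Non-finite forces abort with the last structure attached to the error.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    rng = np.random.default_rng(seed)
    s = start.copy()
    n = s.n_atoms
    m = _masses(s.species)[:, None]
    if initial_velocities is not None:
        v = np.array(initial_velocities, dtype=float)
    elif temperature > 0:
        v = maxwell_boltzmann_velocities(s.species, temperature, rng)
    else:
        v = np.zeros((n, 3))
    g_dof = 3 * n
    xi = 0.0
    kT = KB_EV * temperature

    def accel(structure):
        e, f = force_fn(structure)
        if not np.all(np.isfinite(f)):
            err = RuntimeError("non-finite forces during MD")
            err.last_structure = structure
            raise err
        return e, f * (1.0 / EV_PER_AMU_A2_FS2) / m

    def twice_ke(vel):
        return EV_PER_AMU_A2_FS2 * float((m * vel**2).sum())

    _, a = accel(s)
    unwrapped = s.positions.copy()
    frames_w, frames_u, frames_v, temps = [], [], [], []

    def record():
        frames_w.append(_wrap(unwrapped, s.cell, s.pbc))
        frames_u.append(unwrapped.copy())
        frames_v.append(v.copy())
        temps.append(kinetic_temperature(v, s.species))

    record()
    for step in range(n_steps):
        unwrapped = unwrapped + v * dt + 0.5 * (a - xi * v) * dt**2
        v_half = v + 0.5 * (a - xi * v) * dt
        s.positions = _wrap(unwrapped, s.cell, s.pbc)
        _, a = accel(s)
        if thermostat is not None:
            xi_half = xi + 0.5 * dt / thermostat.Q * (twice_ke(v) - g_dof * kT)
            xi = xi_half + 0.5 * dt / thermostat.Q * (twice_ke(v_half) - g_dof * kT)
            v = (v_half + 0.5 * dt * a) / (1.0 + 0.5 * dt * xi)
        else:
            v = v_half + 0.5 * dt * a
        if (step + 1) % sample_every == 0:
            record()
    return Trajectory(
        positions=np.array(frames_w),
        unwrapped=np.array(frames_u),
        velocities=np.array(frames_v),
        dt=dt * sample_every,
        temperatures=np.array(temps),
        cell=None if s.cell is None else s.cell.copy(),
        species=s.species.copy(),
    )


def _wrap(positions, cell, pbc):
    if cell is None or not np.any(pbc):
        return positions.copy()
    frac = positions @ np.linalg.inv(cell)
    frac[:, pbc] -= np.floor(frac[:, pbc])
    return frac @ cell


# --------------------------------------------------------------------------
# observables
# --------------------------------------------------------------------------

def msd(trajectory: Trajectory, element: Optional[int] = None,
        max_lag: Optional[int] = None):
    """Mean square displacement (Å²) vs lag time (fs), multi-origin average.

    Uses unwrapped coordinates; the default maximum lag is half the
    trajectory so every lag averages over at least T/2 origins.
    """
    u = trajectory.unwrapped
    if element is not None:
        sel = trajectory.species == element
        if not sel.any():
            raise ValueError(f"no atoms with Z={element}")
        u = u[:, sel]
    T = len(u)
    if max_lag is None:
        max_lag = T // 2
    if max_lag >= T:
        raise ValueError("lag window exceeds trajectory length")
    lags = np.arange(max_lag + 1)
    out = np.zeros(len(lags))
    for k, lag in enumerate(lags[1:], start=1):
        d = u[lag:] - u[:-lag]
        out[k] = (d**2).sum(axis=-1).mean()
    return lags * trajectory.dt, out


def diffusivity(times: np.ndarray, msd_curve: np.ndarray,
                fit_window: Optional[tuple] = None):
    """Diffusion coefficient from the MSD slope: D = slope / 6 (3D).

    ``fit_window`` is (t_min, t_max) in fs; the default discards the first
    10% of the available lags and fits up to the end.  Returns a dict with D
    in both Å²/fs and cm²/s (1 Å²/fs = 0.1 cm²/s), the fit R², and a
    ``non_diffusive`` flag raised when the log-log slope of the MSD deviates
    strongly from 1 (e.g. ballistic motion, slope 2).
    """
    if fit_window is None:
        fit_window = (0.1 * times[-1], times[-1])
    lo, hi = fit_window
    mask = (times >= lo) & (times <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window outside trajectory")
    t, y = times[mask], msd_curve[mask]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = ((y - pred) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pos = (t > 0) & (y > 0)
    if pos.sum() >= 2 and y[pos].max() > 0:
        alpha = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)[0]
    else:
        alpha = 0.0
    D = slope / 6.0
    return {
        "D_A2_per_fs": D,
        "D_cm2_per_s": D * 0.1,
        "slope": slope,
        "r_squared": r2,
        "fit_window_fs": (float(lo), float(hi)),
        "log_log_slope": float(alpha),
        "non_diffusive": bool(abs(alpha - 1.0) > 0.3) if slope != 0 else True,
    }


def rdf(trajectory: Trajectory, r_max: float = 6.0, bins: int = 100):
    """Pair-distance probability density over [0, r_max], all elements pooled.

    Normalized so the density integrates to 1 over the range (a probability
    density over observed pair distances, not the conventional g(r); see
    :func:`rdf_to_gr` for the conversion).
    """
    counts = np.zeros(bins)
    edges = np.linspace(0.0, r_max, bins + 1)
    pbc = [True] * 3 if trajectory.cell is not None else [False] * 3
    for frame in trajectory.positions:
        d = _pair_distances(frame, trajectory.species, trajectory.cell, pbc, r_max)
        h, _ = np.histogram(d, bins=edges)
        counts += h
    total = counts.sum()
    dr = edges[1] - edges[0]
    density = counts / (total * dr) if total > 0 else counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def _pair_distances(positions, species, cell, pbc, r_max):
    s = AtomicStructure(positions, species, cell=cell,
                        pbc=pbc if cell is not None else [False] * 3)
    g = build_neighbor_graph(s, r_max)
    if g.n_edges == 0:
        return np.zeros(0)
    # keep one orientation of every undirected pair (i<j, or i==j with
    # lexicographically positive image shift)
    first = np.zeros(g.n_edges, dtype=bool)
    for k in range(g.n_edges):
        if g.edge_i[k] < g.edge_j[k]:
            first[k] = True
        elif g.edge_i[k] == g.edge_j[k]:
            s_ = tuple(g.shifts[k])
            first[k] = s_ > (-s_[0], -s_[1], -s_[2])
    return g.distances[first]


def rdf_to_gr(centers, density, n_atoms, volume, n_pairs_per_frame=None):
    """Convenience transform of the probability density to conventional g(r)."""
    rho = n_atoms / volume
    shell = 4.0 * np.pi * centers**2 * (centers[1] - centers[0])
    # density integrates to 1; rescale to mean pair counts requires the total
    # pair count, supplied by the caller when known
    if n_pairs_per_frame is None:
        n_pairs_per_frame = n_atoms * (n_atoms - 1) / 2.0
    dr = centers[1] - centers[0]
    counts = density * dr * n_pairs_per_frame
    ideal = shell * rho * n_atoms / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ideal > 0, counts / ideal, 0.0)


def adf(trajectory: Trajectory, center_element: int, neighbor_element: int,
        cutoff: float = 2.5, bins: int = 90):
    """Bond-angle probability density over [0°, 180°].

    For every atom of the center element, the angle between each pair of
    neighbors of the neighbor element within the cutoff; normalized to
    integrate to 1 over the angular range.
    """
    if not (trajectory.species == center_element).any():
        raise ValueError(f"no atoms with Z={center_element}")
    if not (trajectory.species == neighbor_element).any():
        raise ValueError(f"no atoms with Z={neighbor_element}")
    counts = np.zeros(bins)
    edges = np.linspace(0.0, 180.0, bins + 1)
    pbc = [True] * 3 if trajectory.cell is not None else [False] * 3
    for frame in trajectory.positions:
        s = AtomicStructure(frame, trajectory.species, cell=trajectory.cell,
                            pbc=pbc if trajectory.cell is not None else [False] * 3)
        g = build_neighbor_graph(s, cutoff)
        for c in np.nonzero(trajectory.species == center_element)[0]:
            sel = (g.edge_i == c) & (trajectory.species[g.edge_j] == neighbor_element)
            vecs = g.vectors[sel]
            for a in range(len(vecs)):
                for b in range(a + 1, len(vecs)):
                    cosang = np.dot(vecs[a], vecs[b]) / (
                        np.linalg.norm(vecs[a]) * np.linalg.norm(vecs[b])
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    h = min(int(ang / 180.0 * bins), bins - 1)
                    counts[h] += 1
    total = counts.sum()
    dtheta = edges[1] - edges[0]
    density = counts / (total * dtheta) if total > 0 else counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
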