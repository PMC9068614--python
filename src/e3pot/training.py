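"""Loss, target normalization, optimizer, and the training loop.

The loss is a weighted sum of a squared energy error and a per-component
mean squared force error,

    L = lambda_E ||E_hat - E||^2
      + lambda_F * (1/3N) * sum_{i,alpha} ||-dE_hat/dr_{i,alpha} - F_{i,alpha}||^2,

averaged over the structures of a batch.  Because the force term contains
the gradient of the prediction, optimizing L requires differentiating
through the force computation (second-order gradients).

Targets are normalized before training: energies are shifted by the
training-set mean and both energies and force components are scaled by the
root mean square of the force components.  A per-species mode (for datasets
mixing structure sizes) instead initializes the learnable per-species shift
to the mean per-atom energy and the scale to the force-component standard
deviation, with no global target scaling.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .network import GraphBatch, ModelConfig, PotentialNetwork
from .structures import build_neighbor_graph

__all__ = [
    "LossWeights",
    "NormalizationStats",
    "TrainSchedule",
    "loss_terms",
    "fit_normalization",
    "AmsgradOptimizer",
    "train",
    "evaluate_metrics",
    "TrainResult",
]


@dataclass
class LossWeights:
    """Energy and force loss weights; optional per-element force weighting.

    ``per_element_force`` maps atomic number -> weight; the force term then
    averages the squared error within each element and combines elements by
    these weights (normalized), instead of the uniform 1/(3N) mean.
    """

    lambda_E: float = 1.0
    lambda_F: float = 1000.0
    per_element_force: Optional[dict] = None

    def __post_init__(self):
        if self.lambda_E < 0 or self.lambda_F < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_E == 0 and self.lambda_F == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class NormalizationStats:
    """Training-target normalization; stored with every checkpoint."""

    energy_mean: float = 0.0
    force_rms: float = 1.0
    mode: str = "global"          # "global" or "per_species"
    per_species_shift: float = 0.0
    per_species_scale: float = 1.0

    def normalize_energy(self, e):
        return (e - self.energy_mean) / self.force_rms

    def denormalize_energy(self, e):
        return e * self.force_rms + self.energy_mean

    def normalize_forces(self, f):
        return f / self.force_rms

    def denormalize_forces(self, f):
        return f * self.force_rms


def fit_normalization(train_set, mode: str = "global") -> NormalizationStats:
    """Normalization statistics from a labeled training set."""
    train_set = list(train_set)
    if not train_set:
        raise ValueError("training set is empty")
    energies = np.array([s.energy for s in train_set], dtype=float)
    if np.any(np.isnan(energies)):
        raise ValueError("training set misses energy labels")
    comps = np.concatenate([s.forces.ravel() for s in train_set])
    f_rms = float(np.sqrt((comps**2).mean()))
    if f_rms <= 0:
        raise ValueError("force components have zero RMS; cannot set the scale")
    if mode == "global":
        return NormalizationStats(energy_mean=float(energies.mean()), force_rms=f_rms)
    if mode == "per_species":
        per_atom = energies / np.array([s.n_atoms for s in train_set])
        return NormalizationStats(
            energy_mean=0.0, force_rms=1.0, mode="per_species",
            per_species_shift=float(per_atom.mean()),
            per_species_scale=float(comps.std()),
        )
    raise ValueError(f"unknown normalization mode {mode!r}")


@dataclass
class TrainSchedule:
    """Optimization schedule (defaults follow the molecular protocol)."""

    learning_rate: float = 0.01
    batch_size: int = 5
    lr_decay_factor: float = 0.8
    lr_patience: int = 50           # epochs without val force-loss improvement
    ema_decay: float = 0.99
    max_epochs: int = 1_000_000
    min_learning_rate: float = 1e-6
    early_stop_patience: int = 1000
    max_seconds: Optional[float] = None
    loss: LossWeights = field(default_factory=LossWeights)
    precision: str = "single"     # "single" (training default) or "double"

    def __post_init__(self):
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("decay factor must be in (0, 1)")
        if self.lr_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience must be positive")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")

    @classmethod
    def periodic(cls, **kw):
        kw.setdefault("learning_rate", 0.005)
        kw.setdefault("batch_size", 1)
        return cls(**kw)


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def loss_terms(pred_energies, pred_forces, target_energies, target_forces,
               species, atom_counts, weights: LossWeights):
    """Per-batch loss (mean over structures) on normalized quantities.

    ``pred_energies``: (n_structs,) Tensor; ``pred_forces``: (n_atoms, 3)
    Tensor for the concatenated batch; targets are numpy arrays in the same
    layout; ``species`` the concatenated atomic numbers; ``atom_counts`` the
    per-structure atom counts.
    """
    n_structs = len(atom_counts)
    total = None
    if weights.lambda_E > 0:
        if target_energies is None or np.any(np.isnan(target_energies)):
            raise ValueError("energy weight is nonzero but energy labels are missing")
        de = pred_energies - Tensor(target_energies)
        total = ad.tsum(de * de) * (weights.lambda_E / n_structs)
    if weights.lambda_F > 0:
        if target_forces is None:
            raise ValueError("force weight is nonzero but force labels are missing")
        df = pred_forces - Tensor(target_forces)
        sq = df * df
        if weights.per_element_force:
            w = weights.per_element_force
            norm = sum(w.values())
            term = None
            for z, wz in w.items():
                sel = np.nonzero(species == z)[0]
                if len(sel) == 0:
                    raise ValueError(f"per-element weight for absent element Z={z}")
                contrib = ad.tsum(ad.take(sq, sel)) * (wz / (3.0 * len(sel) * norm))
                term = contrib if term is None else term + contrib
        else:
            # structures may differ in size: apply 1/(3N) per structure
            inv = np.repeat(1.0 / (3.0 * np.asarray(atom_counts, float)),
                            atom_counts)
            term = ad.tsum(sq * inv[:, None]) * (1.0 / n_structs)
        term = term * weights.lambda_F
        total = term if total is None else total + term
    return total


# --------------------------------------------------------------------------
# optimizer: Adam with the maximum-of-second-moment (AMSGrad) variant
# --------------------------------------------------------------------------

class AmsgradOptimizer:
    """Adam/AMSGrad: beta1=0.9, beta2=0.999, eps=1e-8, no weight decay."""

    def __init__(self, params: dict, learning_rate: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = learning_rate
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.vhat = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.vhat[k] = np.maximum(self.vhat[k], self.v[k])
            mhat = self.m[k] / bc1
            vhat = self.vhat[k] / bc2
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return params


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: dict                  # best-validation EMA parameters
    stats: NormalizationStats
    log: list                     # one dict per epoch
    best_epoch: int
    best_val_force_loss: float
    stop_reason: str


def _batch_predict(net, batch, params_t, need_force_graph):
    pos = Tensor(batch.positions, requires_grad=True)
    e = net.energy(batch, pos, params_t)
    g = ad.grad(ad.tsum(e), pos, create_graph=need_force_graph)
    return e, -g


def _force_metrics(net, params, structures, graphs, stats, r_c):
    """Validation losses/MAEs (normalized-space loss, physical-space MAE)."""
    se_f, ae_f, n_f = 0.0, 0.0, 0
    se_e, ae_e, n_e = 0.0, 0.0, 0
    floss = 0.0
    params_t = {k: Tensor(v) for k, v in params.items()}
    batch = GraphBatch(structures, r_c, graphs=graphs)
    e, f = _batch_predict(net, batch, params_t, need_force_graph=False)
    off = 0
    for si, s in enumerate(structures):
        fs = f.data[off:off + s.n_atoms]
        off += s.n_atoms
        fe = fs - stats.normalize_forces(s.forces)
        floss += float((fe**2).mean())
        df_phys = stats.denormalize_forces(fs) - s.forces
        se_f += float((df_phys**2).sum())
        ae_f += float(np.abs(df_phys).sum())
        n_f += df_phys.size
        if s.energy is not None:
            de = stats.denormalize_energy(float(e.data[si])) - s.energy
            se_e += de * de
            ae_e += abs(de)
            n_e += 1
    out = {
        "val_force_loss": floss / max(len(structures), 1),
        "val_force_mae": ae_f / max(n_f, 1),
        "val_force_rmse": np.sqrt(se_f / max(n_f, 1)),
    }
    if n_e:
        out["val_energy_mae"] = ae_e / n_e
        out["val_energy_rmse"] = np.sqrt(se_e / n_e)
    return out


def train(train_set, val_set, config: ModelConfig, schedule: TrainSchedule,
          seed: int = 0, stats: Optional[NormalizationStats] = None,
          init_params: Optional[dict] = None, verbose: bool = False):
    """Train a network; returns the best-validation-force-loss EMA weights.

    Deterministic given the seed.  The learning rate decays by the schedule
    factor when the validation force loss plateaus; the exponential moving
    average of the weights is what gets validated and returned.
    """
    rng = np.random.default_rng(seed)
    if stats is None:
        stats = fit_normalization(train_set)
    net = PotentialNetwork(config)
    dtype = np.float32 if schedule.precision == "single" else np.float64
    params = init_params if init_params is not None else net.init_params(rng)
    params = {k: np.array(v, dtype=dtype) for k, v in params.items()}
    if stats.mode == "per_species":
        params["scale_shift.lambda"] = np.full(config.n_species,
                                               stats.per_species_shift, dtype=dtype)
        params["scale_shift.sigma"] = np.full(config.n_species,
                                              stats.per_species_scale, dtype=dtype)
    ema = {k: v.copy() for k, v in params.items()}
    opt = AmsgradOptimizer(params, schedule.learning_rate)

    train_graphs = [build_neighbor_graph(s, config.r_c) for s in train_set]
    val_graphs = [build_neighbor_graph(s, config.r_c) for s in val_set]
    norm_e = np.array([stats.normalize_energy(s.energy) if s.energy is not None
                       else np.nan for s in train_set])
    norm_f = [stats.normalize_forces(s.forces) for s in train_set]

    best = {"epoch": -1, "floss": np.inf, "params": None}
    log = []
    t0 = time.time()
    with ad.precision(dtype):
        result = _train_epochs(
            net, params, ema, opt, schedule, rng, train_set, val_set,
            train_graphs, val_graphs, norm_e, norm_f, stats, config,
            best, log, verbose, t0)
    result.params = {k: np.asarray(v, dtype=np.float64)
                     for k, v in result.params.items()}
    return result


def _train_epochs(net, params, ema, opt, schedule, rng, train_set, val_set,
                  train_graphs, val_graphs, norm_e, norm_f, stats, config,
                  best, log, verbose, t0):
    lr_wait, stop_wait = 0, 0
    stop_reason = "max_epochs"
    n_train = len(train_set)
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(n_train)
        train_loss = 0.0
        for start in range(0, n_train, schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            structs = [train_set[i] for i in idx]
            batch = GraphBatch(structs, config.r_c,
                               graphs=[train_graphs[i] for i in idx])
            params_t = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
            e, f = _batch_predict(net, batch, params_t,
                                  need_force_graph=schedule.loss.lambda_F > 0)
            L = loss_terms(
                e, f, norm_e[idx],
                np.concatenate([norm_f[i] for i in idx]),
                batch.species, batch.n_atoms_per_struct, schedule.loss,
            )
            if not np.isfinite(L.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            grads = ad.grad(L, list(params_t.values()))
            gdict = {k: g.data for k, g in zip(params_t.keys(), grads)}
            params = opt.step(params, gdict)
            d = schedule.ema_decay
            for k in ema:
                ema[k] = d * ema[k] + (1 - d) * params[k]
            train_loss += float(L.data) * len(idx)
        train_loss /= n_train

        vm = _force_metrics(net, ema, val_set, val_graphs, stats, config.r_c)
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": train_loss, **vm}
        log.append(row)
        if verbose and (epoch % 10 == 0 or epoch == schedule.max_epochs - 1):
            print(f"epoch {epoch:5d}  lr {opt.lr:.5f}  train {train_loss:.5f}  "
                  f"val F-MAE {vm['val_force_mae']:.5f}")

        floss = vm["val_force_loss"]
        if floss < best["floss"] - 1e-12:
            best = {"epoch": epoch, "floss": floss,
                    "params": {k: v.copy() for k, v in ema.items()}}
            lr_wait, stop_wait = 0, 0
        else:
            lr_wait += 1
            stop_wait += 1
        if lr_wait > schedule.lr_patience:
            opt.lr *= schedule.lr_decay_factor
            lr_wait = 0
        if opt.lr < schedule.min_learning_rate:
            stop_reason = "learning_rate_floor"
            break
        if stop_wait > schedule.early_stop_patience:
            stop_reason = "validation_patience"
            break
        if schedule.max_seconds is not None and time.time() - t0 > schedule.max_seconds:
            stop_reason = "max_time"
            break
    if best["params"] is None:
        best = {"epoch": len(log) - 1, "floss": np.inf, "params": ema}
    return TrainResult(
        params=best["params"], stats=stats, log=log,
        best_epoch=best["epoch"], best_val_force_loss=best["floss"],
        stop_reason=stop_reason,
    )


# --------------------------------------------------------------------------
# evaluation metrics
# --------------------------------------------------------------------------

def evaluate_metrics(net: PotentialNetwork, params: dict,
                     stats: NormalizationStats, structures,
                     per_element: bool = False) -> dict:
    """Test-set MAE/RMSE in meV, meV/atom and meV/Å (physical units)."""
    params_t = {k: Tensor(v) for k, v in params.items()}
    e_err, e_err_per_atom, f_err = [], [], []
    species_all = []
    for s in structures:
        batch = GraphBatch([s], net.config.r_c)
        e, f = _batch_predict(net, batch, params_t, need_force_graph=False)
        e_phys = stats.denormalize_energy(float(e.data[0]))
        f_phys = stats.denormalize_forces(f.data)
        if s.energy is not None:
            e_err.append(e_phys - s.energy)
            e_err_per_atom.append((e_phys - s.energy) / s.n_atoms)
        if s.forces is not None:
            f_err.append((f_phys - s.forces).ravel())
            species_all.append(np.repeat(s.species, 3))
    out = {}
    if e_err:
        e_err = np.array(e_err) * 1000.0
        epa = np.array(e_err_per_atom) * 1000.0
        out["energy_mae_meV"] = float(np.abs(e_err).mean())
        out["energy_rmse_meV"] = float(np.sqrt((e_err**2).mean()))
        out["energy_mae_meV_per_atom"] = float(np.abs(epa).mean())
    if f_err:
        f_err = np.concatenate(f_err) * 1000.0
        species_all = np.concatenate(species_all)
        out["force_mae_meV_per_A"] = float(np.abs(f_err).mean())
        out["force_rmse_meV_per_A"] = float(np.sqrt((f_err**2).mean()))
        if per_element:
            for z in np.unique(species_all):
                sel = species_all == z
                out[f"force_mae_meV_per_A_Z{z}"] = float(np.abs(f_err[sel]).mean())
    return out
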