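"""High-level modelling interface: a potential model fitted to labeled data.

Follows the model/results split familiar from statistical modelling
libraries: :class:`InteratomicPotential` holds the data and the architecture
configuration; :meth:`InteratomicPotential.fit` runs the training protocol
and returns a :class:`PotentialFit` carrying the fitted parameters, the
training log, evaluation methods, a ``summary()`` table, and MD simulation.

Example
-------
>>> from e3pot import InteratomicPotential, toydata
>>> frames = toydata.sample_dataset(toydata.simple_cubic_structure(), 200,
...                                 displacement=0.15, seed=7)
>>> model = InteratomicPotential(frames, l_max=1, num_features=16,
...                              num_layers=2, r_c=4.0)
>>> fit = model.fit(max_epochs=100, seed=0)
>>> result = fit.predict(frames[0])        # energy (eV), forces (eV/Å)
>>> print(fit.summary())
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .dynamics import ThermostatParams, Trajectory, run_nvt
from .network import EnergyForceResult, GraphBatch, ModelConfig, PotentialNetwork
from .structures import AtomicStructure, average_num_neighbors, read_extxyz
from .training import (
    LossWeights,
    NormalizationStats,
    TrainResult,
    TrainSchedule,
    evaluate_metrics,
    fit_normalization,
    train,
)

__all__ = ["InteratomicPotential", "PotentialFit"]


class InteratomicPotential:
    """An E(3)-equivariant potential-energy model over labeled configurations.

    Parameters
    ----------
    structures : list of AtomicStructure
        Labeled configurations (energy in eV, forces in eV/Å).
    config : ModelConfig, optional
        Full architecture configuration; keyword arguments (``l_max``,
        ``num_features``, ``num_layers``, ``r_c`` ...) may be given instead.
        The species list defaults to the elements present in the data, and
        the average neighbor count used by the convolution normalization is
        computed from the data and frozen unless supplied.
    normalization : str
        ``"global"`` (energy mean / force RMS scaling) or ``"per_species"``
        (per-species shift and scale initialization, no global scaling; for
        datasets mixing structure sizes).
    """

    def __init__(self, structures, config: Optional[ModelConfig] = None,
                 normalization: str = "global", **config_kwargs):
        self.structures = list(structures)
        if not self.structures:
            raise ValueError("no structures given")
        if config is None:
            kw = dict(config_kwargs)
            if "species" not in kw:
                kw["species"] = sorted(
                    {int(z) for s in self.structures for z in s.species}
                )
            if "avg_num_neighbors" not in kw:
                r_c = kw.get("r_c", 4.0)
                kw["avg_num_neighbors"] = max(
                    average_num_neighbors(self.structures, r_c), 1e-6
                )
            config = ModelConfig(**kw)
        elif config_kwargs:
            raise ValueError("give either a config object or keyword arguments")
        self.config = config
        self.normalization = normalization

    @classmethod
    def from_extxyz(cls, path, **kwargs) -> "InteratomicPotential":
        return cls(read_extxyz(path), **kwargs)

    def fit(self, schedule: Optional[TrainSchedule] = None, seed: int = 0,
            validation_fraction: float = 0.1,
            validation_set=None, verbose: bool = False,
            **schedule_kwargs) -> "PotentialFit":
        """Train and return the fitted results object.

        The train/validation split is sampled uniformly without replacement
        with the given seed (unless an explicit validation set is passed);
        the returned parameters are the exponential-moving-average weights
        of the epoch with the best validation force loss.
        """
        if schedule is None:
            loss_kw = {}
            for k in ("lambda_E", "lambda_F", "per_element_force"):
                if k in schedule_kwargs:
                    loss_kw[k] = schedule_kwargs.pop(k)
            if loss_kw:
                schedule_kwargs["loss"] = LossWeights(**loss_kw)
            schedule = TrainSchedule(**schedule_kwargs)
        elif schedule_kwargs:
            raise ValueError("give either a schedule object or keyword arguments")
        rng = np.random.default_rng(seed)
        if validation_set is None:
            n = len(self.structures)
            n_val = max(1, int(round(validation_fraction * n)))
            if n_val >= n:
                raise ValueError("validation split leaves no training data")
            val_idx = set(rng.choice(n, size=n_val, replace=False).tolist())
            train_set = [s for i, s in enumerate(self.structures) if i not in val_idx]
            val_set = [self.structures[i] for i in sorted(val_idx)]
            split = {"train": [i for i in range(n) if i not in val_idx],
                     "validation": sorted(val_idx)}
        else:
            train_set, val_set = self.structures, list(validation_set)
            split = None
        stats = fit_normalization(train_set, mode=self.normalization)
        result = train(train_set, val_set, self.config, schedule,
                       seed=seed, stats=stats, verbose=verbose)
        return PotentialFit(self, result, schedule, seed, split)


class PotentialFit:
    """Results of fitting an :class:`InteratomicPotential`."""

    def __init__(self, model: InteratomicPotential, result: TrainResult,
                 schedule: TrainSchedule, seed: int, split):
        self.model = model
        self.network = PotentialNetwork(model.config)
        self.params = result.params
        self.stats = result.stats
        self.log = result.log
        self.best_epoch = result.best_epoch
        self.best_val_force_loss = result.best_val_force_loss
        self.stop_reason = result.stop_reason
        self.schedule = schedule
        self.seed = seed
        self.split = split

    # ---- prediction -----------------------------------------------------
    def predict(self, structure: AtomicStructure) -> EnergyForceResult:
        """Energy (eV), per-atom energies (eV) and forces (eV/Å)."""
        from . import autodiff as ad
        from .autodiff import Tensor

        batch = GraphBatch([structure], self.model.config.r_c)
        pos = Tensor(batch.positions, requires_grad=True)
        params_t = {k: Tensor(v) for k, v in self.params.items()}
        e = self.network.energy(batch, pos, params_t)
        g = ad.grad(ad.tsum(e), pos)
        energy = self.stats.denormalize_energy(float(e.data[0]))
        forces = self.stats.denormalize_forces(-g.data)
        # per-atom energies share the structure-constant shift equally
        e_atom_norm = self._atomic_energies(batch, params_t)
        e_atom = e_atom_norm * self.stats.force_rms + \
            (self.stats.energy_mean / structure.n_atoms)
        return EnergyForceResult(energy=energy, atomic_energies=e_atom, forces=forces)

    def _atomic_energies(self, batch, params_t):
        from .autodiff import Tensor

        pos = Tensor(batch.positions)
        saved = batch.structure_index
        batch.structure_index = np.arange(batch.n_atoms)
        n_saved = batch.n_structs
        batch.n_structs = batch.n_atoms
        try:
            e = self.network.energy(batch, pos, params_t)
        finally:
            batch.structure_index = saved
            batch.n_structs = n_saved
        return e.data

    def __call__(self, structure):
        """Force-field interface for the MD driver: (energy, forces)."""
        r = self.predict(structure)
        return r.energy, r.forces

    # ---- evaluation ------------------------------------------------------
    def evaluate(self, structures, per_element: bool = False) -> dict:
        """MAE/RMSE on a labeled test set (meV, meV/atom, meV/Å)."""
        return evaluate_metrics(self.network, self.params, self.stats,
                                structures, per_element=per_element)

    # ---- simulation ------------------------------------------------------
    def simulate(self, start: AtomicStructure, temperature: float, dt: float,
                 n_steps: int, thermostat: Optional[ThermostatParams] = None,
                 nvt: bool = True, tau_fs: float = 50.0, seed: int = 0,
                 sample_every: int = 1) -> Trajectory:
        """Molecular dynamics driven by the fitted potential (NVT or NVE)."""
        if nvt and thermostat is None:
            thermostat = ThermostatParams.with_tau(temperature, start.n_atoms, tau_fs)
        if not nvt:
            thermostat = None
        return run_nvt(self, start, temperature, dt, n_steps,
                       thermostat=thermostat, seed=seed, sample_every=sample_every)

    # ---- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(np.asarray(v).size for v in self.params.values())
        lines = [
            "Equivariant interatomic potential - fit results",
            "=" * 51,
            f"{'species':<28}{cfg.species}",
            f"{'l_max':<28}{cfg.l_max}",
            f"{'feature multiplicity':<28}{cfg.num_features}",
            f"{'interaction blocks':<28}{cfg.num_layers}",
            f"{'cutoff radius (A)':<28}{cfg.r_c}",
            f"{'avg. neighbors (frozen)':<28}{cfg.avg_num_neighbors:.3f}",
            f"{'parameters':<28}{n_params}",
            f"{'training structures':<28}{len(self.model.structures)}",
            f"{'epochs run':<28}{len(self.log)}",
            f"{'best epoch (val F loss)':<28}{self.best_epoch}",
            f"{'stop reason':<28}{self.stop_reason}",
        ]
        if self.log:
            last = self.log[-1]
            best = min(self.log, key=lambda r: r["val_force_loss"])
            lines += [
                f"{'final lr':<28}{last['lr']:.2e}",
                f"{'best val force MAE':<28}"
                f"{best['val_force_mae'] * 1000:.2f} meV/A",
            ]
            if "val_energy_mae" in best:
                lines.append(
                    f"{'best val energy MAE':<28}{best['val_energy_mae'] * 1000:.2f} meV"
                )
        return "\n".join(lines)

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Versioned checkpoint: config, parameters, normalization, log."""
        extra = {
            "stats": vars(self.stats),
            "schedule": _schedule_dict(self.schedule),
            "seed": self.seed,
            "split": self.split,
            "log": self.log,
            "best_epoch": self.best_epoch,
            "stop_reason": self.stop_reason,
        }
        self.network.save_checkpoint(path, self.params, extra=extra)

    @classmethod
    def load(cls, path) -> "PotentialFit":
        net, params, extra = PotentialNetwork.load_checkpoint(path)
        stats = NormalizationStats(**extra["stats"])
        sched_d = dict(extra.get("schedule", {}))
        loss_d = sched_d.pop("loss", None)
        schedule = TrainSchedule(**sched_d) if sched_d else TrainSchedule()
        if loss_d:
            pe = loss_d.get("per_element_force")
            schedule.loss = LossWeights(
                lambda_E=loss_d["lambda_E"], lambda_F=loss_d["lambda_F"],
                per_element_force={int(k): v for k, v in pe.items()} if pe else None,
            )
        model = InteratomicPotential.__new__(InteratomicPotential)
        model.structures = []
        model.config = net.config
        model.normalization = stats.mode
        result = TrainResult(
            params=params, stats=stats, log=extra.get("log", []),
            best_epoch=extra.get("best_epoch", -1),
            best_val_force_loss=np.nan,
            stop_reason=extra.get("stop_reason", "loaded"),
        )
        fit = cls(model, result, schedule, extra.get("seed", 0), extra.get("split"))
        return fit


def _schedule_dict(schedule: TrainSchedule) -> dict:
    d = dict(vars(schedule))
    d["loss"] = dict(vars(schedule.loss))
    return d
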