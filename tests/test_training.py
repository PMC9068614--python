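"""Loss arithmetic, normalization, optimizer schedule, and training loop."""

import numpy as np
import pytest

from e3pot import toydata
from e3pot.autodiff import Tensor
from e3pot.model import InteratomicPotential
from e3pot.structures import AtomicStructure
from e3pot.training import (
    AmsgradOptimizer,
    LossWeights,
    TrainSchedule,
    evaluate_metrics,
    fit_normalization,
    loss_terms,
)


def _loss_val(pe, pf, te, tf, species, counts, w):
    return float(loss_terms(Tensor(np.atleast_1d(pe)), Tensor(pf),
                            np.atleast_1d(te), tf, np.asarray(species),
                            np.asarray(counts), w).data)


def test_perfect_prediction_gives_zero_loss():
    f = np.zeros((2, 3))
    assert _loss_val(1.0, f, 1.0, f, [1, 1], [2], LossWeights(1.0, 10.0)) == 0.0


def test_loss_arithmetic_matches_hand_computation():
    """N=2, lambda_E=1, lambda_F=4, energy error 0.5, one force component
    error 0.1: 0.25 + 4*(1/6)*0.01 = 0.25666..."""
    pf = np.zeros((2, 3))
    tf = np.zeros((2, 3))
    pf[0, 0] = 0.1
    val = _loss_val(1.5, pf, 1.0, tf, [1, 1], [2], LossWeights(1.0, 4.0))
    assert np.isclose(val, 0.25 + 4.0 / 6.0 * 0.01, atol=1e-12)


def test_energy_weight_zero_ignores_constant_offsets():
    pf = np.zeros((3, 3))
    w = LossWeights(0.0, 1.0)
    v1 = _loss_val(5.0, pf, 0.0, pf, [1] * 3, [3], w)
    v2 = _loss_val(-7.0, pf, 0.0, pf, [1] * 3, [3], w)
    assert v1 == v2 == 0.0


def test_per_element_weighting_recovers_uniform_when_equal():
    rng = np.random.default_rng(0)
    species = np.array([1, 1, 8, 8])
    pf = rng.normal(size=(4, 3))
    tf = np.zeros((4, 3))
    uniform = _loss_val(0, pf, 0, tf, species, [4], LossWeights(0.0, 1.0))
    per_el = _loss_val(0, pf, 0, tf, species, [4],
                       LossWeights(0.0, 1.0, per_element_force={1: 1.0, 8: 1.0}))
    # equal atom counts per element: the weighted mean equals the global mean
    assert np.isclose(per_el, uniform, atol=1e-12)


def test_loss_requires_labels_for_nonzero_weights():
    pf = np.zeros((1, 3))
    with pytest.raises(ValueError):
        _loss_val(np.nan, pf, np.nan, pf, [1], [1], LossWeights(1.0, 0.0))
    with pytest.raises(ValueError):
        loss_terms(Tensor(np.zeros(1)), Tensor(pf), np.zeros(1), None,
                   np.array([1]), np.array([1]), LossWeights(0.0, 1.0))


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def _frames_with(energies, forces_scale, rng):
    out = []
    for e in energies:
        f = rng.normal(scale=forces_scale, size=(3, 3))
        out.append(AtomicStructure(rng.normal(size=(3, 3)) * 3, [1, 1, 1],
                                   energy=e, forces=f))
    return out


def test_normalization_centers_energies(rng):
    frames = _frames_with([2.0, 2.0, 2.0], 1.0, rng)
    stats = fit_normalization(frames)
    assert stats.energy_mean == 2.0
    assert np.allclose([stats.normalize_energy(s.energy) for s in frames], 0.0)


def test_normalization_roundtrip(rng):
    frames = _frames_with([1.0, -3.0, 0.5], 2.0, rng)
    stats = fit_normalization(frames)
    for e in (-1.7, 0.0, 4.2):
        assert np.isclose(stats.denormalize_energy(stats.normalize_energy(e)), e)
    f = rng.normal(size=(3, 3))
    assert np.allclose(stats.denormalize_forces(stats.normalize_forces(f)), f)


def test_normalization_rejects_zero_force_scale(rng):
    frames = _frames_with([1.0], 1.0, rng)
    frames[0].forces = np.zeros((3, 3))
    with pytest.raises(ValueError, match="zero RMS"):
        fit_normalization(frames)


def test_per_species_mode_uses_per_atom_energy(rng):
    frames = _frames_with([3.0, 3.0], 1.0, rng)
    stats = fit_normalization(frames, mode="per_species")
    assert stats.mode == "per_species"
    assert np.isclose(stats.per_species_shift, 1.0)   # 3 eV over 3 atoms
    assert stats.force_rms == 1.0                     # no global scaling
    assert stats.energy_mean == 0.0


# --------------------------------------------------------------------------
# optimizer and schedule arithmetic
# --------------------------------------------------------------------------

def test_amsgrad_first_step_is_learning_rate_sized():
    params = {"w": np.array([1.0])}
    opt = AmsgradOptimizer(params, learning_rate=0.01)
    out = opt.step(params, {"w": np.array([100.0])})
    # mhat/sqrt(vhat) == 1 on the first step regardless of gradient scale
    assert np.isclose(out["w"][0], 1.0 - 0.01, atol=1e-6)


def test_amsgrad_second_moment_never_decreases():
    params = {"w": np.array([0.0])}
    opt = AmsgradOptimizer(params, learning_rate=0.1)
    opt.step(params, {"w": np.array([10.0])})
    vhat_big = opt.vhat["w"].copy()
    opt.step(params, {"w": np.array([0.001])})
    assert opt.vhat["w"][0] >= vhat_big[0]


def test_schedule_validation():
    with pytest.raises(ValueError):
        TrainSchedule(lr_decay_factor=1.5)
    with pytest.raises(ValueError):
        LossWeights(0.0, 0.0)
    assert TrainSchedule.periodic().learning_rate == 0.005
    assert TrainSchedule.periodic().batch_size == 1


def test_two_plateau_decays_multiply():
    """LR after two consecutive plateaus: 0.01 * 0.8^2 = 0.0064."""
    lr = 0.01
    for _ in range(2):
        lr *= TrainSchedule().lr_decay_factor
    assert np.isclose(lr, 0.0064)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def test_evaluate_metrics_match_hand_computed_errors(tiny_dataset):
    """evaluate() must agree with MAE/RMSE computed by hand from predict(),
    including the eV -> meV conversions and per-element selection.  A frame
    whose labels are overwritten with the model's own predictions scores
    exactly zero; shifting one force component by 0.3 eV/Å on a 2-atom
    frame gives MAE 100 meV/Å and RMSE ~173.2 meV/Å."""
    model = InteratomicPotential(tiny_dataset, l_max=0, num_features=4,
                                 num_layers=1, r_c=3.5)
    fit = model.fit(max_epochs=1, batch_size=5, seed=3)
    test = [s.copy() for s in tiny_dataset[:3]]
    preds = [fit.predict(s) for s in test]
    for s, p in zip(test, preds):
        s.energy = p.energy
        s.forces = p.forces.copy()
    m0 = fit.evaluate(test, per_element=True)
    assert m0["energy_mae_meV"] < 1e-9
    assert m0["force_mae_meV_per_A"] < 1e-9
    # two-atom frame with a single +0.3 / -0.3 eV/Å error pattern
    two = AtomicStructure(np.array([[0.0, 0, 0], [2.2, 0, 0]]), [18, 18])
    p = fit.predict(two)
    two.energy = p.energy
    two.forces = p.forces.copy()
    two.forces[0, 0] -= 0.3
    two.forces[1, 0] += 0.3
    m = fit.evaluate([two])
    assert np.isclose(m["force_mae_meV_per_A"], 100.0, atol=1e-6)
    assert np.isclose(m["force_rmse_meV_per_A"], 1000 * 0.3 / np.sqrt(3), atol=1e-6)


# --------------------------------------------------------------------------
# training loop behaviour (tiny runs)
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_dataset():
    tpl = toydata.simple_cubic_structure()
    return toydata.sample_dataset(tpl, 14, displacement=0.12, seed=9)


def test_training_is_deterministic_given_seed(tiny_dataset):
    logs = []
    for _ in range(2):
        model = InteratomicPotential(tiny_dataset, l_max=0, num_features=4,
                                     num_layers=1, r_c=3.5)
        fit = model.fit(max_epochs=2, batch_size=5, seed=7)
        logs.append(fit.log)
    assert logs[0] == logs[1]


def test_training_decreases_loss_and_selects_best(tiny_dataset):
    model = InteratomicPotential(tiny_dataset, l_max=0, num_features=4,
                                 num_layers=1, r_c=3.5)
    fit = model.fit(max_epochs=8, batch_size=5, seed=1)
    losses = [r["train_loss"] for r in fit.log]
    assert losses[-1] < losses[0]
    flosses = [r["val_force_loss"] for r in fit.log]
    assert fit.best_epoch == int(np.argmin(flosses))
    assert fit.summary()  # renders without error


def test_student_learns_representable_teacher_labels(tiny_dataset):
    """Labels produced by another instance of the same architecture are
    exactly representable, so the validation force loss must fall well below
    its starting value."""
    from e3pot.network import ModelConfig, PotentialNetwork

    cfg = ModelConfig(species=[18], l_max=0, num_features=4, num_layers=1,
                      r_c=3.5, avg_num_neighbors=10.0)
    teacher = PotentialNetwork(cfg)
    tparams = teacher.init_params(np.random.default_rng(77))
    frames = []
    for s in tiny_dataset:
        f = s.copy()
        e, forces = teacher.energy_forces_raw(f, tparams)
        f.energy, f.forces = 3.0 * e, 3.0 * forces
        frames.append(f)
    model = InteratomicPotential(frames, config=cfg)
    fit = model.fit(max_epochs=40, batch_size=5, seed=5)
    flosses = [r["val_force_loss"] for r in fit.log]
    assert min(flosses) < 0.2 * flosses[0]


def test_fit_checkpoint_roundtrip(tiny_dataset, tmp_path):
    from e3pot.model import PotentialFit

    model = InteratomicPotential(tiny_dataset, l_max=0, num_features=4,
                                 num_layers=1, r_c=3.5)
    fit = model.fit(max_epochs=2, batch_size=5, seed=1)
    r0 = fit.predict(tiny_dataset[0])
    path = tmp_path / "fit.ckpt"
    fit.save(path)
    fit2 = PotentialFit.load(path)
    r1 = fit2.predict(tiny_dataset[0])
    assert np.isclose(r0.energy, r1.energy)
    assert np.allclose(r0.forces, r1.forces)
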