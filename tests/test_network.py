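"""Symmetry and gradient contracts of the full potential network."""

import numpy as np
import pytest

from e3pot import autodiff as ad
from e3pot.autodiff import Tensor
from e3pot.irreps import IrrepsSignature, EquivariantArray, random_rotation
from e3pot.network import GraphBatch, ModelConfig, PotentialNetwork
from e3pot.structures import AtomicStructure

RNG = np.random.default_rng(5)


def make_net(l_max=1, num_features=8, num_layers=2, species=(1, 8), r_c=4.0,
             avg_n=5.0, seed=0):
    cfg = ModelConfig(species=list(species), l_max=l_max,
                      num_features=num_features, num_layers=num_layers,
                      r_c=r_c, avg_num_neighbors=avg_n)
    net = PotentialNetwork(cfg)
    return net, net.init_params(np.random.default_rng(seed))


def cluster(n=6, seed=3, spread=1.8):
    rng = np.random.default_rng(seed)
    while True:
        pos = rng.normal(size=(n, 3)) * spread
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        if d[np.triu_indices(n, 1)].min() > 1.0:
            return pos


# --------------------------------------------------------------------------
# embedding
# --------------------------------------------------------------------------

def test_embedding_same_species_same_features():
    net, params = make_net()
    s = AtomicStructure(cluster(), np.array([1, 1, 8, 1, 8, 1]))
    batch = GraphBatch([s], 4.0)
    onehot_feat = {}
    species_idx = net.species_index(batch.species)
    onehot = np.zeros((batch.n_atoms, net.config.n_species))
    onehot[np.arange(batch.n_atoms), species_idx] = 1.0
    feat = (onehot @ params["embed.W"]) / np.sqrt(net.config.n_species) \
        + params["embed.b"]
    assert np.allclose(feat[0], feat[1])
    assert not np.allclose(feat[0], feat[2])


def test_unknown_species_rejected():
    net, params = make_net(species=(1, 8))
    s = AtomicStructure([[0, 0, 0]], [79])
    with pytest.raises(ValueError, match="unknown species"):
        net.energy_forces_raw(s, params)


# --------------------------------------------------------------------------
# convolution
# --------------------------------------------------------------------------

def test_isolated_atoms_receive_zero_messages():
    """No neighbors -> empty sum -> the convolution output is zero, and the
    per-atom energy reduces to the embedding-only path."""
    net, params = make_net()
    far = AtomicStructure([[0, 0, 0], [100.0, 0, 0]], [1, 1])
    e, f = net.energy_forces_raw(far, params)
    single = AtomicStructure([[0, 0, 0]], [1])
    e1, _ = net.energy_forces_raw(single, params)
    assert np.isclose(e, 2 * e1, atol=1e-12)
    assert np.allclose(f, 0.0, atol=1e-12)


def test_interaction_block_equivariance():
    """Internal feature fields transform with the Wigner matrices under O(3)."""
    net, params = make_net(l_max=2, num_layers=2)
    params_t = {k: Tensor(v) for k, v in params.items()}
    pos = cluster()
    Z = np.array([1, 1, 8, 1, 8, 1])

    def features_after_blocks(p):
        s = AtomicStructure(p, Z)
        batch = GraphBatch([s], net.config.r_c)
        species_idx = net.species_index(batch.species)
        vec = ad.take(Tensor(p), batch.edge_j) - ad.take(Tensor(p), batch.edge_i) \
            + Tensor(batch.shift_vectors)
        length = ad.tsum(vec * vec, axis=1) ** 0.5
        onehot = np.zeros((batch.n_atoms, net.config.n_species))
        onehot[np.arange(batch.n_atoms), species_idx] = 1.0
        feat = ad.matmul(Tensor(onehot), params_t["embed.W"]) \
            * (1.0 / np.sqrt(net.config.n_species)) + params_t["embed.b"]
        x = EquivariantArray(net.sig_embed, feat)
        for block in net.blocks:
            x = block.apply(x, batch, vec, length, species_idx, params_t)
        return EquivariantArray(x.signature, x.values.data)

    x0 = features_after_blocks(pos)
    for improper in (False, True):
        R = random_rotation(RNG, improper=improper)
        xr = features_after_blocks(pos @ R.matrix.T)
        expected = x0.rotate(R)
        assert np.allclose(xr.values, expected.values, atol=1e-10)


# --------------------------------------------------------------------------
# full model: invariances, forces, locality, ablation
# --------------------------------------------------------------------------

@pytest.mark.parametrize("l_max", [0, 1, 2])
def test_energy_invariant_forces_equivariant(l_max):
    net, params = make_net(l_max=l_max)
    pos = cluster(seed=l_max + 10)
    Z = np.array([1, 1, 8, 1, 8, 1])
    e0, f0 = net.energy_forces_raw(AtomicStructure(pos, Z), params)
    for improper in (False, True):
        R = random_rotation(RNG, improper=improper)
        e1, f1 = net.energy_forces_raw(AtomicStructure(pos @ R.matrix.T, Z), params)
        assert np.isclose(e1, e0, atol=1e-10)
        assert np.allclose(f1, f0 @ R.matrix.T, atol=1e-10)


def test_translation_and_permutation_invariance():
    net, params = make_net()
    pos = cluster(seed=21)
    Z = np.array([1, 1, 8, 1, 8, 1])
    e0, f0 = net.energy_forces_raw(AtomicStructure(pos, Z), params)
    e1, f1 = net.energy_forces_raw(AtomicStructure(pos + 7.3, Z), params)
    assert np.isclose(e1, e0, atol=1e-12)
    assert np.allclose(f1, f0, atol=1e-12)
    perm = np.random.default_rng(0).permutation(6)
    e2, f2 = net.energy_forces_raw(AtomicStructure(pos[perm], Z[perm]), params)
    assert np.isclose(e2, e0, atol=1e-12)
    assert np.allclose(f2, f0[perm], atol=1e-12)


def test_net_force_is_zero_on_isolated_system():
    net, params = make_net()
    pos = cluster(seed=33)
    _, f = net.energy_forces_raw(AtomicStructure(pos, np.array([1, 1, 8, 1, 8, 1])),
                                 params)
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)


def test_forces_match_finite_differences():
    net, params = make_net(l_max=1)
    pos = cluster(n=6, seed=4)
    Z = np.array([1, 8, 1, 1, 8, 1])
    s = AtomicStructure(pos, Z)
    e0, f0 = net.energy_forces_raw(s, params)
    eps = 1e-4
    scale = np.abs(f0).max()
    for i in range(3):
        for a in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, a] += eps
            pm[i, a] -= eps
            ep, _ = net.energy_forces_raw(AtomicStructure(pp, Z), params)
            em, _ = net.energy_forces_raw(AtomicStructure(pm, Z), params)
            assert abs(-(ep - em) / (2 * eps) - f0[i, a]) / scale < 1e-6


def test_locality_beyond_receptive_field():
    """An atom farther than num_layers * r_c cannot influence another's energy."""
    net, params = make_net(num_layers=2, r_c=3.0)
    base = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    far1 = np.vstack([base, [[20.0, 0, 0]]])
    far2 = np.vstack([base, [[25.0, 0, 0]]])
    Z3 = np.array([1, 8, 1])
    e1, _ = net.energy_forces_raw(AtomicStructure(far1, Z3), params)
    e2, _ = net.energy_forces_raw(AtomicStructure(far2, Z3), params)
    assert e1 == e2


def test_lmax0_network_is_purely_scalar():
    """The equivariance ablation is a config switch: with l_max=0 every
    hidden segment is an l=0 irrep."""
    net, _ = make_net(l_max=0, num_layers=2)
    for block in net.blocks:
        for _, ir in block.sig_out.segments:
            assert ir.l == 0


def test_zero_separation_pair_rejected():
    net, params = make_net()
    s = AtomicStructure([[0, 0, 0], [0, 0, 0]], [1, 1])
    with pytest.raises(ValueError, match="zero separation"):
        net.energy_forces_raw(s, params)


def test_checkpoint_roundtrip(tmp_path):
    net, params = make_net()
    s = AtomicStructure(cluster(seed=8), np.array([1, 1, 8, 1, 8, 1]))
    e0, f0 = net.energy_forces_raw(s, params)
    path = tmp_path / "model.ckpt"
    net.save_checkpoint(path, params, extra={"note": "test"})
    net2, params2, extra = PotentialNetwork.load_checkpoint(path)
    e1, f1 = net2.energy_forces_raw(s, params2)
    assert np.isclose(e0, e1)
    assert np.allclose(f0, f1)
    assert extra["note"] == "test"


def test_gate_requires_scalars_for_nonscalar_channels():
    """Gate construction allocates one even-scalar gate per l>0 channel."""
    from e3pot.network import Gate

    sig = IrrepsSignature([(4, "0e"), (3, "1o")])
    gate = Gate(sig)
    assert gate.sig_pre.dim == 4 + 3 + 3 * 3
    x = EquivariantArray(gate.sig_pre, Tensor(RNG.normal(size=(2, gate.sig_pre.dim))))
    out = gate.apply(x)
    assert out.signature == sig


def test_gate_scalar_activations():
    """Even scalars -> SiLU, odd scalars -> tanh, vectors rescaled not rotated."""
    from e3pot.network import Gate

    sig = IrrepsSignature([(2, "0e"), (2, "0o"), (1, "1o")])
    gate = Gate(sig)
    vals = RNG.normal(size=(1, gate.sig_pre.dim))
    out = gate.apply(EquivariantArray(gate.sig_pre, Tensor(vals))).values.data
    x = vals[0]
    silu = lambda v: v / (1 + np.exp(-v))
    assert np.allclose(out[0, :2], silu(x[:2]))          # even scalars
    assert np.allclose(out[0, 2:4], np.tanh(x[2:4]))     # odd scalars
    vec_in, g = x[5:8], x[4]
    vec_out = out[0, 4:7]
    cosang = np.dot(vec_in, vec_out) / (
        np.linalg.norm(vec_in) * np.linalg.norm(vec_out))
    assert np.isclose(abs(cosang), 1.0)                  # direction preserved
    assert np.allclose(vec_out, vec_in * silu(g))
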