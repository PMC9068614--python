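"""The E(3)-equivariant message-passing potential network.

Architecture: a species embedding (one-hot -> even scalars), a stack of
interaction blocks, and an output block producing one scalar per atom.  Each
interaction block runs

    self-interaction -> convolution -> self-interaction
    -> per-species residual add -> gate nonlinearity

where the convolution couples neighbor features with spherical-harmonic
filters through Clebsch-Gordan tensor products; every learnable filter weight
comes from a radial MLP on the Bessel embedding of the interatomic distance,
so messages vanish smoothly at the cutoff.  Per-atom scalars are scaled and
shifted per species and summed into the total energy; forces are the exact
negative gradient of that energy, obtained by differentiating through the
whole computational graph including the edge vectors.

Setting ``l_max = 0`` turns the same code into an invariant (scalar-feature)
network - the equivariance ablation is a configuration switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .irreps import (
    EquivariantArray,
    Irrep,
    IrrepsSignature,
    enumerate_paths,
    spherical_harmonics_tensor,
    tensor_product_output_signature,
    weighted_tensor_product,
)
from .radial import BesselBasis, RadialMLP
from .structures import AtomicStructure, build_neighbor_graph

__all__ = ["ModelConfig", "EnergyForceResult", "PotentialNetwork", "GraphBatch"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``num_features`` is the multiplicity of every (l, p) irrep kept in the
    hidden features; with ``parity=True`` and ``l_max=1`` a value of 32 means
    32x0e + 32x0o + 32x1o + 32x1e.  ``avg_num_neighbors`` is the dataset
    statistic used for the 1/sqrt(N) convolution normalization; it is
    computed once on the training set and frozen here.
    """

    species: list = field(default_factory=lambda: [1])
    l_max: int = 2
    num_features: int = 32
    num_layers: int = 5
    r_c: float = 4.0
    n_basis: int = 8
    envelope_p: int = 6
    radial_hidden: tuple = (64, 64, 64)
    avg_num_neighbors: float = 1.0
    parity: bool = True

    def __post_init__(self):
        if not 0 <= self.l_max <= 3:
            raise ValueError("l_max must be in {0, 1, 2, 3}")
        if self.num_features < 1 or self.num_layers < 1:
            raise ValueError("num_features and num_layers must be positive")
        if self.r_c <= 0:
            raise ValueError("cutoff radius must be positive")
        if self.avg_num_neighbors <= 0:
            raise ValueError("average neighbor count must be positive")
        self.species = [int(z) for z in self.species]
        self.radial_hidden = tuple(int(h) for h in self.radial_hidden)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def filter_signature(self) -> IrrepsSignature:
        """Spherical-harmonic filters: one copy of l with natural parity."""
        return IrrepsSignature([(1, Irrep(l, (-1) ** l)) for l in range(self.l_max + 1)])

    def hidden_irreps(self):
        """The (l, p) set kept in hidden features, in layout order."""
        out = []
        for l in range(self.l_max + 1):
            out.append(Irrep(l, 1))
            if self.parity:
                out.append(Irrep(l, -1))
        return out

    def to_dict(self):
        return asdict(self)


@dataclass
class EnergyForceResult:
    """Total energy (eV), per-atom energies (eV) and forces (eV/Å)."""

    energy: float
    atomic_energies: np.ndarray
    forces: np.ndarray


# --------------------------------------------------------------------------
# batched graph container
# --------------------------------------------------------------------------

class GraphBatch:
    """Several structures merged into one disjoint graph with index offsets."""

    def __init__(self, structures, r_c, graphs=None):
        pos, species, ei, ej, shiftvec, sindex = [], [], [], [], [], []
        offset = 0
        self.n_structs = len(structures)
        self.n_atoms_per_struct = np.array([s.n_atoms for s in structures])
        for si, s in enumerate(structures):
            g = graphs[si] if graphs is not None else build_neighbor_graph(s, r_c)
            pos.append(s.positions)
            species.append(s.species)
            ei.append(g.edge_i + offset)
            ej.append(g.edge_j + offset)
            cell = s.cell if s.cell is not None else np.eye(3)
            shiftvec.append(g.shifts @ cell)
            sindex.append(np.full(s.n_atoms, si))
            offset += s.n_atoms
        self.positions = np.concatenate(pos)
        self.species = np.concatenate(species)
        self.edge_i = np.concatenate(ei)
        self.edge_j = np.concatenate(ej)
        self.shift_vectors = np.concatenate(shiftvec)
        self.structure_index = np.concatenate(sindex)
        self.n_atoms = offset

    @property
    def n_edges(self):
        return len(self.edge_i)


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _p(params, key):
    v = params[key]
    return v if isinstance(v, Tensor) else Tensor(v)


class LinearMix:
    """Atom-wise linear self-interaction: mixes channels within each irrep.

    Weights are shared across the representation index m (required for
    equivariance), stored standard-normal, and rescaled by 1/sqrt(fan_in) at
    application.  With ``per_species=True`` an independent weight set is used
    for every chemical species (the residual connection of each block).
    """

    def __init__(self, sig_in: IrrepsSignature, sig_out: IrrepsSignature, label: str,
                 per_species: bool = False, n_species: int = 1,
                 allow_missing: bool = False):
        self.sig_in = sig_in
        self.sig_out = sig_out
        self.label = label
        self.per_species = per_species
        self.n_species = n_species
        self.mapping = []  # (out_idx, [in_idx...]) with matching irreps
        for o, (_, ir_o) in enumerate(sig_out.segments):
            ins = [i for i, (_, ir_i) in enumerate(sig_in.segments) if ir_i == ir_o]
            if not ins:
                if allow_missing:
                    continue
                raise ValueError(
                    f"{label}: output irrep {ir_o} cannot be produced from {sig_in!r}"
                )
            self.mapping.append((o, ins))

    def param_shapes(self):
        shapes = {}
        for o, ins in self.mapping:
            c_out = self.sig_out.segments[o][0]
            for i in ins:
                c_in = self.sig_in.segments[i][0]
                base = (self.n_species,) if self.per_species else ()
                shapes[f"{self.label}.W{o}_{i}"] = base + (c_in, c_out)
        return shapes

    def init_params(self, rng):
        return {k: rng.standard_normal(shape) for k, shape in self.param_shapes().items()}

    def apply(self, x: EquivariantArray, params, species: Optional[np.ndarray] = None):
        blocks = {o: None for o in range(len(self.sig_out.segments))}
        x_blocks = list(x.segments())
        for o, ins in self.mapping:
            fan_in = sum(self.sig_in.segments[i][0] for i in ins)
            total = None
            for i in ins:
                _, _, xi = x_blocks[i]
                W = _p(params, f"{self.label}.W{o}_{i}")
                if self.per_species:
                    Wa = ad.take(W, species)          # (a, c_in, c_out)
                    term = ad.bmm(ad.swapaxes(Wa), xi)
                else:
                    term = ad.channel_mix(xi, W)
                total = term if total is None else total + term
            blocks[o] = total * (1.0 / np.sqrt(fan_in))
        n = x.shape[0]
        out_blocks = []
        for o, (mult, ir) in enumerate(self.sig_out.segments):
            b = blocks[o]
            if b is None:
                b = Tensor(np.zeros((n, mult, ir.dim)))
            out_blocks.append(b)
        return EquivariantArray.from_segments(self.sig_out, out_blocks)


class Gate:
    """Equivariant gate nonlinearity.

    Even scalars pass through SiLU, odd scalars through tanh; every l > 0
    channel is multiplied by the SiLU of a dedicated even-scalar gate
    channel.  The layer consumes the gate scalars: its input signature is
    ``scalars + (n_gates x 0e) + non-scalars`` and its output signature is
    ``scalars + non-scalars``.
    """

    def __init__(self, sig_out: IrrepsSignature):
        self.sig_out = sig_out
        scalars, nonscalars = [], []
        for mult, ir in sig_out.segments:
            (scalars if ir.l == 0 else nonscalars).append((mult, ir))
        self.n_gates = sum(m for m, _ in nonscalars)
        pre = list(scalars)
        if self.n_gates:
            pre.append((self.n_gates, Irrep(0, 1)))
        pre += nonscalars
        self.sig_pre = IrrepsSignature(pre)
        self.n_scalar_segs = len(scalars)

    def apply(self, x: EquivariantArray) -> EquivariantArray:
        blocks = list(x.segments())
        out_blocks = []
        k = 0
        for mult, ir, b in blocks[: self.n_scalar_segs]:
            act = ad.silu if ir.p == 1 else ad.tanh
            out_blocks.append(act(b))
            k += 1
        gate_vals = None
        if self.n_gates:
            _, _, gb = blocks[k]
            gate_vals = ad.silu(gb)  # (n, n_gates, 1)
            k += 1
        g_off = 0
        for mult, ir, b in blocks[k:]:
            g = ad.take(gate_vals, (slice(None), slice(g_off, g_off + mult)))
            out_blocks.append(b * g)
            g_off += mult
        return EquivariantArray.from_segments(self.sig_out, out_blocks)


class Convolution:
    """Tensor-product convolution over graph edges with 1/sqrt(N) pooling."""

    def __init__(self, sig_in: IrrepsSignature, config: ModelConfig, label: str):
        self.sig_in = sig_in
        self.config = config
        self.label = label
        self.filter_sig = config.filter_signature()
        self.paths = enumerate_paths(sig_in, self.filter_sig, config.l_max)
        self.sig_out = tensor_product_output_signature(sig_in, self.paths)
        self.weight_counts = [sig_in.segments[p.input_index][0] for p in self.paths]
        self.n_weights = sum(self.weight_counts)
        self.basis = BesselBasis(config.n_basis, config.r_c, config.envelope_p)
        self.radial = RadialMLP(config.n_basis, config.radial_hidden, self.n_weights)

    def init_params(self, rng):
        params = {f"{self.label}.bessel.{k}": v for k, v in self.basis.init_params().items()}
        for k, v in self.radial.init_params(rng).items():
            params[f"{self.label}.radial.{k}"] = v
        return params

    def apply(self, node_feat: EquivariantArray, batch: GraphBatch,
              edge_vec: Tensor, edge_len: Tensor, params) -> EquivariantArray:
        if batch.n_edges == 0:
            values = Tensor(np.zeros((batch.n_atoms, self.sig_out.dim)))
            return EquivariantArray(self.sig_out, values)
        inv_len = edge_len ** -1.0
        unit = edge_vec * inv_len.reshape((batch.n_edges, 1))
        Y = spherical_harmonics_tensor(self.config.l_max, unit)
        filt = EquivariantArray(self.filter_sig, ad.concatenate(Y, axis=1))
        freqs = _p(params, f"{self.label}.bessel.frequencies")
        B = self.basis(edge_len, freqs)
        rp = {k.split(".radial.", 1)[1]: v for k, v in params.items()
              if k.startswith(f"{self.label}.radial.")}
        w = self.radial(B, rp)
        weights, off = [], 0
        for c in self.weight_counts:
            weights.append(ad.take(w, (slice(None), slice(off, off + c))))
            off += c
        neigh = EquivariantArray(self.sig_in, ad.take(node_feat.values, batch.edge_j))
        msg = weighted_tensor_product(neigh, filt, self.paths, weights)
        pooled = ad.segment_sum(msg.values, batch.edge_i, batch.n_atoms)
        pooled = pooled * (1.0 / np.sqrt(self.config.avg_num_neighbors))
        return EquivariantArray(self.sig_out, pooled)


class InteractionBlock:
    """One message-passing block with per-species ResNet update and gate."""

    def __init__(self, index: int, sig_in: IrrepsSignature, config: ModelConfig):
        self.label = f"block{index}"
        self.sig_in = sig_in
        self.lin1 = LinearMix(sig_in, sig_in, f"{self.label}.lin1")
        self.conv = Convolution(sig_in, config, f"{self.label}.conv")
        conv_irreps = {ir for _, ir in self.conv.sig_out.segments}
        h = config.num_features
        kept = [(h, ir) for ir in config.hidden_irreps() if ir in conv_irreps]
        self.sig_out = IrrepsSignature(kept)
        self.gate = Gate(self.sig_out)
        self.lin2 = LinearMix(self.conv.sig_out, self.gate.sig_pre, f"{self.label}.lin2")
        self.residual = LinearMix(
            sig_in, self.gate.sig_pre, f"{self.label}.res",
            per_species=True, n_species=config.n_species, allow_missing=True,
        )

    def init_params(self, rng):
        params = {}
        for layer in (self.lin1, self.conv, self.lin2, self.residual):
            params.update(layer.init_params(rng))
        return params

    def apply(self, x: EquivariantArray, batch, edge_vec, edge_len,
              species_idx, params) -> EquivariantArray:
        h = self.lin1.apply(x, params)
        h = self.conv.apply(h, batch, edge_vec, edge_len, params)
        h = self.lin2.apply(h, params)
        res = self.residual.apply(x, params, species=species_idx)
        h = EquivariantArray(h.signature, h.values + res.values)
        return self.gate.apply(h)


# --------------------------------------------------------------------------
# full network
# --------------------------------------------------------------------------

class PotentialNetwork:
    """Stack of embedding, interaction blocks, output block and scale/shift.

    The network output is in *normalized* energy units; the training-set
    normalization statistics live with the fitted model wrapper, which
    converts predictions back to eV / eV/Å.
    """

    CHECKPOINT_VERSION = 1

    def __init__(self, config: ModelConfig):
        self.config = config
        h = config.num_features
        self.sig_embed = IrrepsSignature([(h, Irrep(0, 1))])
        self.blocks = []
        sig = self.sig_embed
        for k in range(config.num_layers):
            block = InteractionBlock(k, sig, config)
            self.blocks.append(block)
            sig = block.sig_out
        self.sig_final = sig
        # output block: even scalars -> 16 -> 1
        even_scalars = IrrepsSignature([(m, ir) for m, ir in sig.segments
                                        if ir == Irrep(0, 1)])
        self.out1 = LinearMix(even_scalars, IrrepsSignature([(16, "0e")]), "out.lin1")
        self.out2 = LinearMix(IrrepsSignature([(16, "0e")]), IrrepsSignature([(1, "0e")]),
                              "out.lin2")
        self._species_map = {z: i for i, z in enumerate(config.species)}

    # ---- parameters -----------------------------------------------------
    def init_params(self, rng) -> dict:
        cfg = self.config
        params = {
            "embed.W": rng.standard_normal((cfg.n_species, cfg.num_features)),
            "embed.b": np.zeros(cfg.num_features),
            "scale_shift.sigma": np.ones(cfg.n_species),
            "scale_shift.lambda": np.zeros(cfg.n_species),
        }
        for block in self.blocks:
            params.update(block.init_params(rng))
        params.update(self.out1.init_params(rng))
        params.update(self.out2.init_params(rng))
        return params

    def species_index(self, species: np.ndarray) -> np.ndarray:
        try:
            return np.array([self._species_map[int(z)] for z in species])
        except KeyError as exc:
            raise ValueError(f"unknown species Z={exc.args[0]}; "
                             f"model supports {self.config.species}") from exc

    # ---- forward ---------------------------------------------------------
    def energy(self, batch: GraphBatch, pos: Tensor, params) -> Tensor:
        """Per-structure energies (normalized units) as a (n_structs,) Tensor."""
        species_idx = self.species_index(batch.species)
        cfg = self.config
        # edge geometry, differentiable through positions
        if batch.n_edges:
            vec = ad.take(pos, batch.edge_j) - ad.take(pos, batch.edge_i) \
                + Tensor(batch.shift_vectors)
            length = ad.tsum(vec * vec, axis=1) ** 0.5
            if np.any(length.data < 1e-8):
                raise ValueError("atom pair at numerically zero separation")
        else:
            vec = Tensor(np.zeros((0, 3)))
            length = Tensor(np.zeros(0))
        # species embedding (l=0 even scalars only)
        onehot = np.zeros((batch.n_atoms, cfg.n_species))
        onehot[np.arange(batch.n_atoms), species_idx] = 1.0
        W, b = _p(params, "embed.W"), _p(params, "embed.b")
        feat = ad.matmul(Tensor(onehot), W) * (1.0 / np.sqrt(cfg.n_species)) + b
        x = EquivariantArray(self.sig_embed, feat)
        for block in self.blocks:
            x = block.apply(x, batch, vec, length, species_idx, params)
        even = EquivariantArray(
            self.out1.sig_in,
            ad.concatenate(
                [blk.reshape((batch.n_atoms, mult * ir.dim))
                 for mult, ir, blk in x.segments() if ir == Irrep(0, 1)],
                axis=1,
            ),
        )
        e = self.out2.apply(self.out1.apply(even, params), params)
        e_atom = e.values.reshape((batch.n_atoms,))
        sigma = ad.take(_p(params, "scale_shift.sigma"), species_idx)
        lam = ad.take(_p(params, "scale_shift.lambda"), species_idx)
        e_atom = sigma * e_atom + lam
        return ad.segment_sum(e_atom, batch.structure_index, batch.n_structs)

    def energy_forces_raw(self, structure: AtomicStructure, params):
        """Normalized-unit energy, per-atom energies and forces for one structure."""
        batch = GraphBatch([structure], self.config.r_c)
        pos = Tensor(batch.positions, requires_grad=True)
        params_t = {k: Tensor(v) if not isinstance(v, Tensor) else v
                    for k, v in params.items()}
        e = self.energy(batch, pos, params_t)
        e_total = ad.tsum(e)
        g = ad.grad(e_total, pos)
        return float(e_total.data), -g.data

    # ---- checkpoint ------------------------------------------------------
    def save_checkpoint(self, path, params, extra=None):
        payload = {
            "version": self.CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "params": {k: np.asarray(v.data if isinstance(v, Tensor) else v).tolist()
                       for k, v in params.items()},
            "extra": extra or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_checkpoint(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != cls.CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
        config = ModelConfig(**payload["config"])
        net = cls(config)
        params = {k: np.array(v) for k, v in payload["params"].items()}
        return net, params, payload.get("extra", {})
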