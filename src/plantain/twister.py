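"""The Twister encoder and its training loop.

The encoder maps a 2D ligand graph plus a binding-pocket graph to the
coefficients ``C[i, j, k]`` (and scalar bias) of the RBF scoring function.
It runs once per complex; pose evaluation afterwards is a cheap closed form.

Seven representation tracks are maintained: ligand atoms, ligand bonds
(densely, with a learned "no bond" embedding), pocket residues, residue-pair
edges, pocket atoms, and the ligand-ligand / ligand-residue /
ligand-pocket-atom interaction tracks (the latter initialized to zeros).
Each TwistBlock
  1. updates the ligand and residue graphs with an edge-featured
     graph-attention convolution (edge states updated alongside nodes),
  2. exchanges residue-level and atomic-level pocket information via
     scaled-dot-product cross-attention,
  3. refreshes each interaction entry from its endpoint nodes and lets each
     node attend over the interaction entries that involve it, and
  4. finalizes every track with a dense layer followed by layer
     normalization,
with a LeakyReLU after each operation and a residual connection to the state
two blocks earlier after every other block.  Residue-pair distances enter
through a Gaussian RBF encoding; pocket atom *coordinates* never enter, so
the coefficients are invariant to rigid motion of the pocket by
construction.

Input features live in closed vocabularies; anything outside them raises
:class:`~plantain.errors.UnknownFeatureError`.

Everything runs on the package's NumPy autodiff engine in double precision,
single-threaded, so training traces are reproducible bit for bit.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .errors import TrainingDivergedError, UnknownFeatureError
from .molio import BOND_ORDERS, HYBRIDIZATIONS, STANDARD_AA, LigandGraph, PocketStructure
from .noiser import NoiseSchedule, TrainingComplex, make_training_example
from .scorer import RBFBasis, ScoreCoefficients, pair_features

__all__ = [
    "TwisterConfig",
    "TrainConfig",
    "Twister",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se")
CHARGES = (-2, -1, 0, 1, 2)
MAX_NUM_H = 4
_BOND_VOCAB = BOND_ORDERS + ("none",)


def _vocab_index(vocab, value, kind: str) -> int:
    try:
        return vocab.index(value)
    except ValueError:
        raise UnknownFeatureError(f"unknown {kind} {value!r}; vocabulary: {vocab}")


@dataclass(frozen=True)
class TwisterConfig:
    """Architecture hyperparameters.

    The reference depth is 32 blocks; the default here is a 4-block
    configuration sized so the encoder is exercised end to end at toy scale.
    """

    n_blocks: int = 4
    d_lig: int = 32        # ligand atom / bond hidden width
    d_res: int = 32        # residue / residue-edge hidden width
    d_atom: int = 32       # pocket-atom hidden width
    d_inter: int = 16      # interaction-track hidden width
    n_heads: int = 4
    n_edge_rbf: int = 16   # Gaussian RBFs encoding residue-edge distances
    edge_rbf_max: float = 10.0  # A, span of the residue-edge RBF grid
    leaky_slope: float = 0.1
    n_rbf_out: int = 24    # coefficients per pair (matches the scoring basis)
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2 (residual every other block)")
        for name in ("d_lig", "d_res", "d_atom", "d_inter", "n_heads", "n_edge_rbf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for d in (self.d_lig, self.d_res, self.d_atom, self.d_inter):
            if d % self.n_heads != 0:
                raise ValueError("hidden widths must be divisible by n_heads")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    steps: int = 500
    batch_size: int = 8            # examples per complex per step
    examples_per_complex: int = 32
    seed: int = 0
    log_every: int = 50


class Twister:
    """Coefficient-producing encoder; weights are a flat name->Parameter dict."""

    def __init__(self, config: TwisterConfig):
        self.config = config
        self.params: dict[str, ad.Parameter] = {}
        self.n_encode_calls = 0
        rng = np.random.default_rng(config.seed)
        self._build(rng)

    # -- parameter construction -------------------------------------------
    def _add(self, name: str, shape, rng, scale=None) -> None:
        if scale is None:  # Glorot-style
            fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
            fan_out = shape[-1]
            scale = math.sqrt(2.0 / (fan_in + fan_out))
        self.params[name] = ad.Parameter(rng.normal(0.0, scale, size=shape))

    def _add_linear(self, name: str, d_in: int, d_out: int, rng) -> None:
        self._add(f"{name}.W", (d_in, d_out), rng)
        self.params[f"{name}.b"] = ad.Parameter(np.zeros(d_out))

    def _add_ln(self, name: str, d: int) -> None:
        self.params[f"{name}.g"] = ad.Parameter(np.ones(d))
        self.params[f"{name}.b"] = ad.Parameter(np.zeros(d))

    def _add_mha(self, name: str, d_q: int, d_kv: int, d_model: int, rng) -> None:
        self._add_linear(f"{name}.q", d_q, d_model, rng)
        self._add_linear(f"{name}.k", d_kv, d_model, rng)
        self._add_linear(f"{name}.v", d_kv, d_model, rng)
        self._add_linear(f"{name}.o", d_model, d_q, rng)

    def _build(self, rng) -> None:
        c = self.config
        # embeddings
        self._add("emb.lig_elem", (len(ELEMENTS), c.d_lig), rng, 0.2)
        self._add("emb.lig_charge", (len(CHARGES), c.d_lig), rng, 0.2)
        self._add("emb.lig_hyb", (len(HYBRIDIZATIONS), c.d_lig), rng, 0.2)
        self._add("emb.lig_numh", (MAX_NUM_H + 1, c.d_lig), rng, 0.2)
        self._add("emb.lig_arom", (2, c.d_lig), rng, 0.2)
        self._add("emb.bond", (len(_BOND_VOCAB), c.d_lig), rng, 0.2)
        self._add("emb.res_aa", (len(STANDARD_AA), c.d_res), rng, 0.2)
        self._add("emb.atom_elem", (len(ELEMENTS), c.d_atom), rng, 0.2)
        self._add("emb.atom_aa", (len(STANDARD_AA), c.d_atom), rng, 0.2)
        self._add_linear("emb.res_edge", c.n_edge_rbf, c.d_res, rng)
        for b in range(c.n_blocks):
            p = f"blk{b}"
            # ligand graph conv
            self._add_linear(f"{p}.lig_edge", 2 * c.d_lig + c.d_lig, c.d_lig, rng)
            self._add_linear(f"{p}.lig_att", c.d_lig, c.n_heads, rng)
            self._add_linear(f"{p}.lig_val", c.d_lig, c.d_lig, rng)
            self._add_linear(f"{p}.lig_upd", 2 * c.d_lig, c.d_lig, rng)
            # residue graph conv
            self._add_linear(f"{p}.res_edge", 2 * c.d_res + c.d_res, c.d_res, rng)
            self._add_linear(f"{p}.res_att", c.d_res, c.n_heads, rng)
            self._add_linear(f"{p}.res_val", c.d_res, c.d_res, rng)
            self._add_linear(f"{p}.res_upd", 2 * c.d_res, c.d_res, rng)
            # residue <-> pocket-atom cross attention
            self._add_mha(f"{p}.att_a2r", c.d_atom, c.d_res, c.d_atom, rng)
            self._add_mha(f"{p}.att_r2a", c.d_res, c.d_atom, c.d_res, rng)
            # interaction updates from endpoint nodes
            self._add_linear(f"{p}.ll_mix", c.d_inter + 2 * c.d_lig, c.d_inter, rng)
            self._add_linear(f"{p}.lr_mix", c.d_inter + c.d_lig + c.d_res, c.d_inter, rng)
            self._add_linear(f"{p}.lp_mix", c.d_inter + c.d_lig + c.d_atom, c.d_inter, rng)
            # nodes attending over their interaction entries
            self._add_mha(f"{p}.att_l2i", c.d_lig, c.d_inter, c.d_lig, rng)
            self._add_mha(f"{p}.att_r2i", c.d_res, c.d_inter, c.d_res, rng)
            self._add_mha(f"{p}.att_a2i", c.d_atom, c.d_inter, c.d_atom, rng)
            # track finalizers: dense + layer norm
            for track, d in (
                ("lig", c.d_lig), ("bond", c.d_lig), ("res", c.d_res),
                ("redge", c.d_res), ("atom", c.d_atom),
                ("ll", c.d_inter), ("lr", c.d_inter), ("lp", c.d_inter),
            ):
                self._add_linear(f"{p}.fin_{track}", d, d, rng)
                self._add_ln(f"{p}.ln_{track}", d)
        self._add_linear("head.ll", c.d_inter, c.n_rbf_out, rng)
        self._add_linear("head.lp", c.d_inter, c.n_rbf_out, rng)
        # single scalar head for the bias beta, fed by mean-pooled final tracks
        self._add_linear(
            "head.beta", 2 * c.d_lig + 2 * c.d_res + c.d_atom + 3 * c.d_inter, 1, rng
        )

    # -- building blocks ---------------------------------------------------
    def _lin(self, name: str, x):
        return ad.matmul(x, self.params[f"{name}.W"]) + self.params[f"{name}.b"]

    def _act(self, x):
        return ad.leaky_relu(x, self.config.leaky_slope)

    def _finalize(self, prefix: str, track: str, x):
        y = self._act(self._lin(f"{prefix}.fin_{track}", x))
        return ad.layer_norm(y, self.params[f"{prefix}.ln_{track}.g"],
                             self.params[f"{prefix}.ln_{track}.b"])

    def _graph_conv(self, prefix: str, nodes, edges, adj_mask: np.ndarray):
        """Edge-featured attention convolution on a dense small graph.

        ``nodes`` (N, d), ``edges`` (N, N, d), ``adj_mask`` (N, N) bool.
        Returns updated (nodes, edges).
        """
        n, d = nodes.shape
        h = self.config.n_heads
        hi = ad.broadcast_to(ad.reshape(nodes, (n, 1, d)), (n, n, d))
        hj = ad.broadcast_to(ad.reshape(nodes, (1, n, d)), (n, n, d))
        e_new = self._act(self._lin(f"{prefix}_edge", ad.concat([hi, hj, edges], axis=2)))
        logits = self._act(self._lin(f"{prefix}_att", e_new))          # (N, N, H)
        neg = np.full((1,), -1e9)
        logits = ad.where(adj_mask[:, :, None], logits, neg)
        att = ad.softmax(logits, axis=1)                               # over neighbors j
        att = ad.where(adj_mask[:, :, None], att, np.zeros(1))         # isolated nodes -> no message
        vals = self._lin(f"{prefix}_val", nodes)                       # (N, d)
        vals = ad.reshape(vals, (n, h, d // h))
        msg = ad.tsum(
            ad.reshape(att, (n, n, h, 1)) * ad.reshape(vals, (1, n, h, d // h)),
            axis=1,
        )                                                              # (N, H, d/H)
        msg = ad.reshape(msg, (n, d))
        upd = self._act(self._lin(f"{prefix}_upd", ad.concat([nodes, msg], axis=1)))
        return upd, e_new

    def _mha(self, name: str, q_in, kv_in):
        """Cross attention, queries (N, dq), keys/values (M, dkv)."""
        h = self.config.n_heads
        q = self._lin(f"{name}.q", q_in)
        k = self._lin(f"{name}.k", kv_in)
        v = self._lin(f"{name}.v", kv_in)
        n, dm = q.shape
        m = k.shape[0]
        dh = dm // h
        q = ad.transpose(ad.reshape(q, (n, h, dh)), (1, 0, 2))         # (H, N, dh)
        k = ad.transpose(ad.reshape(k, (m, h, dh)), (1, 2, 0))         # (H, dh, M)
        v = ad.transpose(ad.reshape(v, (m, h, dh)), (1, 0, 2))         # (H, M, dh)
        att = ad.softmax(ad.matmul(q, k) * (1.0 / math.sqrt(dh)), axis=2)
        out = ad.matmul(att, v)                                        # (H, N, dh)
        out = ad.reshape(ad.transpose(out, (1, 0, 2)), (n, dm))
        return self._act(self._lin(f"{name}.o", out))

    def _mha_batched(self, name: str, q_in, kv_in):
        """Per-row attention: queries (B, dq), keys/values (B, M, dkv)."""
        h = self.config.n_heads
        q = self._lin(f"{name}.q", q_in)                               # (B, dm)
        k = self._lin(f"{name}.k", kv_in)                              # (B, M, dm)
        v = self._lin(f"{name}.v", kv_in)
        b, dm = q.shape
        m = k.shape[1]
        dh = dm // h
        q = ad.transpose(ad.reshape(q, (b, 1, h, dh)), (0, 2, 1, 3))   # (B, H, 1, dh)
        k = ad.transpose(ad.reshape(k, (b, m, h, dh)), (0, 2, 3, 1))   # (B, H, dh, M)
        v = ad.transpose(ad.reshape(v, (b, m, h, dh)), (0, 2, 1, 3))   # (B, H, M, dh)
        att = ad.softmax(ad.matmul(q, k) * (1.0 / math.sqrt(dh)), axis=3)
        out = ad.matmul(att, v)                                        # (B, H, 1, dh)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (b, dm))
        return self._act(self._lin(f"{name}.o", out))

    # -- featurization -----------------------------------------------------
    def _ligand_indices(self, graph: LigandGraph):
        elem, chg, hyb, numh, arom = [], [], [], [], []
        for a in graph.atoms:
            elem.append(_vocab_index(ELEMENTS, a.element, "ligand element"))
            chg.append(_vocab_index(CHARGES, a.formal_charge, "formal charge"))
            hyb.append(_vocab_index(HYBRIDIZATIONS, a.hybridization, "hybridization"))
            if not 0 <= a.n_hydrogens <= MAX_NUM_H:
                raise UnknownFeatureError(f"hydrogen count {a.n_hydrogens} outside 0..{MAX_NUM_H}")
            numh.append(a.n_hydrogens)
            arom.append(int(a.aromatic))
        return map(np.array, (elem, chg, hyb, numh, arom))

    def _residue_edge_rbf(self, pocket: PocketStructure) -> np.ndarray:
        """(R, R, n_edge_rbf) Gaussian encodings of connected CA distances."""
        c = self.config
        r = pocket.n_residues
        centers = np.linspace(0.0, c.edge_rbf_max, c.n_edge_rbf)
        width = c.edge_rbf_max / max(c.n_edge_rbf - 1, 1)
        out = np.zeros((r, r, c.n_edge_rbf))
        for (a, b), dist in zip(pocket.residue_edges, pocket.residue_edge_distances):
            enc = np.exp(-((dist - centers) ** 2) / width**2)
            out[a, b] = enc
            out[b, a] = enc
        return out

    # -- forward -----------------------------------------------------------
    def forward(self, graph: LigandGraph, pocket: PocketStructure):
        """Run the encoder; returns (C, beta) as autodiff tensors."""
        c = self.config
        L, R, P = graph.heavy_atom_count, pocket.n_residues, pocket.n_atoms
        elem, chg, hyb, numh, arom = self._ligand_indices(graph)
        h_lig = (
            ad.getitem(self.params["emb.lig_elem"], elem)
            + ad.getitem(self.params["emb.lig_charge"], chg)
            + ad.getitem(self.params["emb.lig_hyb"], hyb)
            + ad.getitem(self.params["emb.lig_numh"], numh)
            + ad.getitem(self.params["emb.lig_arom"], arom)
        )
        bond_idx = np.full((L, L), _BOND_VOCAB.index("none"), dtype=int)
        adj_lig = np.zeros((L, L), dtype=bool)
        for b in graph.bonds:
            k = _vocab_index(_BOND_VOCAB, b.order, "bond order")
            bond_idx[b.i, b.j] = bond_idx[b.j, b.i] = k
            adj_lig[b.i, b.j] = adj_lig[b.j, b.i] = True
        h_bond = ad.getitem(self.params["emb.bond"], bond_idx)          # (L, L, d)
        res_idx = np.array(
            [_vocab_index(STANDARD_AA, r, "residue class") for r in pocket.residue_classes]
        )
        h_res = ad.getitem(self.params["emb.res_aa"], res_idx)
        adj_res = np.zeros((R, R), dtype=bool)
        for a, b in pocket.residue_edges:
            adj_res[a, b] = adj_res[b, a] = True
        h_redge = self._act(
            self._lin("emb.res_edge", ad.as_tensor(self._residue_edge_rbf(pocket)))
        )
        pa_elem = np.array(
            [_vocab_index(ELEMENTS, e, "pocket-atom element") for e in pocket.atom_elements]
        )
        pa_aa = np.array(
            [_vocab_index(STANDARD_AA, r, "pocket-atom residue class")
             for r in pocket.atom_residue_classes]
        )
        h_atom = ad.getitem(self.params["emb.atom_elem"], pa_elem) + ad.getitem(
            self.params["emb.atom_aa"], pa_aa
        )
        h_ll = ad.as_tensor(np.zeros((L, L, c.d_inter)))
        h_lr = ad.as_tensor(np.zeros((L, R, c.d_inter)))
        h_lp = ad.as_tensor(np.zeros((L, P, c.d_inter)))

        tracks = dict(lig=h_lig, bond=h_bond, res=h_res, redge=h_redge,
                      atom=h_atom, ll=h_ll, lr=h_lr, lp=h_lp)
        history = [dict(tracks)]
        for b in range(c.n_blocks):
            p = f"blk{b}"
            tracks["lig"], tracks["bond"] = self._graph_conv(
                f"{p}.lig", tracks["lig"], tracks["bond"], adj_lig
            )
            tracks["res"], tracks["redge"] = self._graph_conv(
                f"{p}.res", tracks["res"], tracks["redge"], adj_res
            )
            tracks["atom"] = tracks["atom"] + self._mha(f"{p}.att_a2r", tracks["atom"], tracks["res"])
            tracks["res"] = tracks["res"] + self._mha(f"{p}.att_r2a", tracks["res"], tracks["atom"])
            # interaction entries refreshed from their endpoint nodes
            li = ad.broadcast_to(ad.reshape(tracks["lig"], (L, 1, c.d_lig)), (L, L, c.d_lig))
            lj = ad.broadcast_to(ad.reshape(tracks["lig"], (1, L, c.d_lig)), (L, L, c.d_lig))
            tracks["ll"] = tracks["ll"] + self._act(
                self._lin(f"{p}.ll_mix", ad.concat([tracks["ll"], li, lj], axis=2))
            )
            li = ad.broadcast_to(ad.reshape(tracks["lig"], (L, 1, c.d_lig)), (L, R, c.d_lig))
            rj = ad.broadcast_to(ad.reshape(tracks["res"], (1, R, c.d_res)), (L, R, c.d_res))
            tracks["lr"] = tracks["lr"] + self._act(
                self._lin(f"{p}.lr_mix", ad.concat([tracks["lr"], li, rj], axis=2))
            )
            li = ad.broadcast_to(ad.reshape(tracks["lig"], (L, 1, c.d_lig)), (L, P, c.d_lig))
            pj = ad.broadcast_to(ad.reshape(tracks["atom"], (1, P, c.d_atom)), (L, P, c.d_atom))
            tracks["lp"] = tracks["lp"] + self._act(
                self._lin(f"{p}.lp_mix", ad.concat([tracks["lp"], li, pj], axis=2))
            )
            # nodes attend over the interaction entries that involve them
            inter_rows = ad.concat([tracks["ll"], tracks["lr"], tracks["lp"]], axis=1)
            tracks["lig"] = tracks["lig"] + self._mha_batched(f"{p}.att_l2i", tracks["lig"], inter_rows)
            tracks["res"] = tracks["res"] + self._mha_batched(
                f"{p}.att_r2i", tracks["res"], ad.transpose(tracks["lr"], (1, 0, 2))
            )
            tracks["atom"] = tracks["atom"] + self._mha_batched(
                f"{p}.att_a2i", tracks["atom"], ad.transpose(tracks["lp"], (1, 0, 2))
            )
            for name in tracks:
                tracks[name] = self._finalize(p, name, tracks[name])
            if b % 2 == 1:  # residual to the state two layers earlier
                prev = history[b - 1]
                for name in tracks:
                    tracks[name] = tracks[name] + prev[name]
            history.append(dict(tracks))
        C_ll = self._lin("head.ll", tracks["ll"])                       # (L, L, K)
        C_lp = self._lin("head.lp", tracks["lp"])                       # (L, P, K)
        C = ad.concat([C_ll, C_lp], axis=1)                             # (L, L+P, K)
        pooled = ad.concat(
            [
                ad.tmean(tracks["lig"], axis=0),
                ad.tmean(ad.reshape(tracks["bond"], (-1, c.d_lig)), axis=0),
                ad.tmean(tracks["res"], axis=0),
                ad.tmean(ad.reshape(tracks["redge"], (-1, c.d_res)), axis=0),
                ad.tmean(tracks["atom"], axis=0),
                ad.tmean(ad.reshape(tracks["ll"], (-1, c.d_inter)), axis=0),
                ad.tmean(ad.reshape(tracks["lr"], (-1, c.d_inter)), axis=0),
                ad.tmean(ad.reshape(tracks["lp"], (-1, c.d_inter)), axis=0),
            ],
            axis=0,
        )
        beta = ad.reshape(self._lin("head.beta", ad.reshape(pooled, (1, -1))), ())
        return C, beta

    def encode(self, graph: LigandGraph, pocket: PocketStructure) -> ScoreCoefficients:
        """Inference entry point (counts calls; runs once per docking job)."""
        self.n_encode_calls += 1
        C, beta = self.forward(graph, pocket)
        return ScoreCoefficients(C=np.array(C.value), beta=float(beta.value))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _example_pool(
    complexes: list[TrainingComplex],
    schedule: NoiseSchedule,
    basis: RBFBasis,
    n_per_complex: int,
    rng: np.random.Generator,
):
    """Pre-generate noised examples; Phi is precomputed since coordinates are
    fixed per example (the loss is linear in C given Phi)."""
    pool = []
    for ci, cx in enumerate(complexes):
        for _ in range(n_per_complex):
            ex = make_training_example(cx.crystal, cx.graph, cx.pocket, schedule, rng)
            phi = pair_features(ex.noised, cx.pocket, basis)
            pool.append((ci, phi, ex.targets))
    return pool


def _example_loss(C, beta, phi: np.ndarray, targets: np.ndarray):
    d_hat = ad.tsum(C * phi, axis=(1, 2)) + beta
    err = d_hat - targets
    return ad.tmean(err * err)


def evaluate_mse(model: Twister, complexes, pool) -> float:
    """Mean MSE over an example pool (no gradient bookkeeping kept)."""
    total = 0.0
    coeffs = {}
    for ci, phi, targets in pool:
        if ci not in coeffs:
            C, beta = model.forward(complexes[ci].graph, complexes[ci].pocket)
            coeffs[ci] = (C.value, float(beta.value))
        Cv, bv = coeffs[ci]
        d_hat = np.einsum("ijk,ijk->i", Cv, phi) + bv
        total += float(np.mean((d_hat - targets) ** 2))
    return total / len(pool)


def train(
    complexes: list[TrainingComplex],
    config: TwisterConfig | None = None,
    train_config: TrainConfig | None = None,
    schedule: NoiseSchedule | None = None,
    basis: RBFBasis | None = None,
    loss_log_path=None,
):
    """Minimize the MSE between predicted and true per-atom distances.

    Returns ``(model, trace)`` where ``trace`` is the per-step loss list.
    A non-finite loss aborts with :class:`TrainingDivergedError`.
    """
    if not complexes:
        raise ValueError("need at least one training complex")
    config = config or TwisterConfig()
    train_config = train_config or TrainConfig()
    schedule = schedule or NoiseSchedule()
    basis = basis or RBFBasis()
    model = Twister(config)
    rng = np.random.default_rng(train_config.seed)
    pool = _example_pool(complexes, schedule, basis,
                         train_config.examples_per_complex, rng)
    by_complex: dict[int, list[int]] = {}
    for idx, (ci, _, _) in enumerate(pool):
        by_complex.setdefault(ci, []).append(idx)
    opt = ad.Adam(list(model.params.values()), lr=train_config.lr)
    trace: list[float] = []
    for step in range(train_config.steps):
        opt.zero_grad()
        losses = []
        for ci, cx in enumerate(complexes):
            C, beta = model.forward(cx.graph, cx.pocket)
            take = rng.choice(
                by_complex[ci],
                size=min(train_config.batch_size, len(by_complex[ci])),
                replace=False,
            )
            for idx in take:
                _, phi, targets = pool[idx]
                losses.append(_example_loss(C, beta, phi, targets))
        loss = ad.tmean(ad.stack(losses))
        if not np.isfinite(loss.value):
            raise TrainingDivergedError(f"non-finite loss at step {step}")
        ad.backward(loss)
        opt.step()
        trace.append(float(loss.value))
    if loss_log_path is not None:
        import pandas as pd

        pd.DataFrame({"step": np.arange(len(trace)), "loss": trace}).to_csv(
            loss_log_path, index=False
        )
    return model, trace


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: Twister, path) -> None:
    arrays = {f"param:{k}": p.value for k, p in model.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> Twister:
    data = np.load(path)
    cfg = TwisterConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = Twister(cfg)
    for k, p in model.params.items():
        p.value[...] = data[f"param:{k}"]
    return model
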