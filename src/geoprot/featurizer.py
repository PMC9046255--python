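"""Residue-graph featurization.

Turns a backbone structure into an attributed directed k-nearest-neighbour
graph: each residue receives edges from its k spatially nearest residues by
CA distance. Node features carry backbone dihedrals (as sin/cos pairs),
amino-acid identity (one-hot over 20 standard residues + X) and three unit
direction vectors (to the next CA, to the previous CA, and toward the ideal
C-beta); edge features carry a 16-component Gaussian radial-basis encoding
of the CA-CA distance, a 16-component sinusoidal encoding of the sequence
offset, and the unit CA->CA direction vector.

Scalar features are invariant under rigid transforms of the coordinates;
vector features rotate with them. Undefined quantities (the first phi, the
last psi/omega, terminal direction vectors, degenerate frames) are encoded
as exact zeros and flagged, so the graph always has one node per residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import dihedral
from .structure_io import AA_ALPHABET, AA_TO_INDEX, BackboneStructure, impute_cbeta

N_RBF = 16
RBF_MAX = 20.0
N_POSENC = 16
DEFAULT_K = 30

FEATURE_MODES = ("onehot", "lm_only", "lm_concat")
N_DIHEDRAL_SCALARS = 6
N_ONEHOT = len(AA_ALPHABET)  # 21


@dataclass
class ProteinGraph:
    """Attributed residue graph, the input to the graph networks."""

    n_nodes: int
    edge_src: np.ndarray       # (E,) source node j of each directed edge j->i
    edge_dst: np.ndarray       # (E,) destination node i
    node_scalar: np.ndarray    # (L, a)
    node_vector: np.ndarray    # (L, 3, 3)
    edge_scalar: np.ndarray    # (E, 32)
    edge_vector: np.ndarray    # (E, 1, 3)
    feature_mode: str
    aa_sequence: str = ""
    coords_CA: np.ndarray | None = None
    node_vector_defined: np.ndarray | None = field(default=None)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def __post_init__(self):
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if np.any(self.edge_src == self.edge_dst):
            raise ValueError("graph contains self-edges")


def compute_dihedrals(struct: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Backbone torsions phi, psi, omega per residue, with a defined-mask.

    Returns ``(angles, defined)`` where ``angles`` is (L, 3) in radians in
    (-pi, pi] and ``defined`` is a (L, 3) boolean mask. phi is undefined at
    the first residue; psi and omega at the last. Degenerate (collinear)
    atom quadruples are marked undefined with a warning.

    Conventions: phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-
    N(i+1); omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1), IUPAC signs.
    """
    L = len(struct)
    angles = np.zeros((L, 3))
    defined = np.zeros((L, 3), dtype=bool)
    N, CA, C = struct.coords_N, struct.coords_CA, struct.coords_C

    def _safe(p0, p1, p2, p3):
        b2 = p2 - p1
        n1 = np.cross(p1 - p0, b2)
        n2 = np.cross(b2, p3 - p2)
        if (np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8
                or np.linalg.norm(b2) < 1e-8):
            return None
        return float(dihedral(p0, p1, p2, p3))

    for i in range(L):
        if i > 0:
            val = _safe(C[i - 1], N[i], CA[i], C[i])
            if val is None:
                warnings.warn(f"degenerate phi at residue {i}", stacklevel=2)
            else:
                angles[i, 0], defined[i, 0] = val, True
        if i < L - 1:
            psi_val = _safe(N[i], CA[i], C[i], N[i + 1])
            if psi_val is None:
                warnings.warn(f"degenerate psi at residue {i}", stacklevel=2)
            else:
                angles[i, 1], defined[i, 1] = psi_val, True
            omega_val = _safe(CA[i], C[i], N[i + 1], CA[i + 1])
            if omega_val is None:
                warnings.warn(f"degenerate omega at residue {i}", stacklevel=2)
            else:
                angles[i, 2], defined[i, 2] = omega_val, True
    return angles, defined


def build_knn_edges(ca: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed k-NN edges by CA distance: ``(src, dst)`` index arrays.

    Each node i receives edges from its min(k, L-1) nearest other nodes;
    distance ties break toward the smaller residue index (stable sort).
    """
    ca = np.asarray(ca, dtype=np.float64)
    L = len(ca)
    if L < 2:
        raise ValueError("need at least 2 residues to build edges")
    if k < 1:
        raise ValueError("k must be positive")
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    np.fill_diagonal(dist, np.inf)
    kk = min(k, L - 1)
    # quantize distances so exact geometric ties stay ties under the float
    # noise of a rigid transform; stable sort then breaks them by index
    order = np.argsort(np.round(dist, 6), axis=1, kind="stable")[:, :kk]
    dst = np.repeat(np.arange(L), kk)
    src = order.reshape(-1)
    return src, dst


def rbf_encode(d) -> np.ndarray:
    """Gaussian radial-basis encoding of distances in Angstrom.

    16 centers evenly spaced on [0, 20] A; width equals the center spacing.
    Output shape is ``d.shape + (16,)`` with components in (0, 1].
    """
    d = np.asarray(d, dtype=np.float64)
    centers = np.linspace(0.0, RBF_MAX, N_RBF)
    sigma = RBF_MAX / (N_RBF - 1)
    return np.exp(-(((d[..., None] - centers) / sigma) ** 2))


def positional_encode(offset) -> np.ndarray:
    """Sinusoidal encoding of the signed sequence offset j - i, 16 dims.

    Transformer recipe: dimension pairs (sin, cos) at geometrically spaced
    frequencies 10000^(-2m/16). Even dims are sines (zero at offset 0), odd
    dims cosines (one at offset 0).
    """
    offset = np.asarray(offset, dtype=np.float64)
    m = np.arange(N_POSENC // 2)
    freqs = 1.0 / (10000.0 ** (2.0 * m / N_POSENC))
    args = offset[..., None] * freqs
    out = np.empty(offset.shape + (N_POSENC,))
    out[..., 0::2] = np.sin(args)
    out[..., 1::2] = np.cos(args)
    return out


def _unit_rows(v: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Normalize rows; rows with tiny norm become exact zeros, flagged False."""
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    ok = norms[..., 0] > eps
    out = np.where(ok[..., None], v / np.where(ok[..., None], norms, 1.0), 0.0)
    return out, ok


def featurize_graph(struct: BackboneStructure, embeddings: np.ndarray | None = None,
                    mode: str = "onehot", k: int = DEFAULT_K) -> ProteinGraph:
    """Assemble the attributed k-NN residue graph.

    Parameters
    ----------
    struct:
        Parsed or generated backbone.
    embeddings:
        Optional (L, h) per-residue embedding matrix (accepted as an array or
        any object with a ``.values`` array attribute); required for modes
        ``lm_only`` and ``lm_concat``.
    mode:
        ``onehot`` — dihedral sin/cos + one-hot identity (width 27);
        ``lm_only`` — embeddings as the entire node scalar channel (width h);
        ``lm_concat`` — embeddings concatenated to the full structural
        scalars (width 27 + h).
    k:
        Neighbour count; every node receives min(k, L-1) incoming edges.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    L = len(struct)
    emb = None
    if mode in ("lm_only", "lm_concat"):
        if embeddings is None:
            raise ValueError(f"mode {mode!r} requires embeddings")
        emb = np.asarray(getattr(embeddings, "values", embeddings), dtype=np.float64)
        if emb.shape[0] != L:
            raise ValueError(
                f"sequence/structure length mismatch: {emb.shape[0]} embedding rows "
                f"for {L} residues")

    # --- node scalars
    angles, defined = compute_dihedrals(struct)
    sincos = np.zeros((L, N_DIHEDRAL_SCALARS))
    sincos[:, 0::2] = np.where(defined, np.sin(angles), 0.0)
    sincos[:, 1::2] = np.where(defined, np.cos(angles), 0.0)
    onehot = np.zeros((L, N_ONEHOT))
    for i, aa in enumerate(struct.aa_sequence):
        onehot[i, AA_TO_INDEX.get(aa, AA_TO_INDEX["X"])] = 1.0
    structural = np.concatenate([sincos, onehot], axis=1)
    if mode == "onehot":
        node_scalar = structural
    elif mode == "lm_only":
        node_scalar = emb
    else:
        node_scalar = np.concatenate([structural, emb], axis=1)

    # --- node vectors: forward / reverse CA directions, CA->ideal-CB direction
    ca = struct.coords_CA
    fwd = np.zeros((L, 3))
    rev = np.zeros((L, 3))
    fwd[:-1] = ca[1:] - ca[:-1]
    rev[1:] = ca[:-1] - ca[1:]
    fwd, fwd_ok = _unit_rows(fwd)
    rev, rev_ok = _unit_rows(rev)
    fwd[-1], rev[0] = 0.0, 0.0
    fwd_ok[-1] = rev_ok[0] = False
    cb_dir = np.zeros((L, 3))
    cb_ok = np.zeros(L, dtype=bool)
    for i in range(L):
        try:
            ideal_cb = impute_cbeta(struct.coords_N[i], ca[i], struct.coords_C[i])
        except ValueError:
            warnings.warn(f"degenerate N-CA-C frame at residue {i}", stacklevel=2)
            continue
        cb_dir[i] = ideal_cb - ca[i]
        cb_ok[i] = True
    cb_dir, cb_unit_ok = _unit_rows(cb_dir)
    cb_ok &= cb_unit_ok
    node_vector = np.stack([fwd, rev, cb_dir], axis=1)  # (L, 3, 3)
    vec_defined = np.stack([fwd_ok, rev_ok, cb_ok], axis=1)

    # --- edges
    src, dst = build_knn_edges(ca, k)
    delta = ca[src] - ca[dst]
    d = np.linalg.norm(delta, axis=1)
    edge_scalar = np.concatenate([rbf_encode(d), positional_encode(src - dst)], axis=1)
    edge_unit, _ = _unit_rows(delta)
    edge_vector = edge_unit[:, None, :]  # (E, 1, 3)

    return ProteinGraph(
        n_nodes=L, edge_src=src, edge_dst=dst,
        node_scalar=node_scalar, node_vector=node_vector,
        edge_scalar=edge_scalar, edge_vector=edge_vector,
        feature_mode=mode, aa_sequence=struct.aa_sequence,
        coords_CA=ca.copy(), node_vector_defined=vec_defined,
    )


def save_graph_npz(graph: ProteinGraph, path: str) -> None:
    """Write a graph as an .npz archive with named arrays (documented layout)."""
    np.savez(
        path,
        edge_src=graph.edge_src, edge_dst=graph.edge_dst,
        node_scalar=graph.node_scalar, node_vector=graph.node_vector,
        edge_scalar=graph.edge_scalar, edge_vector=graph.edge_vector,
        feature_mode=np.array(graph.feature_mode),
        aa_sequence=np.array(graph.aa_sequence),
        coords_CA=graph.coords_CA,
    )
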