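"""Deterministic synthetic fixtures: idealized backbones, toy labeled tasks
and toy mutational scans.

Everything here is seed-deterministic and CPU-cheap, so the full model stack
(featurization, graph networks, language-model stub, training, attribution,
zero-shot scoring, contact probing) can be exercised offline. Chains are
built by sequential NeRF placement from ideal bond lengths and angles; they
are internally consistent with the dihedral measurement code (building a
chain from stated phi/psi/omega and re-measuring recovers the angles), which
is what the feature tests rely on. They are not crystallographically
realistic decoys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .structure_io import BackboneStructure, impute_cbeta

# Ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

#: canonical (phi, psi) in degrees for secondary-structure states
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

_STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

# residue propensities used when a sequence is coupled to secondary structure
_SS_PREFERRED = {"H": "AELMQK", "E": "VITYFW", "C": "GPSND"}


@dataclass
class ChainSpec:
    """Internal-coordinate specification of one idealized chain.

    ``phi``, ``psi``, ``omega`` are per-residue torsions in degrees (scalars
    broadcast to all residues). ``phi[0]`` and the last ``psi``/``omega`` are
    not used in construction, mirroring which torsions exist on a chain.
    """

    length: int
    phi: np.ndarray | float = -57.0
    psi: np.ndarray | float = -47.0
    omega: np.ndarray | float = 180.0
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("chain length must be >= 2")
        for name in ("phi", "psi", "omega"):
            val = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=np.float64), (self.length,)
            ).copy()
            if np.any(val <= -180.0) or np.any(val > 180.0):
                raise ValueError(f"{name} angles must lie in (-180, 180]")
            setattr(self, name, val)
        if self.sequence is None:
            rng = np.random.default_rng(self.seed)
            self.sequence = "".join(rng.choice(list(_STANDARD_AAS), size=self.length))
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match chain length")


def build_chain(spec: ChainSpec) -> BackboneStructure:
    """Construct an idealized backbone by sequential NeRF placement.

    Round-trips with the dihedral measurement in the featurizer: interior
    residues of the built chain reproduce the specified torsions to well
    below 1e-3 degrees.
    """
    L = spec.length
    phi = np.deg2rad(spec.phi)
    psi = np.deg2rad(spec.psi)
    omega = np.deg2rad(spec.omega)

    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    O = np.zeros((L, 3))

    # seed residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(L - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N,
                              np.deg2rad(ANGLE_CA_C_N), psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA,
                               np.deg2rad(ANGLE_C_N_CA), omega[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C,
                              np.deg2rad(ANGLE_N_CA_C), phi[i + 1])
        # carbonyl O of residue i, anti to the next N
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O,
                          np.deg2rad(ANGLE_CA_C_O),
                          _wrap(psi[i] + np.pi))
    O[L - 1] = place_atom(N[L - 1], CA[L - 1], C[L - 1], BOND_C_O,
                          np.deg2rad(ANGLE_CA_C_O), _wrap(np.pi))

    CB = np.array([impute_cbeta(N[i], CA[i], C[i]) for i in range(L)])
    return BackboneStructure(
        residue_ids=[("A", i + 1, "") for i in range(L)],
        aa_sequence=spec.sequence,
        coords_N=N, coords_CA=CA, coords_C=C, coords_O=O, coords_CB=CB,
        cb_imputed=np.ones(L, dtype=bool),
    )


def _wrap(angle: float) -> float:
    """Wrap an angle in radians to (-pi, pi]."""
    wrapped = (angle + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if np.isclose(wrapped, -np.pi) else wrapped


# --------------------------------------------------------------- toy tasks
@dataclass
class SyntheticTask:
    """A toy labeled dataset of idealized structures."""

    structures: list[BackboneStructure]
    labels: np.ndarray  # (n,) real or {0,1}
    helix_fractions: np.ndarray
    task_kind: str  # "multilabel" (single binary label) or "regression"
    provenance: dict = field(default_factory=dict)


def _sample_segmented_chain(rng: np.random.Generator, length: int,
                            helix_target: float) -> tuple[ChainSpec, float]:
    """Chain of helix/strand/coil segments with roughly the target helix content.

    The sequence is coupled to the secondary structure through residue
    propensities, so sequence models can recover structural labels.
    """
    states: list[str] = []
    while len(states) < length:
        remaining = length - len(states)
        seg_len = min(int(rng.integers(4, 9)), remaining)
        p_helix = helix_target
        r = rng.random()
        if r < p_helix:
            state = "H"
        elif r < p_helix + (1 - p_helix) * 0.6:
            state = "E"
        else:
            state = "C"
        states.extend([state] * seg_len)
    states = states[:length]

    phi = np.empty(length)
    psi = np.empty(length)
    seq_chars = []
    for i, s in enumerate(states):
        if s == "H":
            phi[i], psi[i] = HELIX_PHI_PSI
        elif s == "E":
            phi[i], psi[i] = STRAND_PHI_PSI
        else:
            phi[i] = rng.uniform(-150, -60)
            psi[i] = rng.uniform(-60, 170)
        pool = _SS_PREFERRED[s] if rng.random() < 0.8 else _STANDARD_AAS
        seq_chars.append(pool[int(rng.integers(len(pool)))])
    helix_fraction = float(np.mean([s == "H" for s in states]))
    spec = ChainSpec(length=length, phi=phi, psi=psi, omega=180.0,
                     sequence="".join(seq_chars))
    return spec, helix_fraction


def make_structure_task(n_proteins: int, rule: str = "helix_fraction_threshold",
                        seed: int = 0, min_length: int = 25,
                        max_length: int = 35) -> SyntheticTask:
    """Generate a desk-scale labeled task over idealized structures.

    rule ``helix_fraction_threshold``: binary label 1 iff the helix fraction
    of the chain is >= 0.5. rule ``radius_label``: real label = radius of
    gyration of the CA trace (regression).
    """
    if n_proteins < 4:
        raise ValueError("need at least 4 proteins")
    if rule not in ("helix_fraction_threshold", "radius_label"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    structures, fractions = [], []
    for _ in range(n_proteins):
        length = int(rng.integers(min_length, max_length + 1))
        target = rng.uniform(0.1, 0.9)
        spec, frac = _sample_segmented_chain(rng, length, target)
        structures.append(build_chain(spec))
        fractions.append(frac)
    fractions = np.asarray(fractions)
    if rule == "helix_fraction_threshold":
        labels = (fractions >= 0.5).astype(np.float64)
        task_kind = "multilabel"
    else:
        labels = np.array([
            float(np.sqrt(((s.coords_CA - s.coords_CA.mean(0)) ** 2).sum(1).mean()))
            for s in structures
        ])
        task_kind = "regression"
    prov = {
        "generator": "make_structure_task", "rule": rule, "seed": seed,
        "n_proteins": n_proteins, "min_length": min_length, "max_length": max_length,
        "content_hash": _content_hash([s.coords_CA for s in structures] + [labels]),
    }
    return SyntheticTask(structures=structures, labels=labels,
                         helix_fractions=fractions, task_kind=task_kind,
                         provenance=prov)


# ----------------------------------------------------------- toy mutscans
def make_mutscan(wt_length: int = 40, n_records: int = 200, sigma: float = 0.1,
                 seed: int = 0, lm=None, max_order: int = 2):
    """Toy deep-mutational-scan table with a known ground-truth signal.

    Assay value = masked-marginal score under the stub language model plus
    Gaussian noise of scale ``sigma``; at ``sigma=0`` the rank correlation
    between model scores and assay values is exactly 1.
    """
    from .lm import StubProteinLM
    from .variant_scoring import MutScanTable, MutScanRecord, masked_marginal_score

    if n_records < 3:
        raise ValueError("need at least 3 records")
    rng = np.random.default_rng(seed)
    if lm is None:
        lm = StubProteinLM(seed=0)
    wt = "".join(rng.choice(list(_STANDARD_AAS), size=wt_length))
    records = []
    for _ in range(n_records):
        order = int(rng.integers(1, max_order + 1))
        positions = rng.choice(wt_length, size=order, replace=False) + 1
        muts = []
        for pos in sorted(positions.tolist()):
            wt_aa = wt[pos - 1]
            mt_aa = wt_aa
            while mt_aa == wt_aa:
                mt_aa = _STANDARD_AAS[int(rng.integers(20))]
            muts.append((pos, wt_aa, mt_aa))
        score = masked_marginal_score(lm, wt, muts)
        assay = score + rng.normal(0.0, sigma)
        records.append(MutScanRecord(mutations=muts, assay=assay))
    table = MutScanTable(wildtype=wt, records=records)
    table.provenance = {
        "generator": "make_mutscan", "seed": seed, "sigma": sigma,
        "wt_length": wt_length, "n_records": n_records,
        "content_hash": _content_hash([np.array([r.assay for r in records])]),
    }
    return table


def make_planted_attention(n_proteins: int = 12, length: int = 30,
                           n_noise_heads: int = 3, seed: int = 0):
    """Pair-feature tables with one attention head equal to the contact map.

    For each protein a compact random CA trace defines true contacts; the
    first attention head is the (row-normalised) contact map itself and the
    remaining heads are random row-stochastic noise. A contact probe fit on
    these tables should put its largest-magnitude weight on head 0.
    """
    from .contact_probe import attention_pair_features, true_contacts
    from .lm import AttentionMaps

    rng = np.random.default_rng(seed)
    tables = []
    for p in range(n_proteins):
        ca = rng.normal(size=(length, 3)).cumsum(axis=0) * 2.2
        struct = BackboneStructure(
            residue_ids=[("A", i + 1, "") for i in range(length)],
            aa_sequence="A" * length,
            coords_N=ca + [0.5, 0.5, 0.0], coords_CA=ca,
            coords_C=ca + [0.5, -0.5, 0.0], coords_O=ca + [0.9, -0.9, 0.0],
            coords_CB=ca + [0.0, 0.0, 1.0])
        cmap = true_contacts(struct)
        signal = cmap.matrix.astype(float) + 1e-3  # avoid all-zero rows
        signal /= signal.sum(-1, keepdims=True)
        heads = [signal]
        for _ in range(n_noise_heads):
            noise = rng.random((length, length))
            heads.append(noise / noise.sum(-1, keepdims=True))
        maps = AttentionMaps(maps=np.stack(heads).reshape(1, -1, length, length))
        tables.append(attention_pair_features(maps, cmap))
    return tables


def _content_hash(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=np.float64)).tobytes())
    return h.hexdigest()[:16]


def provenance_json(obj) -> str:
    """Provenance metadata of a generated fixture as JSON text."""
    return json.dumps(getattr(obj, "provenance", {}), indent=2, sort_keys=True)
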