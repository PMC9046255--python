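"""Backbone extraction from PDB files.

Reads ATOM/HETATM records of a single chain into a validated per-residue
:class:`BackboneStructure` holding N, CA, C, O coordinates, the one-letter
sequence and a C-beta coordinate for every residue (observed where present,
otherwise imputed from ideal tetrahedral geometry of the local N-CA-C frame).

Conventions for real-world files: only the first model of a multi-model file
is used; alternate locations are resolved by highest occupancy, then first
listed; HETATM amino acids such as selenomethionine are accepted; residues
missing any of N/CA/C are dropped with a warning (O may be absent — it is not
used by any downstream feature).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
from biotite.sequence import ProteinSequence

from ._geometry import place_atom

# Ideal C-beta internal coordinates: CA-CB bond length (A), N-CA-CB bond
# angle and C-N-CA-CB torsion (degrees). Standard ideal-geometry values.
CB_BOND_LENGTH = 1.522
CB_BOND_ANGLE_DEG = 110.4
CB_TORSION_DEG = -122.5

#: one-letter alphabet used throughout: 20 standard residues + X for anything else
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates and identities for one chain.

    Coordinates are in Angstrom, in the frame of the source file. ``cb_imputed``
    marks residues whose C-beta was reconstructed rather than observed
    (glycine, or missing atom).
    """

    residue_ids: list[tuple[str, int, str]]
    aa_sequence: str
    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray
    coords_CB: np.ndarray
    cb_imputed: np.ndarray = field(default=None)

    def __post_init__(self):
        L = len(self.aa_sequence)
        if L < 1:
            raise ValueError("no complete residues")
        for name in ("coords_N", "coords_CA", "coords_C", "coords_O", "coords_CB"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({L}, 3)")
            setattr(self, name, arr)
        if len(self.residue_ids) != L:
            raise ValueError("residue_ids length mismatch")
        self.cb_imputed = np.asarray(
            self.cb_imputed if self.cb_imputed is not None else np.zeros(L, bool), dtype=bool
        )
        finite = [np.isfinite(getattr(self, n)).all()
                  for n in ("coords_N", "coords_CA", "coords_C", "coords_CB")]
        if not all(finite):
            raise ValueError("non-finite backbone coordinates")

    def __len__(self) -> int:
        return len(self.aa_sequence)

    # --------------------------------------------------------- serialization
    def to_json(self) -> str:
        """Serialize to the documented JSON sidecar layout."""
        return json.dumps({
            "residue_ids": [[c, int(r), i] for c, r, i in self.residue_ids],
            "aa_sequence": self.aa_sequence,
            "coords_N": self.coords_N.tolist(),
            "coords_CA": self.coords_CA.tolist(),
            "coords_C": self.coords_C.tolist(),
            "coords_O": self.coords_O.tolist(),
            "coords_CB": self.coords_CB.tolist(),
            "cb_imputed": self.cb_imputed.astype(int).tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "BackboneStructure":
        d = json.loads(text)
        return cls(
            residue_ids=[(c, int(r), i) for c, r, i in d["residue_ids"]],
            aa_sequence=d["aa_sequence"],
            coords_N=np.array(d["coords_N"], dtype=np.float64),
            coords_CA=np.array(d["coords_CA"], dtype=np.float64),
            coords_C=np.array(d["coords_C"], dtype=np.float64),
            coords_O=np.array(d["coords_O"], dtype=np.float64),
            coords_CB=np.array(d["coords_CB"], dtype=np.float64),
            cb_imputed=np.array(d["cb_imputed"], dtype=bool),
        )

    def to_pdb(self) -> str:
        """Render as minimal PDB text (N, CA, C, O atoms; chain from ids)."""
        lines = []
        serial = 1
        for i, (chain, resnum, icode) in enumerate(self.residue_ids):
            resname = three_letter(self.aa_sequence[i])
            for atom_name, coords in (("N", self.coords_N), ("CA", self.coords_CA),
                                      ("C", self.coords_C), ("O", self.coords_O)):
                x, y, z = coords[i]
                if not np.isfinite([x, y, z]).all():
                    continue
                lines.append(
                    f"ATOM  {serial:5d}  {atom_name:<3s} {resname:>3s} {chain:1s}"
                    f"{resnum:4d}{icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom_name[0]:>2s}"
                )
                serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def three_letter(aa: str) -> str:
    return _ONE_TO_THREE.get(aa, "UNK")


def one_letter(resname: str) -> str:
    """Map a 3-letter residue name to the 21-letter alphabet (X fallback)."""
    try:
        code = ProteinSequence.convert_letter_3to1(resname)
    except KeyError:
        return "X"
    return code if code in AA_TO_INDEX else "X"


def impute_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta position from the local N-CA-C frame.

    Constructed by NeRF placement with bond length 1.522 A, N-CA-CB angle
    110.4 deg and C-N-CA-CB torsion -122.5 deg; deterministic and equivariant
    under rigid transforms of the three input points. The construction uses a
    cross product of frame vectors, so it preserves chirality: mirroring the
    inputs does not mirror the output.
    """
    return place_atom(
        np.asarray(c, dtype=np.float64),
        np.asarray(n, dtype=np.float64),
        np.asarray(ca, dtype=np.float64),
        CB_BOND_LENGTH,
        np.deg2rad(CB_BOND_ANGLE_DEG),
        np.deg2rad(CB_TORSION_DEG),
    )


def parse_backbone(pdb_text: str, chain_selector: str = "first") -> BackboneStructure:
    """Parse one chain's backbone from PDB text.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM/HETATM records in fixed columns).
    chain_selector:
        A chain identifier, or ``"first"`` for the first chain in the file.

    Returns
    -------
    BackboneStructure
        Residues in file order. Residues missing any of N/CA/C are dropped
        with a warning. Missing O coordinates are stored as the CA position
        (O is unused downstream). C-beta is taken from the file when present,
        otherwise imputed.
    """
    pdb_file = pdb_io.PDBFile.read(io.StringIO(pdb_text))
    try:
        atoms = pdb_io.get_structure(pdb_file, model=1, altloc="occupancy")
    except Exception as err:
        raise ValueError(f"could not parse PDB text: {err}") from err
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no complete residues: file contains no amino-acid atoms")

    chains = list(dict.fromkeys(atoms.chain_id))
    if chain_selector == "first":
        chain = chains[0]
    else:
        chain = chain_selector
        if chain not in chains:
            raise ValueError(f"unknown chain id {chain!r}; file has {chains}")
    atoms = atoms[atoms.chain_id == chain]

    residue_ids: list[tuple[str, int, str]] = []
    seq_chars: list[str] = []
    per_atom: dict[str, list[np.ndarray]] = {k: [] for k in ("N", "CA", "C", "O", "CB")}
    imputed: list[bool] = []

    for res in struc.residue_iter(atoms):
        resnum = int(res.res_id[0])
        icode = str(res.ins_code[0]) if hasattr(res, "ins_code") else ""
        names = list(res.atom_name)
        coords = {}
        for atom_name in ("N", "CA", "C", "O", "CB"):
            if atom_name in names:
                coords[atom_name] = np.asarray(
                    res.coord[names.index(atom_name)], dtype=np.float64)
        if any(a not in coords for a in ("N", "CA", "C")):
            warnings.warn(
                f"dropping residue {chain}{resnum}{icode.strip()}: incomplete backbone",
                stacklevel=2,
            )
            continue
        aa = one_letter(str(res.res_name[0]))
        if "CB" in coords:
            cb, was_imputed = coords["CB"], False
        else:
            cb, was_imputed = impute_cbeta(coords["N"], coords["CA"], coords["C"]), True
        residue_ids.append((chain, resnum, icode.strip()))
        seq_chars.append(aa)
        per_atom["N"].append(coords["N"])
        per_atom["CA"].append(coords["CA"])
        per_atom["C"].append(coords["C"])
        per_atom["O"].append(coords.get("O", coords["CA"]))
        per_atom["CB"].append(cb)
        imputed.append(was_imputed)

    if not residue_ids:
        raise ValueError(f"no complete residues in chain {chain!r}")

    return BackboneStructure(
        residue_ids=residue_ids,
        aa_sequence="".join(seq_chars),
        coords_N=np.array(per_atom["N"]),
        coords_CA=np.array(per_atom["CA"]),
        coords_C=np.array(per_atom["C"]),
        coords_O=np.array(per_atom["O"]),
        coords_CB=np.array(per_atom["CB"]),
        cb_imputed=np.array(imputed, dtype=bool),
    )
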