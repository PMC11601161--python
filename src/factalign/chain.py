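"""Cα backbone containers and structure file I/O.

A protein chain is reduced to its ordered Cα trace plus one-letter amino
acid identities; that is the only structural information the aligner uses.
Reading goes through :mod:`gemmi` (PDB and mmCIF); writing emits CA-only
PDB suitable for visualising a superposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, index order used everywhere.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}


class StructureError(ValueError):
    """Raised for unreadable, empty or otherwise invalid structure input."""


@dataclass
class ChainStructure:
    """Ordered Cα trace of one protein chain or domain.

    Parameters
    ----------
    id : str
        Label, e.g. ``"d1qmha1"`` or ``"<pdb stem>_<chain>"``.
    aa : str
        One-letter amino acids, uppercase, 20 standard letters or ``'X'``.
    coords : (n, 3) float array
        Cα coordinates in Å, chain order.
    """

    id: str
    aa: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"{self.id}: coords must be (n, 3)")
        n = self.coords.shape[0]
        if n < 1 or len(self.aa) != n:
            raise StructureError(
                f"{self.id}: need >=1 residue and len(aa) == len(coords) "
                f"(got {len(self.aa)} vs {n})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"{self.id}: non-finite coordinates")
        bad = set(self.aa) - set(AA_LETTERS + "X")
        if bad:
            raise StructureError(f"{self.id}: invalid aa letters {sorted(bad)}")
        if n > 1:
            steps = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            if np.any(steps <= 0):
                raise StructureError(f"{self.id}: coincident consecutive Cα atoms")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list[tuple[str, np.ndarray]]:
        """Residues as ``(aa_letter, ca_xyz)`` pairs, chain order."""
        return [(self.aa[i], self.coords[i]) for i in range(len(self))]


def _one_letter(resname: str) -> str:
    if resname == "MSE":
        return "M"
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code in AA_INDEX else "X"


def read_structures(
    path: str | Path,
    format_hint: str | None = None,
    chain: str | None = None,
) -> list[ChainStructure]:
    """Read one :class:`ChainStructure` per chain from a PDB or mmCIF file.

    Only ATOM records (plus MSE) with atom name CA and altloc blank or 'A'
    are used, first model only; residues without a Cα are skipped with a
    warning.  ``chain`` restricts to a single chain id.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    fmt = gemmi.CoorFormat.Unknown
    if format_hint:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
               "cif": gemmi.CoorFormat.Mmcif}.get(format_hint.lower(), fmt)
    try:
        if fmt is gemmi.CoorFormat.Unknown:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=fmt)
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")

    out: list[ChainStructure] = []
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        letters: list[str] = []
        xyz: list[list[float]] = []
        for res in ch:
            if res.het_flag != "A" and res.name != "MSE":
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.altloc in ("", "\0", "A"):
                    ca = atom
                    break
            if ca is None:
                logger.warning("%s %s/%s %s: no Cα atom, residue skipped",
                               path.name, ch.name, res.seqid.num, res.name)
                continue
            letters.append(_one_letter(res.name))
            xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if letters:
            out.append(ChainStructure(
                id=f"{path.stem}_{ch.name}",
                aa="".join(letters),
                coords=np.array(xyz, dtype=float),
            ))
    if not out:
        raise StructureError(f"no Cα atoms found in {path}")
    return out


def reverse_chain(s: ChainStructure) -> ChainStructure:
    """Residues in reverse chain order (coordinates and letters together)."""
    return ChainStructure(id=s.id + "_rev", aa=s.aa[::-1],
                          coords=s.coords[::-1].copy())


def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise StructureError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=tol):
        raise StructureError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(rotation) - 1.0) > 1e-4:
        raise StructureError("rotation matrix determinant is not +1")
    return rotation


def write_superposed(
    s: ChainStructure,
    rotation: np.ndarray,
    translation: np.ndarray,
    path: str | Path,
) -> None:
    """Write ``R·x + t`` applied to every Cα of ``s`` as a CA-only PDB file."""
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float).reshape(3)
    moved = s.coords @ rotation.T + translation

    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for i, (aa, xyz) in enumerate(zip(s.aa, moved)):
        res = gemmi.Residue()
        # expand one-letter code back to a residue name for the PDB record
        res.name = _THREE_LETTER.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
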