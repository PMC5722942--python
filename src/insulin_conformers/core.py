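"""Core in-memory model: atoms, residues, canonically numbered insulin monomers.

Insulin numbering is 1-based per chain (A1..A21, B1..B30).  All downstream
logic addresses residues through these canonical labels; the author
numbering of the source file is carried along for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Human insulin chain sequences (one-letter), used for canonical numbering.
A_CHAIN_SEQ = "GIVEQCCTSICSLYQLENYCN"  # 21 residues
B_CHAIN_SEQ = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"  # 30 residues

# Cystine bridge positions (canonical labels).
BRIDGES = {
    "A6A11": ("A6", "A11"),
    "A7B7": ("A7", "B7"),
    "A20B19": ("A20", "B19"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """A single atom: label, element, position in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue with author numbering and (optionally) a canonical insulin label."""

    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    insulin_pos: str | None = None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class InsulinMonomer:
    """A canonically numbered two-chain insulin monomer.

    ``a_chain`` holds the residues labelled A1..A21 and ``b_chain`` the
    residues B1..B30, in label order.  Missing residues (disorder in the
    deposited model) are permitted except at the six bridge positions.
    """

    pdb_id: str
    model_no: int
    a_chain: list[Residue]
    b_chain: list[Residue]
    resolution: float | None = None
    source_chain_ids: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self._by_label: dict[str, Residue] = {}
        for res in list(self.a_chain) + list(self.b_chain):
            if res.insulin_pos:
                self._by_label[res.insulin_pos] = res

    def residue(self, label: str) -> Residue | None:
        """Residue by canonical label, e.g. ``'A8'`` or ``'B19'``."""
        return self._by_label.get(label)

    def residues(self) -> list[Residue]:
        return list(self.a_chain) + list(self.b_chain)

    def labels(self) -> list[str]:
        return [r.insulin_pos for r in self.residues() if r.insulin_pos]

    def coords(self, selection: list[tuple[str, str]]) -> np.ndarray:
        """Stack coordinates for (residue label, atom name) pairs.

        Raises ``KeyError`` on any unresolvable selection entry.
        """
        rows = []
        for label, atom_name in selection:
            res = self.residue(label)
            if res is None:
                raise KeyError(f"residue {label} absent from monomer {self.pdb_id}")
            a = res.atom(atom_name)
            if a is None:
                raise KeyError(f"atom {atom_name} absent from residue {label}")
            rows.append(a.coord)
        return np.array(rows)

    def ca_coords(self, labels: list[str]) -> np.ndarray:
        return self.coords([(lab, "CA") for lab in labels])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "InsulinMonomer":
        """A copy with every atom moved by x -> R x + t."""

        def move(chain: list[Residue]) -> list[Residue]:
            out = []
            for res in chain:
                atoms = [
                    Atom(a.name, a.element, rotation @ a.coord + translation,
                         a.occupancy, a.altloc, a.bfactor)
                    for a in res.atoms
                ]
                out.append(Residue(res.name, res.seq_id, atoms, res.insulin_pos))
            return out

        return InsulinMonomer(
            self.pdb_id, self.model_no, move(self.a_chain), move(self.b_chain),
            self.resolution, self.source_chain_ids,
        )


def chain_labels(chain: str) -> list[str]:
    """Canonical labels of one chain: ``'A'`` -> A1..A21, ``'B'`` -> B1..B30."""
    n = len(A_CHAIN_SEQ) if chain == "A" else len(B_CHAIN_SEQ)
    return [f"{chain}{i}" for i in range(1, n + 1)]


def label_chain(label: str) -> str:
    return label[0]


def label_index(label: str) -> int:
    """1-based position within the chain for a canonical label."""
    return int(label[1:])


def sequence_separation(label_a: str, label_b: str) -> int | None:
    """|i - j| within one chain; None for inter-chain pairs."""
    if label_chain(label_a) != label_chain(label_b):
        return None
    return abs(label_index(label_a) - label_index(label_b))
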