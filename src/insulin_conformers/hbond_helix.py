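"""Backbone hydrogen bonds, helix typing, and the two insulin classifiers.

Hydrogen bonds are scored with the Kabsch-Sander electrostatic model used
by DSSP,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

with a bond recorded when E < -0.5 kcal/mol.  X-ray structures rarely
carry amide hydrogens, so the donor H is reconstructed in the peptide
plane when absent.  One criterion drives everything downstream:

* T/R state: R when the B1-B7 segment is substantially helical (>= 3
  residues typed H or G), otherwise T.
* Class 1 / Class 2: decided by the best (lowest-energy) acceptor of the
  Thr A8 backbone amide — Glu A4 (i,i+4, alpha) is Class 1, Val A3
  (i,i+5, pi-like) is Class 2, Gln A5 (i,i+3) marks a 3-10 geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from insulin_conformers.core import (
    InsulinMonomer,
    Residue,
    label_index,
    sequence_separation,
)
from insulin_conformers.geometry import point_distance

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
KS_Q1Q2_F = 0.084 * 332.0
N_H_LENGTH = 1.01

CLASS_BY_ACCEPTOR = {"A4": "CLASS1", "A3": "CLASS2", "A5": "THREE_TEN"}
TR_HELICAL_MIN = 3  # helical residues in B1-B7 required to call the R state


class ClashError(ValueError):
    """Donor and acceptor groups overlap (distance < 0.5 A)."""


@dataclass
class HBond:
    donor: str
    acceptor: str
    energy: float
    n_o_distance: float


@dataclass
class HBondMap:
    bonds: list[HBond] = field(default_factory=list)
    best_acceptor: dict[str, str] = field(default_factory=dict)

    def bonds_from(self, donor: str) -> list[HBond]:
        return [b for b in self.bonds if b.donor == donor]

    def has_bond(self, donor: str, acceptor: str) -> bool:
        return any(b.donor == donor and b.acceptor == acceptor for b in self.bonds)


@dataclass
class ConformationalClass:
    label: str  # CLASS1 | CLASS2 | THREE_TEN | UNCLASSIFIED
    evidence: str | None = None  # best acceptor of the Thr A8 amide
    reason: str | None = None


@dataclass
class StateLabel:
    label: str  # T | R
    helical_b1_b8_count: int = 0


def place_amide_hydrogen(residue_i: Residue, residue_prev: Residue | None) -> np.ndarray | None:
    """Backbone amide H of ``residue_i``.

    An experimentally present H (atom ``H`` or ``HN``) is reused.
    Otherwise H is built at 1.01 A from N in the C(prev)-N-CA plane along
    the direction opposing the bisector of the C(prev)->N and CA->N bonds.
    Prolines and chain-start residues have no amide H.
    """
    for name in ("H", "HN"):
        h = residue_i.coord(name)
        if h is not None:
            return h
    if residue_i.name == "PRO" or residue_prev is None:
        return None
    n = residue_i.coord("N")
    ca = residue_i.coord("CA")
    c_prev = residue_prev.coord("C")
    if n is None or ca is None or c_prev is None:
        return None
    u1 = (n - c_prev) / np.linalg.norm(n - c_prev)
    u2 = (n - ca) / np.linalg.norm(n - ca)
    b = u1 + u2
    nb = np.linalg.norm(b)
    if nb < 1e-9:
        return None
    return n + N_H_LENGTH * b / nb


def hbond_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy, kcal/mol."""
    r_on = point_distance(o, n)
    r_ch = point_distance(c, h)
    r_oh = point_distance(o, h)
    r_cn = point_distance(c, n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        raise ClashError("donor/acceptor atoms closer than 0.5 A")
    return KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _iter_with_prev(monomer: InsulinMonomer):
    for chain in (monomer.a_chain, monomer.b_chain):
        prev = None
        for res in chain:
            yield res, prev
            prev = res


def backbone_hbond_map(monomer: InsulinMonomer,
                       energy_cutoff: float = HBOND_ENERGY_CUTOFF) -> HBondMap:
    """All backbone donor->acceptor bonds with E below the cutoff.

    Pairs separated by fewer than 2 residues within a chain are excluded;
    inter-chain bonds are allowed.  ``best_acceptor`` keeps, per donor, the
    lowest-energy bond (ties broken by smaller sequence separation, then
    lower residue number).
    """
    donors = []
    for res, prev in _iter_with_prev(monomer):
        if res.insulin_pos is None:
            continue
        h = place_amide_hydrogen(res, prev)
        n = res.coord("N")
        if h is None or n is None:
            continue
        donors.append((res.insulin_pos, n, h))
    acceptors = []
    for res in monomer.residues():
        c, o = res.coord("C"), res.coord("O")
        if res.insulin_pos is None or c is None or o is None:
            continue
        acceptors.append((res.insulin_pos, c, o))

    hmap = HBondMap()
    for dlab, n, h in donors:
        for alab, c, o in acceptors:
            if dlab == alab:
                continue
            sep = sequence_separation(dlab, alab)
            if sep is not None and sep < 2:
                continue
            try:
                e = hbond_energy(n, h, c, o)
            except ClashError:
                continue
            if e < energy_cutoff:
                hmap.bonds.append(HBond(dlab, alab, e, point_distance(n, o)))

    def rank(b: HBond):
        sep = sequence_separation(b.donor, b.acceptor)
        return (b.energy, sep if sep is not None else 10_000, label_index(b.acceptor))

    for dlab, _, _ in donors:
        cand = [b for b in hmap.bonds if b.donor == dlab]
        if cand:
            hmap.best_acceptor[dlab] = min(cand, key=rank).acceptor
    return hmap


def _turn_starts(hmap: HBondMap, labels: list[str], n: int) -> set[int]:
    """Indices i (into ``labels``) where an i -> i+n turn closes, i.e. the
    amide of residue i+n donates to the carbonyl of residue i."""
    out = set()
    for i in range(len(labels) - n):
        if hmap.has_bond(labels[i + n], labels[i]):
            out.add(i)
    return out


def assign_helix_types(monomer: InsulinMonomer,
                       hmap: HBondMap | None = None) -> dict[str, str]:
    """DSSP-style per-residue typing: H (alpha), G (3-10), I (pi), T, C.

    Two consecutive n-turns are required to open a helix (priority
    H > G > I); residues inside any single turn that are otherwise
    unassigned are typed T, everything else C.  Applied per chain.
    """
    if hmap is None:
        hmap = backbone_hbond_map(monomer)
    types: dict[str, str] = {}
    for chain in (monomer.a_chain, monomer.b_chain):
        labels = [r.insulin_pos for r in chain if r.insulin_pos]
        assigned = {lab: "C" for lab in labels}
        turns = {n: _turn_starts(hmap, labels, n) for n in (3, 4, 5)}
        for n, code in ((4, "H"), (3, "G"), (5, "I")):
            for i in sorted(turns[n]):
                if i - 1 in turns[n] or i + 1 in turns[n]:
                    if i + 1 in turns[n]:
                        span = range(i + 1, i + n + 1)
                    else:
                        span = range(i, i + n)
                    for j in span:
                        if 0 <= j < len(labels) and assigned[labels[j]] == "C":
                            assigned[labels[j]] = code
        for n in (3, 4, 5):
            for i in turns[n]:
                for j in range(i + 1, i + n):
                    if j < len(labels) and assigned[labels[j]] == "C":
                        assigned[labels[j]] = "T"
        types.update(assigned)
    return types


def classify_tr_state(monomer: InsulinMonomer,
                      helix_types: dict[str, str] | None = None,
                      helical_min: int = TR_HELICAL_MIN) -> StateLabel:
    """T/R state from helicity of the B-chain N-terminal segment.

    R when at least ``helical_min`` residues among B1-B7 are typed H or G
    (the N-terminal alpha-helical extension of the B8-B20 helix); T
    otherwise.
    """
    if helix_types is None:
        helix_types = assign_helix_types(monomer)
    segment = [f"B{i}" for i in range(1, 8)]
    missing = [lab for lab in segment if monomer.residue(lab) is None
               or not monomer.residue(lab).has_backbone]
    if missing:
        raise ValueError(f"B1-B7 backbone incomplete ({missing}): T/R state undetermined")
    count = sum(1 for lab in segment if helix_types.get(lab) in ("H", "G"))
    return StateLabel(label="R" if count >= helical_min else "T",
                      helical_b1_b8_count=count)


def classify_a1_helix(monomer: InsulinMonomer,
                      hmap: HBondMap | None = None) -> ConformationalClass:
    """Class 1 / Class 2 from the best acceptor of the Thr A8 backbone amide."""
    a8 = monomer.residue("A8")
    a7 = monomer.residue("A7")
    if a8 is None or a7 is None or a8.coord("N") is None or a8.coord("CA") is None:
        return ConformationalClass("UNCLASSIFIED", reason="A8 donor atoms missing")
    if hmap is None:
        hmap = backbone_hbond_map(monomer)
    acceptor = hmap.best_acceptor.get("A8")
    if acceptor is None:
        return ConformationalClass("UNCLASSIFIED", evidence=None,
                                   reason="no hydrogen bond from the A8 amide")
    label = CLASS_BY_ACCEPTOR.get(acceptor, "UNCLASSIFIED")
    reason = None if label != "UNCLASSIFIED" else f"A8 amide bonds to {acceptor}"
    return ConformationalClass(label, evidence=acceptor, reason=reason)
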