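"""Geometry of the three insulin bridges (A6-A11, A7-B7, A20-B19).

Bridge chemistry is typed from atoms, never from residue names, because
dicarba half-residues are deposited under varying names: a disulfide is
two S-gamma atoms within bonding distance; a dicarba bridge is a
C-beta - C-gamma = C-gamma' - C-beta' four-carbon path with bonded
(< 1.75 A) steps.  Chi dihedrals run along the bridge path from the
lower-numbered residue; the dicarba cis/trans flag comes from the central
C=C torsion (|tau| < 90 deg -> cis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from insulin_conformers.core import BRIDGES, InsulinMonomer, Residue
from insulin_conformers.geometry import dihedral_angle, point_distance

SS_BOND_MAX = 2.5     # S-gamma pair counted as bonded below this
CC_BOND_MAX = 1.75    # carbon-carbon bonded threshold (covers C=C at 1.33)
CIS_TRANS_BOUNDARY = 90.0


class BridgeError(ValueError):
    """Missing bridge residues/atoms or wrong bridge chemistry."""


@dataclass
class BridgeGeometry:
    bridge_id: str                     # A6A11 | A7B7 | A20B19
    bridge_type: str                   # disulfide | dicarba | other
    ca_ca: float                       # Calpha-Calpha, Angstrom
    sg_sg: float | None = None         # disulfide only
    chi: tuple[float, ...] = ()        # chi1, chi2, chi3, chi2', chi1'
    cis_trans: str = "n/a"             # dicarba only: cis | trans


@dataclass
class ConformerLabel:
    signs: tuple[str, str, str]        # signs of chi1, chi3 (core), chi1'
    core_bin: int                      # chi3 binned to the nearest 30 deg

    @property
    def text(self) -> str:
        return "".join(self.signs) + f"@{self.core_bin:+d}"


def _gamma_atom(res: Residue) -> np.ndarray | None:
    """Bridge gamma carbon of a dicarba half-residue: a carbon bonded to
    C-beta that is neither backbone nor C-beta itself."""
    cb = res.coord("CB")
    if cb is None:
        return None
    backbone = {"N", "CA", "C", "O", "CB"}
    for a in res.atoms:
        if a.name in backbone or a.element != "C":
            continue
        if point_distance(a.coord, cb) < CC_BOND_MAX:
            return a.coord
    return None


def extract_bridge_geometry(monomer: InsulinMonomer, bridge_id: str) -> BridgeGeometry:
    """Distances, chi dihedrals and cis/trans flag of one bridge."""
    if bridge_id not in BRIDGES:
        raise BridgeError(f"unknown bridge id {bridge_id!r}")
    lab1, lab2 = BRIDGES[bridge_id]
    r1, r2 = monomer.residue(lab1), monomer.residue(lab2)
    missing = [lab for lab, r in ((lab1, r1), (lab2, r2)) if r is None]
    if missing:
        raise BridgeError(f"bridge {bridge_id}: residues missing {missing}")
    ca1, ca2 = r1.coord("CA"), r2.coord("CA")
    if ca1 is None or ca2 is None:
        raise BridgeError(f"bridge {bridge_id}: Calpha atoms missing")
    ca_ca = point_distance(ca1, ca2)

    sg1, sg2 = r1.coord("SG"), r2.coord("SG")
    if sg1 is not None and sg2 is not None and point_distance(sg1, sg2) < SS_BOND_MAX:
        n1, cb1 = r1.coord("N"), r1.coord("CB")
        n2, cb2 = r2.coord("N"), r2.coord("CB")
        chi: tuple[float, ...] = ()
        if all(x is not None for x in (n1, cb1, n2, cb2)):
            chi = (
                dihedral_angle(n1, ca1, cb1, sg1),
                dihedral_angle(ca1, cb1, sg1, sg2),
                dihedral_angle(cb1, sg1, sg2, cb2),
                dihedral_angle(sg1, sg2, cb2, ca2),
                dihedral_angle(sg2, cb2, ca2, n2),
            )
        return BridgeGeometry(bridge_id, "disulfide", ca_ca,
                              sg_sg=point_distance(sg1, sg2), chi=chi)

    g1, g2 = _gamma_atom(r1), _gamma_atom(r2)
    if g1 is not None and g2 is not None and point_distance(g1, g2) < CC_BOND_MAX:
        cb1, cb2 = r1.coord("CB"), r2.coord("CB")
        n1, n2 = r1.coord("N"), r2.coord("N")
        tau = dihedral_angle(cb1, g1, g2, cb2)
        chi = (
            dihedral_angle(n1, ca1, cb1, g1),
            dihedral_angle(ca1, cb1, g1, g2),
            tau,
            dihedral_angle(g1, g2, cb2, ca2),
            dihedral_angle(g2, cb2, ca2, n2),
        )
        flag = "cis" if abs(tau) < CIS_TRANS_BOUNDARY else "trans"
        return BridgeGeometry(bridge_id, "dicarba", ca_ca, sg_sg=None,
                              chi=chi, cis_trans=flag)

    if (sg1 is None) != (sg2 is None):
        raise BridgeError(
            f"bridge {bridge_id}: S-gamma present on one residue only")
    return BridgeGeometry(bridge_id, "other", ca_ca)


def disulfide_conformer_label(geom: BridgeGeometry) -> ConformerLabel:
    """Sign-bin conformer label of a disulfide from (chi1, chi3, chi1').

    Signs use the convention that a torsion of exactly 0 deg bins as '+';
    the core chi3 is additionally binned to the nearest 30 deg so that
    left- and right-handed (-90 / +90) disulfides are distinct.
    """
    if geom.bridge_type != "disulfide":
        raise BridgeError("conformer labels are defined for disulfides only")
    if len(geom.chi) != 5:
        raise BridgeError("all five chi dihedrals required")
    chi1, _, chi3, _, chi1p = geom.chi
    signs = tuple("+" if c >= 0.0 else "-" for c in (chi1, chi3, chi1p))
    core_bin = int(round(chi3 / 30.0)) * 30
    return ConformerLabel(signs=signs, core_bin=core_bin)
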