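"""Synthetic insulin-like structures built from backbone torsions.

Purpose: every analysis stage in this package must be testable without
downloading crystal structures.  The generator builds two-chain toys whose
A-chain N-terminal helix is either a pure alpha-helix (Class 1) or one
alpha turn followed by a pi-widened segment (Class 2), places the three
bridges (disulfide or cis/trans dicarba at A6-A11), adds Gaussian
coordinate noise, and emits multi-model ensembles with known class
mixtures.

Backbones come from a natural-extension reference-frame (NeRF)
construction with canonical peptide geometry (N-CA 1.458 A, CA-C 1.525 A,
C-N 1.329 A, omega 180 deg), so recomputing (phi, psi, omega) from the
output reproduces the input torsions to numerical precision.  The loop
torsions A10-A12 and the rigid placement of the B chain are solved by
least squares so that bridge distances hit the construction targets;
bridge atoms (S-gamma or the dicarba C-gamma pair) are then solved from
ideal bond lengths and angles.  Side chains are reduced to C-beta plus the
bridge atoms: classification never looks further.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from insulin_conformers.core import (
    A_CHAIN_SEQ,
    B_CHAIN_SEQ,
    Atom,
    InsulinMonomer,
    Residue,
)
from insulin_conformers.geometry import dihedral_angle
from insulin_conformers.hbond_helix import place_amide_hydrogen

# canonical backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# torsion presets: (phi, psi)
ALPHA = (-57.0, -47.0)
THREE_TEN = (-49.0, -26.0)
PI = (-57.0, -70.0)
STRAND = (-120.0, 130.0)
# toy A-chain N-terminal helix torsions, chosen to maximise the energy
# margin of the defining Thr A8 hydrogen bond over competing acceptors so
# classification stays stable under coordinate noise
CLASS1_HELIX = (-54.5, -56.5)
CLASS2_PI = (-57.0, -70.0)

# bridge construction geometry
SS_BOND = 2.04          # S-gamma to S-gamma
CB_SG = 1.81
ANGLE_CB_S_S = 104.0
CC_DOUBLE = 1.33        # dicarba C-gamma = C-gamma
CB_CG = 1.50
ANGLE_CB_CG_CG = 124.0

# Calpha A6-A11 construction targets (Angstrom) per (class, bridge):
# the disulfide values are the crystal-survey class means, the trans
# dicarba value is the trans-isomer crystal distance, and the cis Class 2
# value matches the shorter distances seen for cis-bridged active
# conformers; the remaining combinations use the nearest geometrically
# reachable analogue of their class value.
CA_TARGET = {
    ("CLASS1", "disulfide"): 4.78,
    ("CLASS2", "disulfide"): 4.55,
    ("CLASS1", "trans_dicarba"): 5.17,
    ("CLASS2", "trans_dicarba"): 4.90,
    ("CLASS1", "cis_dicarba"): 4.55,
    ("CLASS2", "cis_dicarba"): 4.05,
}
# Calpha A7-B7 targets by class: Class 2 sits slightly further from B7
A7B7_TARGET = {"CLASS1": 4.62, "CLASS2": 4.76}
DISULFIDE_CHI3 = -85.0  # preferred core torsion for synthetic disulfides

DICARBA_RESNAME = "ASU"  # 2-aminosuberic half-residue stand-in at A6/A11


class ConstructionError(RuntimeError):
    """Bridge closure or torsion solve failed to converge."""


@dataclass
class SyntheticSpec:
    """Record of what a synthetic structure is, written to sidecar JSON."""

    kind: str
    length: int | None = None
    mixture: dict[str, float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    bridge_variant: str = "disulfide"

    def to_json(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as requested."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ConstructionError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def pseudo_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealised L-amino-acid C-beta from the backbone frame."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


def build_backbone(sequence: str, torsions: list[tuple[float, float, float]]) -> list[Residue]:
    """Build N/CA/C/O (+CB for non-Gly) residues from per-residue
    (phi, psi, omega).

    phi of the first residue and omega "into" the first residue are not
    used; psi/omega of the last residue only position its carbonyl oxygen.
    """
    nres = len(sequence)
    if nres < 2:
        raise ValueError("need at least 2 residues")
    if len(torsions) != nres:
        raise ValueError("one (phi, psi, omega) triple per residue required")
    if not all(np.isfinite(t) for tri in torsions for t in tri):
        raise ValueError("torsions must be finite")

    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    c_xyz = [ca_xyz[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]

    for i in range(1, nres):
        phi, _, _ = torsions[i]
        _, psi_prev, _ = torsions[i - 1]
        _, _, omega_prev = torsions[i]  # omega of the bond into residue i
        n_i = place_atom(n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(ca_xyz[i - 1], c_xyz[i - 1], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        c_i = place_atom(c_xyz[i - 1], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        n_xyz.append(n_i)
        ca_xyz.append(ca_i)
        c_xyz.append(c_i)

    residues = []
    for i, aa in enumerate(sequence):
        psi_i = torsions[i][1]
        if i < nres - 1:
            o_i = place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                             BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0)
        else:
            o_i = place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                             BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0)
        atoms = [
            Atom("N", "N", n_xyz[i]),
            Atom("CA", "C", ca_xyz[i]),
            Atom("C", "C", c_xyz[i]),
            Atom("O", "O", o_i),
        ]
        if aa != "G":
            atoms.append(Atom("CB", "C", pseudo_cbeta(n_xyz[i], ca_xyz[i], c_xyz[i])))
        residues.append(Residue(name=_three_letter(aa), seq_id=i + 1, atoms=atoms))
    return residues


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _three_letter(aa: str) -> str:
    return _ONE_TO_THREE.get(aa, "UNK")


def measure_torsions(residues: list[Residue]) -> list[tuple[float, float, float]]:
    """Recover (phi, psi, omega) from coordinates; inverse of build_backbone
    where defined (NaN elsewhere)."""
    out = []
    for i, res in enumerate(residues):
        phi = psi = omega = float("nan")
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        if i > 0:
            prev = residues[i - 1]
            phi = dihedral_angle(prev.coord("C"), n, ca, c)
            omega = dihedral_angle(prev.coord("CA"), prev.coord("C"), n, ca)
        if i < len(residues) - 1:
            psi = dihedral_angle(n, ca, c, residues[i + 1].coord("N"))
        out.append((phi, psi, omega))
    return out


def build_ideal_helix(kind: str = "alpha", length: int = 12,
                      sequence: str | None = None) -> list[Residue]:
    """An ideal helix (or strand) fixture: 'alpha', 'three_ten', 'pi', 'strand'."""
    presets = {"alpha": ALPHA, "three_ten": THREE_TEN, "pi": PI, "strand": STRAND}
    if kind not in presets:
        raise ValueError(f"unknown helix kind {kind!r}")
    phi, psi = presets[kind]
    seq = sequence if sequence is not None else "A" * length
    return build_backbone(seq, [(phi, psi, 180.0)] * len(seq))


# ---------------------------------------------------------------------------
# bridge atom solvers


def _angle(a, b, c) -> float:
    v1, v2 = a - b, c - b
    return float(np.degrees(np.arccos(np.clip(
        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))))


def _ideal_fragment(b_outer: float, b_inner: float, angle: float,
                    torsion: float) -> np.ndarray:
    """Four-atom bridge fragment X1-Y1-Y2-X2 in a local frame, with outer
    bonds ``b_outer``, central bond ``b_inner``, both X-Y-Y angles equal to
    ``angle`` and the X1-Y1-Y2-X2 torsion fixed."""
    a = np.radians(angle)
    x1 = np.zeros(3)
    y1 = np.array([b_outer, 0.0, 0.0])
    y2 = y1 + b_inner * np.array([-np.cos(a), np.sin(a), 0.0])
    x2 = place_atom(x1, y1, y2, b_outer, angle, torsion)
    return np.array([x1, y1, y2, x2])


def bridge_span(b_outer: float, b_inner: float, angle: float, torsion: float) -> float:
    """End-to-end C-beta separation implied by ideal bridge geometry."""
    frag = _ideal_fragment(b_outer, b_inner, angle, torsion)
    return float(np.linalg.norm(frag[3] - frag[0]))


# C-beta separations each bridge chemistry spans with ideal geometry;
# for a dicarba bridge the fixed C=C torsion determines the span exactly
CB_TARGET = {
    "disulfide": bridge_span(CB_SG, SS_BOND, ANGLE_CB_S_S, DISULFIDE_CHI3),
    "cis_dicarba": bridge_span(CB_CG, CC_DOUBLE, ANGLE_CB_CG_CG, 0.0),
    "trans_dicarba": bridge_span(CB_CG, CC_DOUBLE, ANGLE_CB_CG_CG, 180.0),
}


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    c = float(u @ v)
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        k = np.cross(u, p)
        k /= np.linalg.norm(k)
        return 2.0 * np.outer(k, k) - np.eye(3)
    kx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + kx + kx @ kx * ((1 - c) / s**2)


def _seed_bridge(cb1: np.ndarray, cb2: np.ndarray, frag: np.ndarray,
                 perp_seed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly place the ideal fragment between the actual C-betas.

    The end-to-end direction is aligned exactly; the residual spin about
    that axis is fixed by pointing the first inner atom toward
    ``perp_seed`` (projected off-axis), making the construction
    deterministic.
    """
    axis = cb2 - cb1
    d = np.linalg.norm(axis)
    axis = axis / d
    v_ideal = frag[3] - frag[0]
    rot = _rotation_aligning(v_ideal / np.linalg.norm(v_ideal), axis)
    y1 = rot @ (frag[1] - frag[0])
    y2 = rot @ (frag[2] - frag[0])
    p = perp_seed - (perp_seed @ axis) * axis
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(axis, np.array([0.12, 0.94, 0.32]))
    p /= np.linalg.norm(p)
    y1p = y1 - (y1 @ axis) * axis
    if np.linalg.norm(y1p) > 1e-9:
        y1p_n = y1p / np.linalg.norm(y1p)
        cosang = np.clip(float(y1p_n @ p), -1.0, 1.0)
        sign = np.sign(np.cross(y1p_n, p) @ axis) or 1.0
        theta = sign * np.arccos(cosang)
        k = axis
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        spin = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
        y1, y2 = spin @ y1, spin @ y2
    return cb1 + y1, cb1 + y2


def _polish_bridge(cb1, cb2, m1_0, m2_0, b_outer, b_inner, angle,
                   torsion, torsion_weight) -> tuple[np.ndarray, np.ndarray]:
    def residuals(x):
        m1, m2 = x[:3], x[3:]
        r = [
            np.linalg.norm(cb1 - m1) - b_outer,
            np.linalg.norm(cb2 - m2) - b_outer,
            np.linalg.norm(m1 - m2) - b_inner,
            (_angle(cb1, m1, m2) - angle) / 30.0,
            (_angle(m1, m2, cb2) - angle) / 30.0,
        ]
        try:
            tau = dihedral_angle(cb1, m1, m2, cb2)
            d = (tau - torsion + 180.0) % 360.0 - 180.0
            r.append(torsion_weight * d / 30.0)
        except Exception:
            r.append(1.0)
        return r

    sol = least_squares(residuals, np.concatenate([m1_0, m2_0]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.max(np.abs(sol.fun[:5])) > 2e-3:
        raise ConstructionError(
            "bridge closure failed for C-beta separation "
            f"{np.linalg.norm(cb2 - cb1):.2f} A (residual "
            f"{np.max(np.abs(sol.fun[:5])):.1e})")
    return sol.x[:3].copy(), sol.x[3:].copy()


def solve_disulfide(cb1: np.ndarray, cb2: np.ndarray, ca1: np.ndarray,
                    ss_length: float = SS_BOND,
                    chi3_target: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Place the two S-gamma atoms of a disulfide between fixed C-betas.

    Five hard constraints (the two C-beta/S bonds, the S-S bond, the two
    C-beta-S-S angles) leave one rotational degree of freedom: the core
    chi3 torsion.  With ``chi3_target=None`` the left-handed chi3 whose
    ideal span matches the actual C-beta separation is chosen (preferring
    the canonical value where the separation allows), making the
    construction deterministic for any feasible separation.
    """
    d = float(np.linalg.norm(cb2 - cb1))
    if chi3_target is None:
        # the span is monotone in |chi3| on the negative branch: bisect
        # for the chi3 whose ideal span equals the actual separation
        lo, hi = -178.0, -8.0
        span_lo = bridge_span(CB_SG, ss_length, ANGLE_CB_S_S, lo)
        span_hi = bridge_span(CB_SG, ss_length, ANGLE_CB_S_S, hi)
        if d >= span_lo:
            chi3_target = lo
        elif d <= span_hi:
            chi3_target = hi
        else:
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if bridge_span(CB_SG, ss_length, ANGLE_CB_S_S, mid) > d:
                    lo = mid
                else:
                    hi = mid
            chi3_target = 0.5 * (lo + hi)
            if bridge_span(CB_SG, ss_length, ANGLE_CB_S_S,
                           DISULFIDE_CHI3) <= d <= span_lo \
                    and abs(chi3_target - DISULFIDE_CHI3) < 0.5:
                chi3_target = DISULFIDE_CHI3
    frag = _ideal_fragment(CB_SG, ss_length, ANGLE_CB_S_S, chi3_target)
    s1_0, s2_0 = _seed_bridge(cb1, cb2, frag, ca1 - cb1)
    # the span-matched rigid seed is already exact up to the bisection
    # tolerance; skip the polish when its residuals are negligible
    err = max(
        abs(np.linalg.norm(cb1 - s1_0) - CB_SG),
        abs(np.linalg.norm(cb2 - s2_0) - CB_SG),
        abs(np.linalg.norm(s1_0 - s2_0) - ss_length),
        abs(_angle(cb1, s1_0, s2_0) - ANGLE_CB_S_S) / 30.0,
        abs(_angle(s1_0, s2_0, cb2) - ANGLE_CB_S_S) / 30.0,
    )
    if err < 5e-4:
        return s1_0, s2_0
    return _polish_bridge(cb1, cb2, s1_0, s2_0, CB_SG, ss_length,
                          ANGLE_CB_S_S, chi3_target, torsion_weight=0.02)


def solve_dicarba(cb1: np.ndarray, cb2: np.ndarray, torsion: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Place the C-gamma pair of a dicarba (C=C) bridge with the
    CB-CG=CG'-CB' torsion fixed at 0 (cis) or 180 (trans)."""
    frag = _ideal_fragment(CB_CG, CC_DOUBLE, ANGLE_CB_CG_CG, torsion)
    g1_0, g2_0 = _seed_bridge(cb1, cb2, frag, np.array([0.12, 0.94, 0.32]))
    return _polish_bridge(cb1, cb2, g1_0, g2_0, CB_CG, CC_DOUBLE,
                          ANGLE_CB_CG_CG, torsion, torsion_weight=1.0)


# ---------------------------------------------------------------------------
# class toys


def _a_chain_torsions(class_label: str) -> list[tuple[float, float, float]]:
    """Torsion plan for the 21-residue A chain.

    Class 1: A1-A9 alpha.  Class 2: one alpha turn A1-A3, then a pi-widened
    A4-A9 segment — chosen so the Thr A8 amide's best acceptor is the Val A3
    carbonyl (the defining observable), not to match any particular
    deposited geometry.  A10-A12 are loop placeholders later refined to
    close the A6-A11 bridge; A13-A19 form the second A-chain helix.
    """
    t: list[tuple[float, float, float]] = []
    for i in range(1, 22):
        if i <= 9:
            if class_label == "CLASS1":
                phi, psi = CLASS1_HELIX
            elif i <= 3:
                phi, psi = ALPHA
            else:
                phi, psi = CLASS2_PI
        elif i <= 12:
            phi, psi = (-90.0, 60.0)  # loop seed, refined below
        elif i <= 19:
            phi, psi = ALPHA
        else:
            phi, psi = (-120.0, 140.0)
        t.append((phi, psi, 180.0))
    return t


def _b_chain_torsions(b_state: str) -> list[tuple[float, float, float]]:
    t: list[tuple[float, float, float]] = []
    for i in range(1, 31):
        if b_state == "R" and i <= 19:
            phi, psi = ALPHA
        elif i <= 8:
            phi, psi = STRAND
        elif i <= 19:
            phi, psi = ALPHA
        else:
            phi, psi = (-100.0, 120.0)
        t.append((phi, psi, 180.0))
    return t


def _solve_a_loop(torsions: list[tuple[float, float, float]],
                  ca_target: float, cb_target: float) -> list[list[Residue]]:
    """Solve (phi/psi A9, phi/psi A10, phi A11) so the A6-A11 Calpha and
    C-beta separations close the bridge; return all distinct solutions.

    Only these torsions move the A11 Calpha/C-beta relative to A6; the
    A1-A9 amide ladder that defines the class is untouched (phi A9 is
    weakly regularised toward its helical value, and the amide hydrogen
    of A9 does not depend on it).  The residual is evaluated by
    incremental NeRF extension from the fixed A1-A9 prefix, so the solve
    is fast and deterministic.  Several distinct loop conformations can
    close the same bridge; the caller picks the first one for which the
    rest of the assembly (B-chain placement, bridge atoms) also closes.
    """
    prefix = build_backbone(A_CHAIN_SEQ[:9], torsions[:9])
    n9, ca9 = prefix[8].coord("N"), prefix[8].coord("CA")
    c8 = prefix[7].coord("C")
    ca6, cb6 = prefix[5].coord("CA"), prefix[5].coord("CB")
    phi9_0 = torsions[8][0]

    def extend(x):
        phi9, psi9, phi10, psi10, phi11 = x
        c9 = place_atom(c8, n9, ca9, BOND_CA_C, ANGLE_N_CA_C, phi9)
        n10 = place_atom(n9, ca9, c9, BOND_C_N, ANGLE_CA_C_N, psi9)
        ca10 = place_atom(ca9, c9, n10, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c10 = place_atom(c9, n10, ca10, BOND_CA_C, ANGLE_N_CA_C, phi10)
        n11 = place_atom(n10, ca10, c10, BOND_C_N, ANGLE_CA_C_N, psi10)
        ca11 = place_atom(ca10, c10, n11, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c11 = place_atom(c10, n11, ca11, BOND_CA_C, ANGLE_N_CA_C, phi11)
        return ca11, pseudo_cbeta(n11, ca11, c11)

    def resid(x):
        ca11, cb11 = extend(x)
        d_ca = np.linalg.norm(ca6 - ca11)
        d_cb = np.linalg.norm(cb6 - cb11)
        return [d_ca - ca_target, d_cb - cb_target,
                0.003 * ((x[0] - phi9_0 + 180.0) % 360.0 - 180.0)]

    x0 = np.array([phi9_0, torsions[8][1], torsions[9][0],
                   torsions[9][1], torsions[10][0]])
    rng = np.random.default_rng(20200101)  # construction-time seed, fixed
    # coarse scan first: the feasible set can be a thin manifold, so seed
    # the local solver from the best scan points rather than blind starts
    cand = np.column_stack([
        phi9_0 + rng.uniform(-30.0, 30.0, 3000),
        rng.uniform(-180.0, 180.0, (3000, 4)),
    ])
    scores = np.array([np.hypot(*resid(c)[:2]) for c in cand])
    order = np.argsort(scores)[:16]
    solutions: list[np.ndarray] = []
    for s in [x0] + [cand[i] for i in order]:
        sol = least_squares(resid, s, xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, diff_step=1e-7)
        if np.max(np.abs(sol.fun[:2])) > 2e-3:
            continue
        key = np.round(sol.x, 1)
        if any(np.allclose(key, np.round(prev, 1)) for prev in solutions):
            continue
        solutions.append(sol.x)
    if not solutions:
        raise ConstructionError("A-chain loop closure failed")
    # prefer the solution that perturbs phi(A9) least
    solutions.sort(key=lambda x: abs((x[0] - phi9_0 + 180.0) % 360.0 - 180.0))
    out = []
    for x in solutions:
        phi9, psi9, phi10, psi10, phi11 = (float(v) for v in x)
        t = list(torsions)
        t[8] = (phi9, psi9, 180.0)
        t[9] = (phi10, psi10, 180.0)
        t[10] = (phi11, t[10][1], 180.0)
        out.append(build_backbone(A_CHAIN_SEQ, t))
    return out


def _place_b_chain(a_res: list[Residue], b_res: list[Residue],
                   a7b7_ca_target: float, cb_bridge_target: float
                   ) -> list[Residue]:
    """Rigid-body placement of the B chain to close the two inter-chain
    bridges without steric overlap.

    Targets: Calpha A7-B7 at the class value, C-beta separations at A7-B7
    and A20-B19 spannable by a disulfide, plus a soft clash penalty on
    Calpha pairs closer than 4 A.
    """
    ca_a = np.array([r.coord("CA") for r in a_res])
    a7_ca, a7_cb = a_res[6].coord("CA"), a_res[6].coord("CB")
    a20_cb = a_res[19].coord("CB")
    b_n = np.array([r.coord("N") for r in b_res])
    b_ca = np.array([r.coord("CA") for r in b_res])
    b_c = np.array([r.coord("C") for r in b_res])
    b7_i, b19_i = 6, 18
    b_center = b_ca.mean(axis=0)

    def transform(x):
        rotvec, trans = x[:3], x[3:]
        theta = np.linalg.norm(rotvec)
        if theta < 1e-12:
            rot = np.eye(3)
        else:
            k = rotvec / theta
            kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
        return rot, trans

    def resid(x):
        rot, trans = transform(x)
        ca = (b_ca - b_center) @ rot.T + trans
        n7 = (b_n[b7_i] - b_center) @ rot.T + trans
        c7 = (b_c[b7_i] - b_center) @ rot.T + trans
        cb7 = pseudo_cbeta(n7, ca[b7_i], c7)
        n19 = (b_n[b19_i] - b_center) @ rot.T + trans
        c19 = (b_c[b19_i] - b_center) @ rot.T + trans
        cb19 = pseudo_cbeta(n19, ca[b19_i], c19)
        hard = [
            np.linalg.norm(ca[b7_i] - a7_ca) - a7b7_ca_target,
            np.linalg.norm(cb7 - a7_cb) - cb_bridge_target,
            np.linalg.norm(cb19 - a20_cb) - CB_TARGET["disulfide"],
        ]
        # soft clash on Calpha-Calpha pairs, excluding the bridge residues
        d = np.linalg.norm(ca_a[:, None, :] - ca[None, :, :], axis=2)
        d[6, b7_i] = 99.0
        d[19, b19_i] = 99.0
        clash = 0.3 * np.clip(4.0 - d, 0.0, None).ravel()
        return np.concatenate([hard, clash])

    def hard_error(x):
        return float(np.max(np.abs(resid(x)[:3])))

    rng = np.random.default_rng(20200202)  # construction-time seed, fixed
    best = None
    starts = [np.concatenate([rng.uniform(-np.pi, np.pi, 3),
                              rng.uniform(-12.0, 12.0, 3)]) for _ in range(40)]
    for x0 in starts:
        sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                            diff_step=1e-5)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if hard_error(best.x) > 5e-3:
        raise ConstructionError(
            f"B-chain placement failed (residual {best.cost:.2e})")
    rot, trans = transform(best.x)
    out = []
    for r in b_res:
        atoms = [Atom(a.name, a.element, (a.coord - b_center) @ rot.T + trans,
                      a.occupancy, a.altloc, a.bfactor) for a in r.atoms]
        out.append(Residue(r.name, r.seq_id, atoms, r.insulin_pos))
    return out


@functools.lru_cache(maxsize=16)
def _base_toy(class_label: str, bridge_variant: str, b_state: str) -> InsulinMonomer:
    """Noiseless toy for a (class, bridge, B-state) combination; cached
    because the torsion/placement solves are the expensive step."""
    if class_label not in ("CLASS1", "CLASS2"):
        raise ValueError(f"unknown class label {class_label!r}")
    if bridge_variant not in CB_TARGET:
        raise ValueError(f"unknown bridge variant {bridge_variant!r}")

    ca_target = CA_TARGET[(class_label, bridge_variant)]
    torsions = _a_chain_torsions(class_label)
    if bridge_variant == "disulfide":
        # the free chi3 lets a disulfide span a range of C-beta separations;
        # try the canonical span first, then neighbours
        cb_candidates = (CB_TARGET["disulfide"], 3.9, 3.6, 4.1, 3.45)
    else:
        cb_candidates = (CB_TARGET[bridge_variant],)

    b_raw = build_backbone(B_CHAIN_SEQ, _b_chain_torsions(b_state))
    last_exc: Exception | None = None
    for cb_t in cb_candidates:
        try:
            loop_solutions = _solve_a_loop(torsions, ca_target, cb_t)
        except ConstructionError as exc:
            last_exc = exc
            continue
        for a_res in loop_solutions:
            try:
                return _assemble_toy(class_label, bridge_variant, a_res, b_raw)
            except ConstructionError as exc:
                last_exc = exc
    raise ConstructionError(
        f"could not assemble {class_label}/{bridge_variant} toy") from last_exc


def add_amide_hydrogens(residues: list[Residue]) -> None:
    """Attach explicit backbone amide hydrogens (skipping chain starts and
    prolines), as MD-frame ensembles carry them; the classifier trusts
    file hydrogens over reconstruction."""
    prev = None
    for res in residues:
        if prev is not None and res.atom("H") is None:
            h = place_amide_hydrogen(res, prev)
            if h is not None:
                res.atoms.append(Atom("H", "H", h))
        prev = res


def _assemble_toy(class_label: str, bridge_variant: str,
                  a_res: list[Residue], b_raw: list[Residue]) -> InsulinMonomer:
    b_res = _place_b_chain(a_res, b_raw, A7B7_TARGET[class_label],
                           CB_TARGET["disulfide"])
    for i, r in enumerate(a_res):
        r.insulin_pos = f"A{i + 1}"
    for i, r in enumerate(b_res):
        r.insulin_pos = f"B{i + 1}"

    # A6-A11 bridge per variant
    cb6, cb11 = a_res[5].coord("CB"), a_res[10].coord("CB")
    if bridge_variant == "disulfide":
        s1, s2 = solve_disulfide(cb6, cb11, a_res[5].coord("CA"))
        a_res[5].atoms.append(Atom("SG", "S", s1))
        a_res[10].atoms.append(Atom("SG", "S", s2))
    else:
        tau = 0.0 if bridge_variant == "cis_dicarba" else 180.0
        g1, g2 = solve_dicarba(cb6, cb11, tau)
        a_res[5].atoms.append(Atom("CG", "C", g1))
        a_res[10].atoms.append(Atom("CG", "C", g2))
        a_res[5].name = DICARBA_RESNAME
        a_res[10].name = DICARBA_RESNAME

    # inter-chain disulfides
    for (ra, rb) in ((a_res[6], b_res[6]), (a_res[19], b_res[18])):
        s1, s2 = solve_disulfide(ra.coord("CB"), rb.coord("CB"), ra.coord("CA"))
        ra.atoms.append(Atom("SG", "S", s1))
        rb.atoms.append(Atom("SG", "S", s2))

    add_amide_hydrogens(a_res)
    add_amide_hydrogens(b_res)

    return InsulinMonomer(
        pdb_id=f"SY{class_label[-1]}{bridge_variant[0].upper()}",
        model_no=1, a_chain=a_res, b_chain=b_res,
        resolution=1.50, source_chain_ids=("A", "B"),
    )


def perturb(coords: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """I.i.d. Gaussian displacement of every coordinate; sigma=0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    coords = np.asarray(coords, float)
    if sigma == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, sigma, size=coords.shape)


def _perturb_monomer(m: InsulinMonomer, sigma: float, seed: int) -> InsulinMonomer:
    atoms = [a for r in m.residues() for a in r.atoms]
    xyz = np.array([a.coord for a in atoms])
    new = perturb(xyz, sigma, seed)

    # rebuild with new coordinates, preserving residue/atom metadata
    new_chains = []
    k = 0
    for chain in (m.a_chain, m.b_chain):
        rebuilt = []
        for r in chain:
            new_atoms = []
            for a in r.atoms:
                new_atoms.append(Atom(a.name, a.element, new[k], a.occupancy,
                                      a.altloc, a.bfactor))
                k += 1
            rebuilt.append(Residue(r.name, r.seq_id, new_atoms, r.insulin_pos))
        new_chains.append(rebuilt)
    return InsulinMonomer(m.pdb_id, m.model_no, new_chains[0], new_chains[1],
                          m.resolution, m.source_chain_ids)


def _reidealize_bridges(m: InsulinMonomer, bridge_variant: str) -> None:
    """Restore ideal covalent bridge geometry after coordinate noise.

    Crystallographic refinement restrains covalent bonds, so uncorrelated
    coordinate noise must not stretch the S-gamma-S-gamma (or dicarba C=C)
    bond: the bridge atoms are re-solved from the perturbed C-betas.  If a
    perturbation pushes the C-beta separation outside the feasible span
    the noisy coordinates are kept as-is (an unrestrained, poorly modelled
    bridge, which the curation filter may then reject).
    """
    pairs = [("A7", "B7"), ("A20", "B19")]
    if bridge_variant == "disulfide":
        pairs.insert(0, ("A6", "A11"))
    else:
        r1, r2 = m.residue("A6"), m.residue("A11")
        tau = 0.0 if bridge_variant == "cis_dicarba" else 180.0
        try:
            g1, g2 = solve_dicarba(r1.coord("CB"), r2.coord("CB"), tau)
            r1.atom("CG").coord = g1
            r2.atom("CG").coord = g2
        except ConstructionError:
            pass
    for lab1, lab2 in pairs:
        r1, r2 = m.residue(lab1), m.residue(lab2)
        try:
            s1, s2 = solve_disulfide(r1.coord("CB"), r2.coord("CB"),
                                     r1.coord("CA"))
            r1.atom("SG").coord = s1
            r2.atom("SG").coord = s2
        except ConstructionError:
            pass


def build_class_toy(class_label: str, bridge_variant: str = "disulfide",
                    noise_sigma: float = 0.0, seed: int = 0,
                    b_state: str = "T") -> InsulinMonomer:
    """A two-chain insulin toy of the requested conformational class.

    At ``noise_sigma=0`` the toy classifies as the requested class, the
    B1-B7 segment matches the requested T/R state, and the A6-A11 bridge
    matches ``bridge_variant`` (disulfide, cis_dicarba or trans_dicarba).
    Noise is i.i.d. Gaussian per coordinate, after which bridge covalent
    geometry is re-idealised (refinement restrains bonds).  Deterministic
    given ``seed``.
    """
    base = _base_toy(class_label, bridge_variant, b_state)
    if noise_sigma == 0:
        return _perturb_monomer(base, 0.0, seed)  # deep copy
    m = _perturb_monomer(base, noise_sigma, seed)
    _reidealize_bridges(m, bridge_variant)
    return m


def build_ensemble(mixture: dict[str, float], n_frames: int,
                   noise_sigma: float = 0.0, seed: int = 0,
                   bridge_variant: str = "disulfide"
                   ) -> tuple[list[InsulinMonomer], list[str]]:
    """Multi-frame ensemble drawn i.i.d. from a class mixture.

    Returns (frames, true_labels); labels let tests score recovered class
    fractions against the generating truth.  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    labels = sorted(mixture)
    probs = np.array([mixture[k] for k in labels], float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(labels), size=n_frames, p=probs)
    frames, truth = [], []
    for i, d in enumerate(draws):
        lab = labels[d]
        m = build_class_toy(lab, bridge_variant=bridge_variant,
                            noise_sigma=noise_sigma,
                            seed=int(rng.integers(0, 2**31 - 1)))
        m = InsulinMonomer(m.pdb_id, i + 1, m.a_chain, m.b_chain,
                           m.resolution, m.source_chain_ids)
        frames.append(m)
        truth.append(lab)
    return frames, truth


# ---------------------------------------------------------------------------
# PDB output


def _format_atom_line(serial: int, atom: Atom, res: Residue, chain_id: str,
                      hetatm: bool) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    rec = "HETATM" if hetatm else "ATOM  "
    x, y, z = atom.coord
    return (f"{rec}{serial:5d} {name}{'':1s}{res.name:>3s} {chain_id}"
            f"{res.seq_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
            f"{atom.element:>2s}")


def monomer_pdb_lines(m: InsulinMonomer, chain_ids: tuple[str, str] | None = None,
                      serial_start: int = 1) -> tuple[list[str], int]:
    ids = chain_ids or m.source_chain_ids
    lines: list[str] = []
    serial = serial_start
    for chain, cid in zip((m.a_chain, m.b_chain), ids):
        for res in chain:
            het = res.name not in _ONE_TO_THREE.values()
            for atom in res.atoms:
                lines.append(_format_atom_line(serial, atom, res, cid, het))
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain[-1].name:>3s} {cid}"
                     f"{chain[-1].seq_id:4d}")
        serial += 1
    return lines, serial


def write_monomer_pdb(m: InsulinMonomer, path: str | Path,
                      resolution: float | None = None) -> Path:
    """Write a single-model PDB file with a REMARK 2 resolution record."""
    path = Path(path)
    res = resolution if resolution is not None else m.resolution
    lines = [f"HEADER    HORMONE                                 01-JAN-20   {m.pdb_id[:4].upper():<4s}"]
    if res is not None:
        lines.append(f"REMARK   2 RESOLUTION. {res:7.2f} ANGSTROMS.")
    body, _ = monomer_pdb_lines(m)
    lines += body
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ensemble_pdb(frames: list[InsulinMonomer], path: str | Path,
                       truth: list[str] | None = None,
                       spec: SyntheticSpec | None = None) -> Path:
    """Write a multi-model PDB; optional sidecar JSON with true labels."""
    path = Path(path)
    lines = ["HEADER    HORMONE                                 01-JAN-20   SYNT"]
    if frames and frames[0].resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {frames[0].resolution:7.2f} ANGSTROMS.")
    for i, m in enumerate(frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        body, _ = monomer_pdb_lines(m)
        lines += body
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if truth is not None or spec is not None:
        sidecar = {"true_labels": truth}
        if spec is not None:
            sidecar["spec"] = spec.to_json()
        Path(str(path) + ".labels.json").write_text(json.dumps(sidecar, indent=1))
    return path
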