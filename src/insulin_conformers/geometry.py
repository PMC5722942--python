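"""Computational geometry: distances, torsions, Kabsch superposition, helix axes.

Torsion angles follow the IUPAC convention (cis = 0 deg, trans = 180 deg,
reported in (-180, 180]).  Superposition uses the Kabsch SVD solution with
the determinant sign correction, so reflections are never returned.  Helix
axes are fitted by a least-squares line through local helix centres obtained
from the bisector construction on consecutive Calpha quadruples, which is
stable down to the short (8-residue) insulin A-chain N-terminal helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Degenerate geometry: collinear torsion points, rank-deficient point sets."""


@dataclass
class SuperpositionResult:
    """Rigid transform x -> R x + t minimising RMSD of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class HelixFrame:
    """Fitted helix axis with per-residue azimuths about it."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    rise_per_residue: float
    twist_per_residue: float
    azimuth: dict[str, float] = field(default_factory=dict)
    low_confidence: bool = False


def point_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise GeometryError("coincident central torsion points")
    if np.linalg.norm(n1) < 1e-9 * max(1.0, np.linalg.norm(b1) * b2n):
        raise GeometryError("collinear points p1, p2, p3: torsion undefined")
    if np.linalg.norm(n2) < 1e-9 * max(1.0, np.linalg.norm(b3) * b2n):
        raise GeometryError("collinear points p2, p3, p4: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns the rigid transform x -> R x + t that minimises the (weighted)
    RMSD; the sign of the smallest singular value is corrected so the
    rotation determinant is +1.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must be matching N x 3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    pm = mobile - mc
    pr = reference - rc
    if np.linalg.matrix_rank(pm, tol=1e-8) < 2 or np.linalg.matrix_rank(pr, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set: rotation underdetermined")

    h = pm.T @ (w[:, None] * pr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = pm @ rot.T
    rmsd = float(np.sqrt((w * ((moved - pr) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def rmsd_after_superposition(
    mobile_sel: np.ndarray,
    reference_sel: np.ndarray,
    fit_sel_mobile: np.ndarray,
    fit_sel_reference: np.ndarray,
) -> float:
    """Fit on one selection, measure RMSD on another.

    The superposition is computed on the fit selections; the returned RMSD
    is evaluated on the measure selections after applying that transform.
    """
    mobile_sel = np.atleast_2d(np.asarray(mobile_sel, float))
    reference_sel = np.atleast_2d(np.asarray(reference_sel, float))
    if mobile_sel.shape != reference_sel.shape:
        raise GeometryError("measure selections differ in length")
    if mobile_sel.shape[0] < 1:
        raise GeometryError("empty measure selection")
    sup = kabsch_superpose(fit_sel_mobile, fit_sel_reference)
    moved = sup.apply(mobile_sel)
    return float(np.sqrt(((moved - reference_sel) ** 2).sum(axis=1).mean()))


def _local_helix_centers(ca: np.ndarray) -> np.ndarray:
    """Axis points from the bisector construction on Calpha quadruples.

    For the quadruple (i-1, i, i+1, i+2) the inward bisectors at i and i+1
    define two near-intersecting radial lines; their point of closest
    approach is a point on the helix axis.
    """

    def bisector(i: int) -> np.ndarray:
        v1 = ca[i - 1] - ca[i]
        v2 = ca[i + 1] - ca[i]
        b = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        nb = np.linalg.norm(b)
        if nb < 1e-9:
            raise GeometryError("straight Calpha trace: bisector undefined")
        return b / nb

    centers = []
    for i in range(1, len(ca) - 2):
        b1, b2 = bisector(i), bisector(i + 1)
        p1, p2 = ca[i], ca[i + 1]
        # closest approach of lines p1 + t b1 and p2 + s b2
        d = p2 - p1
        a11, a12, a22 = 1.0, float(b1 @ b2), 1.0
        det = a11 * a22 - a12 * a12
        if abs(det) < 1e-12:  # parallel bisectors
            t = float(d @ b1)
            s = 0.0
        else:
            r1, r2 = float(d @ b1), float(d @ b2)
            t = (r1 * a22 - r2 * a12) / det
            s = (r1 * a12 - r2 * a11) / det
        centers.append(0.5 * ((p1 + t * b1) + (p2 + s * b2)))
    return np.array(centers)


def fit_helix_axis(
    ca_coords: np.ndarray,
    labels: list[str] | None = None,
    reference_point: np.ndarray | None = None,
) -> HelixFrame:
    """Fit a helix axis to an ordered Calpha trace (>= 5 points).

    The axis is the least-squares line through the local helix centres;
    rise is the mean axial step between consecutive Calphas, twist the mean
    angular step about the axis (signed, positive right-handed about
    ``axis_dir``, which is oriented from the first to the last residue).
    Azimuths are measured from ``reference_point`` (default: the first
    Calpha) projected perpendicular to the axis.
    """
    ca = np.asarray(ca_coords, float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 5:
        raise GeometryError("helix fit requires >= 5 ordered Calpha positions")
    centers = _local_helix_centers(ca)
    axis_point = centers.mean(axis=0)
    # principal direction of the centres; for very short helices the centre
    # cloud can be nearly isotropic, so fall back on end-to-end direction
    u, s, vt = np.linalg.svd(centers - axis_point)
    axis_dir = vt[0]
    end_to_end = ca[-1] - ca[0]
    if s[0] < 1e-6 or abs(axis_dir @ end_to_end) < 1e-9:
        axis_dir = end_to_end / np.linalg.norm(end_to_end)
    if axis_dir @ end_to_end < 0:
        axis_dir = -axis_dir

    proj = (ca - axis_point) @ axis_dir
    rise = float(np.diff(proj).mean())

    # in-plane components and angular steps about the axis
    perp = ca - axis_point - np.outer(proj, axis_dir)
    steps = []
    for i in range(len(ca) - 1):
        a, b = perp[i], perp[i + 1]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-9 or nb < 1e-9:
            continue
        cosang = np.clip((a @ b) / (na * nb), -1.0, 1.0)
        sign = np.sign(np.cross(a, b) @ axis_dir) or 1.0
        steps.append(sign * np.degrees(np.arccos(cosang)))
    twist = float(np.mean(steps)) if steps else 0.0
    low_confidence = bool(steps) and abs(twist) < 5.0

    ref = ca[0] if reference_point is None else np.asarray(reference_point, float)
    frame = HelixFrame(
        axis_point=axis_point,
        axis_dir=axis_dir,
        rise_per_residue=rise,
        twist_per_residue=twist,
        low_confidence=low_confidence,
    )
    names = labels if labels is not None else [str(i) for i in range(len(ca))]
    for name, c in zip(names, ca):
        frame.azimuth[name] = azimuth_about_axis(frame, c, ref)
    return frame


def azimuth_about_axis(frame: HelixFrame, point: np.ndarray, reference_point: np.ndarray) -> float:
    """Signed angle, in the plane normal to the axis, from the reference
    direction to the projection of ``point``; degrees in (-180, 180]."""

    def radial(p: np.ndarray) -> np.ndarray:
        v = np.asarray(p, float) - frame.axis_point
        v = v - (v @ frame.axis_dir) * frame.axis_dir
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise GeometryError("point lies on the helix axis: azimuth undefined")
        return v / n

    r0 = radial(reference_point)
    r1 = radial(point)
    cosang = np.clip(float(r0 @ r1), -1.0, 1.0)
    sign = np.sign(np.cross(r0, r1) @ frame.axis_dir) or 1.0
    ang = float(sign * np.degrees(np.arccos(cosang)))
    if ang <= -180.0:
        ang += 360.0
    return ang


# span of the A-chain N-terminal helix used for azimuth work
A_HELIX_SPAN = ("A1", "A8")
B_HELIX_FIT = [f"B{i}" for i in range(8, 21)]  # B8-B20 Calpha fit


def _span_labels(span: tuple[str, str]) -> list[str]:
    chain = span[0][0]
    lo, hi = int(span[0][1:]), int(span[1][1:])
    return [f"{chain}{i}" for i in range(lo, hi + 1)]


def azimuth_profile(
    monomer,
    helix_range: tuple[str, str] = A_HELIX_SPAN,
    reference_monomer=None,
    azimuth_zero_label: str = "A6",
) -> dict[str, float]:
    """Per-residue azimuths of the A-chain N-terminal helix.

    Without a reference, returns each residue's azimuth about the monomer's
    own fitted axis, measured from the Calpha of ``azimuth_zero_label``
    (default A6, the bridge anchor of the helix).

    With a reference monomer, the mobile monomer is first superposed on the
    reference over the B8-B20 Calpha trace, the axis and zero direction are
    taken from the *reference* helix, and the returned values are azimuth
    differences (mobile - reference) in that common frame — the quantity
    that measures rotation of the A1-A8 helix between conformational
    classes.
    """
    labels = _span_labels(helix_range)
    if reference_monomer is None:
        ca = monomer.ca_coords(labels)
        zero = monomer.ca_coords([azimuth_zero_label])[0]
        frame = fit_helix_axis(ca, labels=labels, reference_point=zero)
        return dict(frame.azimuth)

    fit_mobile = monomer.ca_coords(B_HELIX_FIT)
    fit_ref = reference_monomer.ca_coords(B_HELIX_FIT)
    sup = kabsch_superpose(fit_mobile, fit_ref)
    ca_mobile = sup.apply(monomer.ca_coords(labels))
    ca_ref = reference_monomer.ca_coords(labels)
    zero = reference_monomer.ca_coords([azimuth_zero_label])[0]
    frame = fit_helix_axis(ca_ref, labels=labels, reference_point=zero)
    out: dict[str, float] = {}
    for lab, cm, cr in zip(labels, ca_mobile, ca_ref):
        d = azimuth_about_axis(frame, cm, zero) - azimuth_about_axis(frame, cr, zero)
        if d <= -180.0:
            d += 360.0
        elif d > 180.0:
            d -= 360.0
        out[lab] = d
    return out
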