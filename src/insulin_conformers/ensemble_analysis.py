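"""Ensemble (multi-model / MD-frame) statistics.

Post-processing applied to conformational ensembles of insulin monomers:
a per-frame RMSD series of the A1-A4 segment against a representative
Class 2 reference (fit on the conserved B-helix Calphas, measured on the
segment), occupancies of the three Thr A8 amide hydrogen-bonding partners
(Val A3, Glu A4, Gln A5), Class-2 occupancy by RMSD threshold, A6-A11
Calpha-distance means per class, and per-residue helicity.  Frames are
treated as given — no correlation correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from insulin_conformers.core import InsulinMonomer, chain_labels
from insulin_conformers.geometry import rmsd_after_superposition
from insulin_conformers.hbond_helix import assign_helix_types, backbone_hbond_map
from insulin_conformers.bridge import extract_bridge_geometry
from insulin_conformers import structure_io

# defaults mirroring the analysis conventions
MEASURE_RESIDUES = ("A1", "A2", "A3", "A4")     # all heavy atoms
FIT_RESIDUES = tuple(f"B{i}" for i in range(9, 20))  # Calpha B9-B19
CLASS2_RMSD_THRESHOLD = 1.5                      # Angstrom
PARTNERS = ("A3", "A4", "A5")


class EnsembleLoadError(ValueError):
    pass


@dataclass
class Ensemble:
    frames: list[InsulinMonomer]
    segment_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise EnsembleLoadError("an ensemble needs at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def segments(self) -> list[tuple[int, int]]:
        bounds = [0] + sorted(self.segment_boundaries) + [len(self.frames)]
        return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


@dataclass
class EnsembleStats:
    rmsd_series: np.ndarray
    rmsd_mean: float
    rmsd_sd: float
    partner_occupancy: dict[str, float]
    class2_fraction: float
    ca_ca_mean_by_class: dict[str, float]
    helicity: dict[str, float]
    per_segment: list[dict] = field(default_factory=list)


def load_ensemble(path: str | Path,
                  segment_boundaries: list[int] | None = None) -> Ensemble:
    """Load a multi-model coordinate file as an ensemble of monomers.

    Every model must contain the same single monomer topology (residue
    labels and atom counts); a mismatching frame is reported by index.
    """
    parsed = structure_io.parse_structure(path)
    frames: list[InsulinMonomer] = []
    signature = None
    for i, model in enumerate(parsed.models):
        sub = structure_io.ParsedStructure(parsed.pdb_id, parsed.resolution, [model])
        monomers = structure_io.identify_insulin_monomers(sub)
        if len(monomers) != 1:
            raise EnsembleLoadError(
                f"frame {i + 1}: expected exactly 1 insulin monomer, "
                f"found {len(monomers)}")
        m = monomers[0]
        sig = tuple((r.insulin_pos, len(r.atoms)) for r in m.residues())
        if signature is None:
            signature = sig
        elif sig != signature:
            raise EnsembleLoadError(f"frame {i + 1}: topology differs from frame 1")
        frames.append(m)
    return Ensemble(frames, segment_boundaries or [])


def _selection(m: InsulinMonomer, residues: tuple[str, ...],
               atoms: str = "heavy") -> list[tuple[str, str]]:
    sel = []
    for lab in residues:
        res = m.residue(lab)
        if res is None:
            raise EnsembleLoadError(f"residue {lab} unresolvable")
        for a in sorted(res.atoms, key=lambda a: a.name):
            if atoms == "ca" and a.name != "CA":
                continue
            if atoms == "heavy" and a.element == "H":
                continue
            sel.append((lab, a.name))
    return sel


def rmsd_vs_reference(ensemble: Ensemble, reference: InsulinMonomer,
                      measure_residues: tuple[str, ...] = MEASURE_RESIDUES,
                      fit_residues: tuple[str, ...] = FIT_RESIDUES) -> np.ndarray:
    """Per-frame heavy-atom RMSD of the measure segment after fitting each
    frame to the reference on the fit-segment Calphas.

    Only atoms present in both the frame and the reference enter the
    measurement, so ensembles with reduced side chains compare cleanly
    against fuller references.
    """
    fit_sel = [(lab, "CA") for lab in fit_residues]
    ref_fit = reference.coords(fit_sel)
    out = np.empty(len(ensemble))
    ref_meas_sel = set(_selection(reference, measure_residues))
    for i, frame in enumerate(ensemble.frames):
        meas_sel = [s for s in _selection(frame, measure_residues)
                    if s in ref_meas_sel]
        if not meas_sel:
            raise EnsembleLoadError("no common measure atoms between frame and reference")
        out[i] = rmsd_after_superposition(
            frame.coords(meas_sel), reference.coords(meas_sel),
            frame.coords(fit_sel), ref_fit,
        )
    return out


def partner_occupancy(ensemble: Ensemble, donor: str = "A8") -> dict[str, float]:
    """Fraction of frames in which each acceptor is the donor's best
    hydrogen-bonding partner.

    Keys are A3, A4, A5 and 'none'; frames whose best acceptor is any
    other residue, or which have no bond from the donor, count as 'none'.
    Fractions sum to 1.
    """
    counts = {p: 0 for p in PARTNERS}
    counts["none"] = 0
    for frame in ensemble.frames:
        hmap = backbone_hbond_map(frame)
        acc = hmap.best_acceptor.get(donor)
        counts[acc if acc in counts else "none"] += 1
    n = len(ensemble)
    return {k: v / n for k, v in counts.items()}


def _frame_stats(frames: list[InsulinMonomer], rmsds: np.ndarray,
                 threshold: float) -> dict:
    is_c2 = rmsds < threshold
    ca = np.array([extract_bridge_geometry(f, "A6A11").ca_ca for f in frames])
    by_class = {}
    for name, mask in (("CLASS2", is_c2), ("OTHER", ~is_c2)):
        if mask.any():
            by_class[name] = float(ca[mask].mean())
    return {
        "rmsd_mean": float(rmsds.mean()),
        "rmsd_sd": float(rmsds.std(ddof=0)),
        "class2_fraction": float(is_c2.mean()),
        "ca_ca_mean_by_class": by_class,
    }


def summarize(ensemble: Ensemble, reference: InsulinMonomer,
              class_threshold: float = CLASS2_RMSD_THRESHOLD) -> EnsembleStats:
    """Full ensemble summary: RMSD series and moments, Class-2 occupancy by
    RMSD threshold, Thr A8 partner occupancies, per-class A6-A11 Calpha
    distance means, per-residue helicity, and per-segment breakdowns when
    segment boundaries are set."""
    rmsds = rmsd_vs_reference(ensemble, reference)
    whole = _frame_stats(ensemble.frames, rmsds, class_threshold)

    helical = {lab: 0 for lab in chain_labels("A") + chain_labels("B")}
    for frame in ensemble.frames:
        types = assign_helix_types(frame)
        for lab, t in types.items():
            if t in ("H", "G", "I"):
                helical[lab] = helical.get(lab, 0) + 1
    n = len(ensemble)
    helicity = {lab: c / n for lab, c in helical.items()}

    per_segment = []
    if ensemble.segment_boundaries:
        for a, b in ensemble.segments():
            seg = _frame_stats(ensemble.frames[a:b], rmsds[a:b], class_threshold)
            seg["range"] = (a, b)
            per_segment.append(seg)

    return EnsembleStats(
        rmsd_series=rmsds,
        rmsd_mean=whole["rmsd_mean"],
        rmsd_sd=whole["rmsd_sd"],
        partner_occupancy=partner_occupancy(ensemble),
        class2_fraction=whole["class2_fraction"],
        ca_ca_mean_by_class=whole["ca_ca_mean_by_class"],
        helicity=helicity,
        per_segment=per_segment,
    )
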