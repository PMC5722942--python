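"""Reading coordinate files, insulin identification, curation, survey output.

Parsing is delegated to gemmi (PDB and mmCIF, single- and multi-model).
Chains are matched to the insulin A and B chains by alignment against the
human sequences, tolerating substitutions and modified bridge residues;
A/B chains are paired into monomers by A7-B7 bridge-atom proximity.
Curation mirrors the survey construction used for T-state insulin
statistics: resolution strictly better than 2.8 A, A6-A11 S-gamma bond
length within [1.95, 2.05] A for disulfides (dicarba bridges exempt), and
optional exclusion of entries complexed with the insulin-degrading enzyme
via a user-supplied accession list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from insulin_conformers.core import (
    A_CHAIN_SEQ,
    B_CHAIN_SEQ,
    Atom,
    InsulinMonomer,
    Residue,
    THREE_TO_ONE,
)
from insulin_conformers.bridge import extract_bridge_geometry, BridgeError

log = logging.getLogger(__name__)

RESOLUTION_CUTOFF = 2.8          # keep strictly better (smaller) than this
SS_LENGTH_RANGE = (1.95, 2.05)   # acceptable A6-A11 S-gamma bond lengths


class StructureParseError(ValueError):
    pass


@dataclass
class ParsedChain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclass
class ParsedModel:
    number: int
    chains: list[ParsedChain]


@dataclass
class ParsedStructure:
    pdb_id: str
    resolution: float | None
    models: list[ParsedModel]


@dataclass
class CurationReport:
    monomer_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> altloc 'A'
    (blank counts as earliest)."""
    by_name: dict[str, list[Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        out.append(min(group, key=lambda a: (-a.occupancy, a.altloc or " ")))
    return out


def parse_structure(path_or_text: str | Path, dialect: str = "auto") -> ParsedStructure:
    """Read a PDB or mmCIF coordinate file into models of chains of residues.

    ``path_or_text`` may be a filesystem path or raw PDB text.  HETATM
    records are retained (modified bridge residues live there); waters are
    dropped; alternate locations are resolved to a single conformer.
    """
    if dialect not in ("pdb", "mmcif", "auto"):
        raise StructureParseError(f"unknown dialect {dialect!r}")
    text = None
    path = Path(str(path_or_text))
    is_path = False
    try:
        is_path = path.exists() and path.is_file()
    except OSError:
        is_path = False
    try:
        if is_path:
            if dialect == "auto":
                dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
            if dialect == "pdb":
                st = gemmi.read_pdb(str(path))
            else:
                st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            text = str(path_or_text)
            st = gemmi.read_pdb_string(text)
    except Exception as exc:  # gemmi raises RuntimeError with line context
        raise StructureParseError(f"unreadable coordinate file: {exc}") from exc

    st.setup_entities()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    models: list[ParsedModel] = []
    for model in st:
        chains = []
        for chain in model:
            residues = []
            for res in chain:
                if res.is_water():
                    continue
                raw = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=min(max(float(a.occ), 0.0), 1.0),
                        altloc=a.altloc if a.altloc != "\x00" else "",
                        bfactor=float(a.b_iso),
                    )
                    for a in res
                ]
                residues.append(
                    Residue(name=res.name, seq_id=res.seqid.num,
                            atoms=_resolve_altlocs(raw))
                )
            if residues:
                chains.append(ParsedChain(chain.name, residues))
        num = int(model.num) if str(model.num).isdigit() else len(models) + 1
        models.append(ParsedModel(num, chains))
    pdb_id = (st.name or "XXXX").strip()[:4].upper() or "XXXX"
    return ParsedStructure(pdb_id=pdb_id, resolution=resolution, models=models)


# --- insulin identification ------------------------------------------------

_CYS_A = (6, 7, 11, 20)   # 1-based positions in the canonical A chain
_CYS_B = (7, 19)


def _best_offset(seq: str, canonical: str) -> tuple[int, float]:
    """Best ungapped alignment offset of ``canonical`` within ``seq``
    (offset may be negative when the chain starts inside the canonical
    sequence); returns (offset, identity fraction over overlap)."""
    best = (0, -1.0)
    for off in range(-3, len(seq) - len(canonical) + 4):
        matches = 0
        overlap = 0
        for i, aa in enumerate(canonical):
            j = off + i
            if 0 <= j < len(seq):
                overlap += 1
                if seq[j] == aa:
                    matches += 1
        if overlap >= len(canonical) - 3:
            frac = matches / max(overlap, 1)
            if frac > best[1]:
                best = (off, frac)
    return best


def _cys_compatible(res: Residue) -> bool:
    """CYS or a modified bridge residue: anything with a CA qualifies at a
    bridge position (bridge typing is atom-based downstream)."""
    return res.coord("CA") is not None


def _assign_labels(chain: ParsedChain, which: str) -> list[Residue] | None:
    canonical = A_CHAIN_SEQ if which == "A" else B_CHAIN_SEQ
    lo, hi = (19, 23) if which == "A" else (26, 32)
    n = len(chain.residues)
    if not lo <= n <= hi:
        return None
    off, ident = _best_offset(chain.sequence, canonical)
    if ident < 0.5:
        return None
    cys_pos = _CYS_A if which == "A" else _CYS_B
    labelled = []
    for i, aa in enumerate(canonical):
        j = off + i
        if 0 <= j < n:
            res = chain.residues[j]
            if i + 1 in cys_pos and not _cys_compatible(res):
                return None
            res = Residue(res.name, res.seq_id, res.atoms, f"{which}{i + 1}")
            labelled.append(res)
    if which == "A":
        need = {f"A{p}" for p in _CYS_A}
    else:
        need = {f"B{p}" for p in _CYS_B}
    have = {r.insulin_pos for r in labelled}
    if not need <= have:
        return None
    return labelled


def _bridge_anchor(residues: list[Residue], label: str) -> np.ndarray | None:
    for r in residues:
        if r.insulin_pos == label:
            for name in ("SG", "CG", "CB", "CA"):
                c = r.coord(name)
                if c is not None:
                    return c
    return None


def identify_insulin_monomers(parsed: ParsedStructure) -> list[InsulinMonomer]:
    """Find and pair insulin A/B chains in every model.

    A chains: 19-23 residues matching the canonical A sequence with
    Cys-compatible residues at A6/A7/A11/A20.  B chains: 26-32 residues
    with Cys-compatible B7/B19.  Pairing minimises the A7-B7 bridge-atom
    distance; ties break deterministically by chain-id order (flagged in
    the log).  Unpaired candidate chains are logged, never silently
    dropped.
    """
    monomers: list[InsulinMonomer] = []
    for model in parsed.models:
        a_cands: list[tuple[str, list[Residue]]] = []
        b_cands: list[tuple[str, list[Residue]]] = []
        for chain in model.chains:
            lab_a = _assign_labels(chain, "A")
            if lab_a is not None:
                a_cands.append((chain.chain_id, lab_a))
                continue
            lab_b = _assign_labels(chain, "B")
            if lab_b is not None:
                b_cands.append((chain.chain_id, lab_b))
        if not a_cands and not b_cands:
            log.warning("model %s: no insulin-like chains found", model.number)
            continue
        # all pairwise A7-B7 distances, greedy minimal matching
        pairs = []
        for ia, (aid, ares) in enumerate(a_cands):
            pa = _bridge_anchor(ares, "A7")
            for ib, (bid, bres) in enumerate(b_cands):
                pb = _bridge_anchor(bres, "B7")
                if pa is None or pb is None:
                    continue
                d = float(np.linalg.norm(pa - pb))
                pairs.append((d, aid, bid, ia, ib))
        pairs.sort(key=lambda t: (round(t[0], 6), t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, aid, bid, ia, ib in pairs:
            if ia in used_a or ib in used_b:
                continue
            ties = [p for p in pairs if p[3] == ia and p[4] not in used_b
                    and abs(p[0] - d) < 1e-6]
            if len(ties) > 1:
                log.warning("model %s: ambiguous A/B pairing for chain %s; "
                            "tie broken by chain id order", model.number, aid)
            used_a.add(ia)
            used_b.add(ib)
            monomers.append(InsulinMonomer(
                pdb_id=parsed.pdb_id, model_no=model.number,
                a_chain=a_cands[ia][1], b_chain=b_cands[ib][1],
                resolution=parsed.resolution,
                source_chain_ids=(aid, bid),
            ))
        for ia, (aid, _) in enumerate(a_cands):
            if ia not in used_a:
                log.warning("model %s: unpaired insulin A chain %s", model.number, aid)
        for ib, (bid, _) in enumerate(b_cands):
            if ib not in used_b:
                log.warning("model %s: unpaired insulin B chain %s", model.number, bid)
    return monomers


def monomer_id(m: InsulinMonomer) -> str:
    return f"{m.pdb_id}/{m.model_no}/{m.source_chain_ids[0]}{m.source_chain_ids[1]}"


def apply_curation_filters(
    monomer: InsulinMonomer,
    resolution: float | None = None,
    excluded_ids: set[str] | None = None,
    resolution_cutoff: float = RESOLUTION_CUTOFF,
    ss_range: tuple[float, float] = SS_LENGTH_RANGE,
) -> CurationReport:
    """Survey curation filters for one monomer.

    ``resolution_fail``: resolution missing or not strictly better than the
    cutoff.  ``ss_bond_length_fail``: the A6-A11 bridge is a disulfide with
    S-gamma bond length outside ``ss_range`` (dicarba bridges are exempt
    and noted).  ``ide_complex_excluded``: accession on the caller's
    exclusion list (insulin-degrading-enzyme complexes).
    """
    mid = monomer_id(monomer)
    reasons: list[str] = []
    notes: list[str] = []
    res = resolution if resolution is not None else monomer.resolution
    if res is None or not res < resolution_cutoff:
        reasons.append("resolution_fail")
    if excluded_ids and monomer.pdb_id.upper() in {x.upper() for x in excluded_ids}:
        reasons.append("ide_complex_excluded")
    try:
        geom = extract_bridge_geometry(monomer, "A6A11")
        if geom.bridge_type == "disulfide":
            assert geom.sg_sg is not None
            if not ss_range[0] <= geom.sg_sg <= ss_range[1]:
                reasons.append("ss_bond_length_fail")
        elif geom.bridge_type == "dicarba":
            notes.append("dicarba_bridge_exempt_from_ss_filter")
        else:
            reasons.append("incomplete_backbone")
    except BridgeError as exc:
        reasons.append("incomplete_backbone")
        notes.append(str(exc))
    return CurationReport(mid, passed=not reasons, reasons=reasons, notes=notes)


# --- survey table ----------------------------------------------------------

_DIST_COLS = ("ca_ca_a6a11", "ca_ca_a7b7", "ca_ca_a20b19", "sg_sg_a6a11")
_ANGLE_PREFIXES = ("chi", "azimuth")


def write_survey(records: list[dict], path: str | Path) -> Path:
    """Write per-monomer metric rows as a TSV.

    Distances are printed to 0.01 A and angles to 0.1 deg; rows are sorted
    by (pdb_id, model, chain) so repeated runs are byte-identical.
    """
    path = Path(path)
    if records:
        keys = list(records[0].keys())
        for r in records:
            if list(r.keys()) != keys:
                raise ValueError("survey records must share one column schema")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        keys = ["pdb_id", "model", "chain"]
        df = pd.DataFrame(columns=keys)
    sort_cols = [c for c in ("pdb_id", "model", "chain") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    for col in df.columns:
        if col in _DIST_COLS:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{float(v):.2f}")
        elif any(col.startswith(p) for p in _ANGLE_PREFIXES):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{float(v):.1f}")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_survey(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
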