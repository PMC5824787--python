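"""Structure parsing, sequence mapping, and distance-shell position selection.

The diversification shell is defined structurally: every residue whose
distance to the catalytic anchor (H133 in human SIRT6, using the 3ZG6
numbering convention) is at most a cutoff (15 Å by default) is eligible.
Distances default to the minimum over heavy-atom pairs, which captures
side-chain proximity; CA-only and CB modes are selectable.

Structure residues are mapped to the target sequence by global alignment of
the structure-derived sequence against the target rather than by trusting
author residue numbering, which is frequently offset in deposited files.

Only ATOM records are read (first MODEL, altloc blank or 'A', HETATM
ignored); a malformed ATOM record raises with its line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq1

from .family import AlignedFamily, SequenceRecord, global_identity
from .asr import AncestralPosterior


@dataclass(frozen=True)
class Atom:
    name: str
    xyz: tuple
    element: str


@dataclass(frozen=True)
class Residue:
    number: int
    name3: str
    atoms: tuple

    @property
    def one_letter(self) -> str:
        code = seq1(self.name3.capitalize())
        return code if code and code != " " else "X"

    def coord(self, atom_name: str):
        for a in self.atoms:
            if a.name == atom_name:
                return np.asarray(a.xyz)
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if a.element.upper() != "H"]
        return np.asarray(pts) if pts else np.empty((0, 3))


@dataclass
class StructureModel:
    chain: str
    residues: list

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass(frozen=True)
class SelectionConfig:
    """Shell-selection parameters around the catalytic anchor."""

    catalytic_position: int = 133
    catalytic_aa: str = "H"
    distance_cutoff_A: float = 15.0
    distance_mode: str = "min_heavy_atom"  # or "CA" / "CB"
    posterior_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.distance_cutoff_A <= 0:
            raise ValueError("cutoff must be > 0")
        if self.distance_mode not in ("min_heavy_atom", "CA", "CB"):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")


def parse_structure(pdb_text: str, chain: str) -> StructureModel:
    """Parse ATOM records of one chain from PDB text.

    First MODEL only; altloc blank or 'A'; HETATM ignored.  Residues are
    returned in file order; a malformed ATOM record raises with its line
    number.
    """
    residues: dict = {}
    order: list = []
    in_model = 0
    chains_seen = set()
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            if in_model >= 1:
                break
        elif rec == "ATOM":
            if len(line) < 54:
                raise ValueError(f"malformed ATOM record at line {lineno}")
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                ch = line[21]
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"malformed ATOM record at line {lineno}: {exc}") from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1]
            chains_seen.add(ch)
            if ch != chain or altloc not in (" ", "A"):
                continue
            key = resnum
            if key not in residues:
                residues[key] = {"name3": resname, "atoms": []}
                order.append(key)
            residues[key]["atoms"].append(Atom(name, (x, y, z), element))
    if not order:
        raise ValueError(
            f"chain {chain!r} has no ATOM records (chains present: "
            f"{sorted(chains_seen) or 'none'})")
    res_objs = [Residue(num, residues[num]["name3"],
                        tuple(residues[num]["atoms"])) for num in order]
    for r in res_objs:
        for a in r.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinate in residue {r.number}")
    return StructureModel(chain, res_objs)


def map_structure_to_target(structure: StructureModel,
                            target: SequenceRecord) -> dict:
    """Map 1-based target positions to structure residues by alignment.

    Raises if alignment identity < 0.3 (structure does not match target).
    """
    struct_seq = structure.sequence
    if not struct_seq:
        raise ValueError("structure has no standard residues")
    srec = SequenceRecord("__structure__", struct_seq)
    ident = global_identity(srec, target)
    if ident < 0.3:
        raise ValueError(
            f"structure does not match target (identity {ident:.2f} < 0.30)")
    from .family import _aligner
    aln = _aligner().align(struct_seq, target.sequence)[0]
    sa, sb = str(aln[0]), str(aln[1])
    mapping = {}
    i = j = 0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            mapping[j + 1] = structure.residues[i]
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return mapping


def _residue_distance(a: Residue, b: Residue, mode: str) -> float:
    if a.number == b.number and a is b:
        return 0.0
    if mode == "CA":
        ca, cb = a.coord("CA"), b.coord("CA")
        if ca is None or cb is None:
            return np.inf
        return float(np.linalg.norm(ca - cb))
    if mode == "CB":
        # glycine has no CB; fall back to CA
        pa = a.coord("CB") if a.coord("CB") is not None else a.coord("CA")
        pb = b.coord("CB") if b.coord("CB") is not None else b.coord("CA")
        if pa is None or pb is None:
            return np.inf
        return float(np.linalg.norm(pa - pb))
    ha, hb = a.heavy_coords(), b.heavy_coords()
    if ha.size == 0 or hb.size == 0:
        return np.inf
    diff = ha[:, None, :] - hb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def residues_within(structure: StructureModel, mapping: dict,
                    anchor: int, cfg: SelectionConfig = SelectionConfig()
                    ) -> list:
    """All mapped target positions within the cutoff of the anchor position.

    Returns [(target position, distance_A)] sorted by distance; the anchor
    itself is included at distance 0.
    """
    if anchor not in mapping:
        raise ValueError(f"anchor position {anchor} is not mapped to the structure")
    anchor_res = mapping[anchor]
    if cfg.catalytic_aa and anchor_res.one_letter != cfg.catalytic_aa:
        raise ValueError(
            f"anchor residue mismatch: expected {cfg.catalytic_aa}, "
            f"found {anchor_res.one_letter}{anchor_res.number}")
    hits = []
    for pos, res in mapping.items():
        d = 0.0 if pos == anchor else _residue_distance(anchor_res, res,
                                                        cfg.distance_mode)
        if d <= cfg.distance_cutoff_A:
            hits.append((pos, d))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


@dataclass
class CandidateSet:
    """Per-position candidate substitutions (wt -> ancestral)."""

    entries: list  # of dicts: position, wt, anc, distance_A, posterior

    @property
    def n_positions(self) -> int:
        return len({e["position"] for e in self.entries})

    @property
    def n_substitutions(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["position", "wt", "anc", "distance_A",
                                     "posterior"])


def candidate_substitutions(family: AlignedFamily, post: AncestralPosterior,
                            node: str, target_id: str,
                            allowed_positions, cfg: SelectionConfig =
                            SelectionConfig()) -> CandidateSet:
    """Ancestral substitutions at spatially allowed target positions.

    allowed_positions: iterable of (target position, distance_A) as produced
    by :func:`residues_within`.  A substitution is proposed where the node's
    MAP state is present, differs from the target residue, and has posterior
    probability at least cfg.posterior_floor.
    """
    if node not in post.node_labels:
        raise ValueError(f"unknown ancestral node {node!r}")
    target_row = family.row(target_id)
    seq = post.map_sequences[node]
    probs = post.probabilities[node]
    from .models import AA_INDEX
    entries = []
    for pos, dist in allowed_positions:
        col = family.ref_position_to_column(pos)
        wt = target_row[col - 1]
        anc = seq[col - 1]
        if wt == "-" or anc == "-" or anc == wt:
            continue
        p_map = float(probs[col - 1, AA_INDEX[anc]])
        if p_map < cfg.posterior_floor:
            continue
        entries.append({"position": pos, "wt": wt, "anc": anc,
                        "distance_A": float(dist), "posterior": p_map})
    entries.sort(key=lambda e: (e["position"], e["anc"]))
    return CandidateSet(entries)
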