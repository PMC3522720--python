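"""Parsing and preprocessing of multi-chain protein structures.

Structures are read from PDB or mmCIF files (via gemmi) into a light-weight
in-memory model: chains grouped into biological units, each chain carrying
its residues and heavy-atom coordinates, with a flag marking whether the
biological-unit operator applied to the chain is the identity.

The preprocessing filter keeps X-ray entries below a resolution cutoff and,
within each biological unit, removes transformed chains, short chains, and
chains left without any interaction partner, finally discarding units that
no longer contain at least two chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._aa import one_letter

HYDROGEN_ELEMENTS = {"H", "D"}


class StructureParseError(ValueError):
    """The file could not be read as a macromolecular structure."""


class EmptyComplexError(ValueError):
    """The structure contains no protein chains."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    altloc: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class ResidueRef:
    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in heavy])


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRef]
    bio_unit: int = 1
    transform_is_identity: bool = True
    transform: np.ndarray | None = None  # 3x4 [R|t] when non-identity

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def heavy_coords(self) -> np.ndarray:
        blocks = [r.heavy_coords() for r in self.residues]
        blocks = [b for b in blocks if len(b)]
        if not blocks:
            return np.empty((0, 3))
        return np.vstack(blocks)


@dataclass
class ComplexRecord:
    entry_id: str
    resolution: float
    method: str
    chains: list[ChainRecord]

    def bio_units(self) -> dict[int, list[ChainRecord]]:
        units: dict[int, list[ChainRecord]] = {}
        for ch in self.chains:
            units.setdefault(ch.bio_unit, []).append(ch)
        return units

    def get_chain(self, chain_id: str, bio_unit: int | None = None) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id and (bio_unit is None or ch.bio_unit == bio_unit):
                return ch
        raise KeyError(chain_id)


@dataclass
class FilterConfig:
    min_chain_len: int = 30
    max_resolution: float = 3.0  # strictly better than ("<")
    contact_cutoff: float = 5.0
    require_xray: bool = True


@dataclass
class FilterReport:
    dropped_entries: dict[str, int] = field(default_factory=dict)
    dropped_chains: dict[str, int] = field(default_factory=dict)
    # (entry_id, chain_id, bio_unit, length, resolution, kept, drop_reason)
    manifest: list[tuple] = field(default_factory=list)

    def _bump(self, table: dict[str, int], reason: str) -> None:
        table[reason] = table.get(reason, 0) + 1


def _is_protein_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue names: treat as protein when they carry a CA atom
    return info is None and any(a.name == "CA" for a in res)


def _best_altloc_atoms(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def parse_structure(path: str | Path) -> ComplexRecord:
    """Read a PDB or mmCIF file into a ComplexRecord.

    Chains are assigned to biological units from the file's assembly
    (REMARK 350 / pdbx_struct_assembly) records: each chain goes to the
    first biomolecule that lists it; chains listed by several biomolecules
    are duplicated per unit.  A chain is flagged ``transform_is_identity``
    only when every operator its unit applies to it is the identity.
    Hydrogens are flagged; for alternate locations only the
    highest-occupancy conformer is kept; residues without any heavy atom
    are dropped.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureParseError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    model = st[0]

    # unit assignment: chain_id -> list of (unit_number, identity_flag, transform)
    assignments: dict[str, list[tuple[int, bool, np.ndarray | None]]] = {}
    for idx, asm in enumerate(st.assemblies, start=1):
        try:
            unit_no = int(asm.name)
        except ValueError:
            unit_no = idx
        for gen in asm.generators:
            ops = list(gen.operators)
            identity = all(op.transform.is_identity() for op in ops) if ops else True
            transform = None
            if not identity:
                tr = next(op.transform for op in ops if not op.transform.is_identity())
                transform = np.hstack([
                    np.array(tr.mat.tolist()),
                    np.array(tr.vec.tolist()).reshape(3, 1),
                ])
            for cid in list(gen.chains) + list(gen.subchains):
                assignments.setdefault(cid, [])
                if unit_no not in [u for u, _, _ in assignments[cid]]:
                    assignments[cid].append((unit_no, identity, transform))

    chains: list[ChainRecord] = []
    serial = 0
    for chain in model:
        residues: list[ResidueRef] = []
        for res in chain:
            if not _is_protein_residue(res):
                continue
            atoms: list[AtomRecord] = []
            for atom in _best_altloc_atoms(res):
                serial += 1
                elem = atom.element.name.upper()
                atoms.append(AtomRecord(
                    serial=serial,
                    name=atom.name,
                    element=elem,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    is_hydrogen=elem in HYDROGEN_ELEMENTS,
                ))
            if not any(not a.is_hydrogen for a in atoms):
                continue  # nothing usable for geometry
            residues.append(ResidueRef(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip() if res.seqid.icode else "",
                aa=one_letter(res.name),
                atoms=atoms,
            ))
        if not residues:
            continue
        units = assignments.get(chain.name, [(1, True, None)])
        for unit_no, identity, transform in units:
            chains.append(ChainRecord(
                chain_id=chain.name,
                residues=residues if identity else [ResidueRef(
                    chain_id=r.chain_id, seq_num=r.seq_num, icode=r.icode,
                    aa=r.aa, atoms=list(r.atoms)) for r in residues],
                bio_unit=unit_no,
                transform_is_identity=identity,
                transform=transform,
            ))

    if not chains:
        raise EmptyComplexError(f"no protein chains in {path}")

    resolution = float(st.resolution) if st.resolution else float("nan")
    method = dict(st.info).get("_exptl.method", "")
    return ComplexRecord(
        entry_id=st.name.strip() or path.stem,
        resolution=resolution,
        method=method,
        chains=chains,
    )


def write_pdb(complex_: ComplexRecord, path: str | Path) -> None:
    """Write a ComplexRecord as PDB text with EXPDTA and REMARK 350 records."""
    lines: list[str] = []
    lines.append(f"HEADER    COMPLEX                                 01-JAN-00   {complex_.entry_id[:4].upper():<4}")
    method = complex_.method or "X-RAY DIFFRACTION"
    lines.append(f"EXPDTA    {method:<66}"[:80].rstrip())
    if math.isfinite(complex_.resolution):
        lines.append(f"REMARK   2 RESOLUTION. {complex_.resolution:7.2f} ANGSTROMS.")
    for unit_no, unit_chains in sorted(complex_.bio_units().items()):
        lines.append(f"REMARK 350 BIOMOLECULE: {unit_no}")
        # group chains in the unit by transform
        ident_ids = [c.chain_id for c in unit_chains if c.transform_is_identity]
        if ident_ids:
            lines.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: " + ", ".join(ident_ids))
            for i in range(3):
                row = [1.0 if j == i else 0.0 for j in range(3)]
                lines.append(
                    f"REMARK 350   BIOMT{i + 1}   1 {row[0]:9.6f} {row[1]:9.6f} {row[2]:9.6f} {0.0:14.5f}")
        for ch in unit_chains:
            if ch.transform_is_identity:
                continue
            lines.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: " + ch.chain_id)
            tr = ch.transform if ch.transform is not None else np.hstack([np.zeros((3, 3)), np.ones((3, 1))])
            for i in range(3):
                lines.append(
                    f"REMARK 350   BIOMT{i + 1}   1 {tr[i, 0]:9.6f} {tr[i, 1]:9.6f} {tr[i, 2]:9.6f} {tr[i, 3]:14.5f}")
    serial = 0
    seen: set[tuple[str, int]] = set()
    from ._aa import ONE_TO_THREE
    for ch in complex_.chains:
        if (ch.chain_id, 1) in seen:  # chain duplicated across units: write once
            continue
        seen.add((ch.chain_id, 1))
        for res in ch.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4}{'':1}{resname:<3} {ch.chain_id:1}{res.seq_num:4d}"
                    f"{res.icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2}")
        lines.append(f"TER   {serial + 1:5d}      {ONE_TO_THREE.get(ch.residues[-1].aa, 'UNK'):<3} "
                     f"{ch.chain_id:1}{ch.residues[-1].seq_num:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _has_partner(chain: ChainRecord, others: Sequence[ChainRecord], cutoff: float) -> bool:
    coords = chain.heavy_coords()
    if not len(coords):
        return False
    tree = cKDTree(coords)
    for other in others:
        oc = other.heavy_coords()
        if not len(oc):
            continue
        dists, _ = tree.query(oc, k=1, distance_upper_bound=cutoff)
        if np.any(np.isfinite(dists)):
            return True
    return False


def filter_complexes(
    complexes: Iterable[ComplexRecord],
    cfg: FilterConfig | None = None,
) -> tuple[list[ComplexRecord], FilterReport]:
    """Apply the retrieval/preprocessing filters; returns kept records + report.

    Entry-level: X-ray only, resolution strictly better (smaller) than the
    cutoff.  Chain-level per biological unit: drop non-identity transforms,
    then chains shorter than the length cutoff, then (to a fixed point)
    chains without any heavy-atom contact within ``contact_cutoff`` of
    another surviving chain of the same unit.  Units with fewer than two
    surviving chains are dropped.  Filtering is idempotent.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    kept: list[ComplexRecord] = []
    for cx in complexes:
        entry_reason = None
        if cfg.require_xray and "X-RAY" not in cx.method.upper():
            entry_reason = "non_xray"
        elif not (math.isfinite(cx.resolution) and 0 < cx.resolution < cfg.max_resolution):
            entry_reason = "resolution"
        if entry_reason:
            report._bump(report.dropped_entries, entry_reason)
            for ch in cx.chains:
                report.manifest.append((cx.entry_id, ch.chain_id, ch.bio_unit,
                                        len(ch), cx.resolution, False, entry_reason))
            continue

        surviving: list[ChainRecord] = []
        for unit_no, unit_chains in sorted(cx.bio_units().items()):
            alive: list[ChainRecord] = []
            for ch in unit_chains:
                if not ch.transform_is_identity:
                    report._bump(report.dropped_chains, "transformed")
                    report.manifest.append((cx.entry_id, ch.chain_id, unit_no,
                                            len(ch), cx.resolution, False, "transformed"))
                elif len(ch) < cfg.min_chain_len:
                    report._bump(report.dropped_chains, "short")
                    report.manifest.append((cx.entry_id, ch.chain_id, unit_no,
                                            len(ch), cx.resolution, False, "short"))
                else:
                    alive.append(ch)
            # remove partnerless chains to a fixed point (keeps filtering idempotent)
            changed = True
            while changed and len(alive) >= 2:
                changed = False
                for ch in list(alive):
                    others = [o for o in alive if o is not ch]
                    if not _has_partner(ch, others, cfg.contact_cutoff):
                        alive.remove(ch)
                        changed = True
                        report._bump(report.dropped_chains, "no_partner")
                        report.manifest.append((cx.entry_id, ch.chain_id, unit_no,
                                                len(ch), cx.resolution, False, "no_partner"))
            if len(alive) < 2:
                for ch in alive:
                    report._bump(report.dropped_chains, "unit_too_small")
                    report.manifest.append((cx.entry_id, ch.chain_id, unit_no,
                                            len(ch), cx.resolution, False, "unit_too_small"))
                continue
            for ch in alive:
                report.manifest.append((cx.entry_id, ch.chain_id, unit_no,
                                        len(ch), cx.resolution, True, ""))
            surviving.extend(alive)
        if surviving:
            kept.append(ComplexRecord(cx.entry_id, cx.resolution, cx.method, surviving))
        else:
            report._bump(report.dropped_entries, "no_surviving_unit")
    return kept, report


def write_manifest(report: FilterReport, path: str | Path) -> None:
    """Write the chain manifest TSV (one row per chain seen by the filter)."""
    import pandas as pd

    df = pd.DataFrame(report.manifest, columns=[
        "entry_id", "chain_id", "bio_unit", "length", "resolution", "kept", "drop_reason"])
    df.to_csv(path, sep="\t", index=False)
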