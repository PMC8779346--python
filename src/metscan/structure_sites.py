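"""Metal-site detection in protein structures.

Reads mmCIF/PDB files with gemmi and finds, for every metal ion, the
polymer residues whose donor atoms (side-chain N/O/S or the backbone
carbonyl oxygen) lie within a distance cutoff of the ion.  The resulting
:class:`MetalSite` objects are the raw material for metal-binding patterns
(:mod:`metscan.mbp_library`).

Sequence positions are 1-based indices into the polymer chain's residue
sequence (enumeration order), not author residue numbers — author numbering
carries insertion codes and gaps that break spacing arithmetic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi

from .constants import (
    DONOR_ELEMENTS,
    METALS,
    NON_DONOR_BACKBONE_ATOMS,
    residue_to_one_letter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetalIon",
    "CoordinatingResidue",
    "MetalSite",
    "SiteDetectionPolicy",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "detect_metal_sites",
    "write_sites_tsv",
    "write_sites_json",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed in the named format."""


class EmptyStructureError(ValueError):
    """Raised when a parsed structure contains no models or no atoms."""


@dataclass(frozen=True)
class MetalIon:
    """A single metal ion in a structure."""

    element: str
    structure_id: str
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in METALS:
            raise ValueError(f"element {self.element!r} is not in the metal vocabulary")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("ion coordinates must be finite")


@dataclass(frozen=True)
class CoordinatingResidue:
    """A polymer residue coordinating a metal through one donor atom."""

    residue_type: str  # one-letter code
    chain_id: str
    seq_index: int  # 1-based position in the chain's polymer sequence
    donor_atom: str
    distance: float  # Å to the metal

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass(frozen=True)
class MetalSite:
    """One metal ion with its ordered coordinating residues (single chain)."""

    ion: MetalIon
    residues: tuple[CoordinatingResidue, ...]
    chain_length: int

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a MetalSite needs at least one coordinating residue")
        chains = {r.chain_id for r in self.residues}
        if len(chains) != 1:
            raise ValueError(f"site residues span multiple chains: {sorted(chains)}")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("coordinating residues must have strictly increasing seq_index")


@dataclass(frozen=True)
class SiteDetectionPolicy:
    """Rules for turning raw geometry into metal sites.

    cutoff
        Maximum metal–donor distance in Å for a first-shell contact.
        3.0 Å is the conventional first-shell threshold.
    donor_atom_names
        Optional explicit whitelist of donor atom names.  When None the
        chemical rule applies: any N/O/S atom except the backbone amide N.
    min_ligands
        Sites with fewer coordinating residues are dropped (and logged);
        a pattern needs at least two ligands to define a spacing.
    same_chain_only
        A metal-binding pattern must be searchable in a single sequence,
        so ligands outside the best-represented chain are dropped.
    """

    cutoff: float = 3.0
    donor_atom_names: frozenset[str] | None = None
    min_ligands: int = 2
    same_chain_only: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.cutoff <= 6):
            raise ValueError("cutoff must be in (0, 6] Å")
        if self.min_ligands < 2:
            raise ValueError("min_ligands must be >= 2")

    def is_donor(self, atom_name: str, element: str) -> bool:
        if self.donor_atom_names is not None:
            return atom_name in self.donor_atom_names
        return element in DONOR_ELEMENTS and atom_name not in NON_DONOR_BACKBONE_ATOMS


def _resolve_format(path: Path, format: str | None) -> gemmi.CoorFormat:
    if format is not None:
        fmt = format.lower()
        if fmt in ("mmcif", "cif"):
            return gemmi.CoorFormat.Mmcif
        if fmt == "pdb":
            return gemmi.CoorFormat.Pdb
        raise ValueError(f"unknown structure format {format!r} (expected 'mmCIF' or 'PDB')")
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return gemmi.CoorFormat.Mmcif
    if suffix in (".pdb", ".ent"):
        return gemmi.CoorFormat.Pdb
    return gemmi.CoorFormat.Detect


def read_structure(path: str | Path, format: str | None = None) -> gemmi.Structure:
    """Read a structure file (mmCIF or PDB) into a gemmi Structure.

    Alternate conformations are reduced to the highest-occupancy conformer
    (ties broken by altloc label order) so that downstream distance scans
    see one atom per name per residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or all(len(chain) == 0 for chain in st[0]):
        raise EmptyStructureError(f"{path} contains no atoms")
    st.setup_entities()
    _keep_best_altloc(st)
    if not st.name:
        st.name = path.stem
    return st


def _keep_best_altloc(st: gemmi.Structure) -> None:
    """Keep one conformer per atom name: highest occupancy, then altloc order."""
    for model in st:
        for chain in model:
            for residue in chain:
                by_name: dict[str, list[int]] = {}
                for i, atom in enumerate(residue):
                    by_name.setdefault(atom.name, []).append(i)
                to_drop: list[int] = []
                for name, idxs in by_name.items():
                    if len(idxs) > 1:
                        best = min(idxs, key=lambda i: (-residue[i].occ, residue[i].altloc))
                        to_drop.extend(i for i in idxs if i != best)
                for i in sorted(to_drop, reverse=True):
                    del residue[i]


def _polymer_residues(chain: gemmi.Chain) -> list[tuple[int, str, gemmi.Residue]]:
    """(1-based seq_index, one-letter code, residue) for polymer residues."""
    out = []
    idx = 0
    for residue in chain:
        one = residue_to_one_letter(residue.name)
        if one is None:
            continue
        idx += 1
        out.append((idx, one, residue))
    return out


def _iter_metal_atoms(model: gemmi.Model, structure_id: str) -> Iterable[MetalIon]:
    seen_unknown: set[str] = set()
    for chain in model:
        for residue in chain:
            if residue_to_one_letter(residue.name) is not None:
                continue  # polymer residue, not a free ion
            for atom in residue:
                element = atom.element.name
                if element in METALS:
                    yield MetalIon(
                        element=element,
                        structure_id=structure_id,
                        chain_id=chain.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                elif atom.element.is_metal and element not in seen_unknown:
                    seen_unknown.add(element)
                    logger.warning(
                        "%s: hetero metal %s is outside the metal vocabulary; skipped",
                        structure_id, element,
                    )


def detect_metal_sites(
    st: gemmi.Structure,
    policy: SiteDetectionPolicy | None = None,
) -> list[MetalSite]:
    """Detect metal sites in the first model of a structure.

    A residue coordinates an ion iff at least one of its donor atoms lies
    within ``policy.cutoff`` of the ion; the closest qualifying donor is
    recorded.  Ions with fewer than ``policy.min_ligands`` coordinating
    residues are dropped (logged).  With ``same_chain_only`` the chain
    contributing the most ligands is kept and cross-chain ligands are
    dropped (logged).
    """
    if policy is None:
        policy = SiteDetectionPolicy()
    if len(st) == 0:
        raise EmptyStructureError("structure has no models")
    model = st[0]
    polymer_by_chain = {chain.name: _polymer_residues(chain) for chain in model}
    if not any(polymer_by_chain.values()):
        raise EmptyStructureError("structure has no polymer chains")

    sites: list[MetalSite] = []
    n_dropped_few, n_cross_dropped = 0, 0
    for ion in _iter_metal_atoms(model, st.name):
        pos = gemmi.Position(*ion.position)
        per_chain: dict[str, list[CoordinatingResidue]] = {}
        for chain_name, residues in polymer_by_chain.items():
            for seq_index, one, residue in residues:
                best: tuple[float, str] | None = None
                for atom in residue:
                    if not policy.is_donor(atom.name, atom.element.name):
                        continue
                    d = pos.dist(atom.pos)
                    if d <= policy.cutoff and (best is None or d < best[0]):
                        best = (d, atom.name)
                if best is not None:
                    per_chain.setdefault(chain_name, []).append(
                        CoordinatingResidue(
                            residue_type=one,
                            chain_id=chain_name,
                            seq_index=seq_index,
                            donor_atom=best[1],
                            distance=best[0],
                        )
                    )
        if not per_chain:
            n_dropped_few += 1
            continue
        if policy.same_chain_only:
            # keep the chain with the most ligands; ties by chain name
            best_chain = min(per_chain, key=lambda c: (-len(per_chain[c]), c))
            n_cross_dropped += sum(len(v) for c, v in per_chain.items() if c != best_chain)
            chosen = {best_chain: per_chain[best_chain]}
        else:
            chosen = per_chain
        for chain_name, ligands in sorted(chosen.items()):
            if len(ligands) < policy.min_ligands:
                n_dropped_few += 1
                logger.debug(
                    "%s: %s ion in chain %s has %d ligand(s) < min_ligands=%d; dropped",
                    st.name, ion.element, chain_name, len(ligands), policy.min_ligands,
                )
                continue
            ligands.sort(key=lambda r: r.seq_index)
            sites.append(
                MetalSite(
                    ion=ion,
                    residues=tuple(ligands),
                    chain_length=len(polymer_by_chain[chain_name]),
                )
            )
    if n_dropped_few:
        logger.info("%s: dropped %d under-coordinated ion/chain pairs", st.name, n_dropped_few)
    if n_cross_dropped:
        logger.info("%s: dropped %d cross-chain ligands", st.name, n_cross_dropped)
    return sites


_TSV_HEADER = "structure_id\telement\tchain\tseq_index\tresidue\tdonor_atom\tdistance"


def write_sites_tsv(sites: Sequence[MetalSite], path: str | Path) -> None:
    lines = [_TSV_HEADER]
    for site in sites:
        for r in site.residues:
            lines.append(
                f"{site.ion.structure_id}\t{site.ion.element}\t{r.chain_id}"
                f"\t{r.seq_index}\t{r.residue_type}\t{r.donor_atom}\t{r.distance:.3f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_json(sites: Sequence[MetalSite], path: str | Path) -> None:
    payload = [
        {
            "structure_id": site.ion.structure_id,
            "element": site.ion.element,
            "ion_chain": site.ion.chain_id,
            "chain": site.residues[0].chain_id,
            "chain_length": site.chain_length,
            "residues": [
                {
                    "residue": r.residue_type,
                    "seq_index": r.seq_index,
                    "donor_atom": r.donor_atom,
                    "distance": round(r.distance, 3),
                }
                for r in site.residues
            ],
        }
        for site in sites
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
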