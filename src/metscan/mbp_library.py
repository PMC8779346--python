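"""Metal-binding patterns (MBPs) and the per-metal pattern library.

An MBP is the sequence-expressible fingerprint of a structural metal site:
the ordered ligand residue types plus the number of sequence positions
between consecutive ligands.  Example: a structural zinc site with cysteines
at positions 3 and 6 and histidines at 20 and 24 becomes ligands ``CCHH``
with gaps ``3,14,4``.  Patterns with identical ligands but different gap
vectors are distinct — spacing is the signal the downstream filter uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .constants import AA_SET, ESSENTIAL_METALS, METALS, NON_ESSENTIAL_METALS
from .structure_sites import MetalSite

logger = logging.getLogger(__name__)

__all__ = [
    "MetalBindingPattern",
    "MBPLibrary",
    "PatternError",
    "LibraryFormatError",
    "site_to_mbp",
    "dedupe",
    "save_library",
    "load_library",
]


class PatternError(ValueError):
    """Raised for sites or rows that cannot form a valid pattern."""


class LibraryFormatError(ValueError):
    """Raised for malformed library files (names the offending line)."""


@dataclass(frozen=True)
class MetalBindingPattern:
    """Ordered ligand residue types with inter-ligand sequence gaps."""

    mbp_id: str
    element: str
    ligands: tuple[str, ...]
    gaps: tuple[int, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.element not in METALS:
            raise PatternError(f"element {self.element!r} not in metal vocabulary")
        if len(self.ligands) < 2:
            raise PatternError("a pattern needs at least 2 ligands")
        if len(self.gaps) != len(self.ligands) - 1:
            raise PatternError(
                f"{len(self.ligands)} ligands require {len(self.ligands) - 1} gaps, "
                f"got {len(self.gaps)}"
            )
        if any(g < 1 for g in self.gaps):
            raise PatternError("gaps must be >= 1")
        bad = [l for l in self.ligands if l not in AA_SET]
        if bad:
            raise PatternError(f"non-standard ligand residue(s): {bad}")

    @property
    def span(self) -> int:
        """Number of sequence positions covered, first to last ligand inclusive."""
        return 1 + sum(self.gaps)

    @property
    def key(self) -> tuple[str, tuple[str, ...], tuple[int, ...]]:
        """Identity for deduplication: element + ligands + gaps."""
        return (self.element, self.ligands, self.gaps)


@dataclass(frozen=True)
class MBPLibrary:
    """A deduplicated collection of patterns plus the metal partition."""

    patterns: tuple[MetalBindingPattern, ...]
    essential_set: frozenset[str] = ESSENTIAL_METALS
    non_essential_set: frozenset[str] = NON_ESSENTIAL_METALS

    def __post_init__(self) -> None:
        ids = [p.mbp_id for p in self.patterns]
        if len(ids) != len(set(ids)):
            raise PatternError("mbp_ids must be unique")
        if self.essential_set & self.non_essential_set:
            raise PatternError("essential and non-essential metal sets must be disjoint")

    def by_element(self, element: str) -> tuple[MetalBindingPattern, ...]:
        return tuple(p for p in self.patterns if p.element == element)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted({p.element for p in self.patterns}))

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)


def site_to_mbp(site: MetalSite, mbp_id: str | None = None) -> MetalBindingPattern:
    """Read the pattern straight off a metal site's residue indices.

    Raises :class:`PatternError` for sites with fewer than two residues
    (no spacing to express).
    """
    if len(site.residues) < 2:
        raise PatternError(
            f"site on {site.ion.structure_id} has {len(site.residues)} residue(s); "
            "a pattern needs at least 2"
        )
    ligands = tuple(r.residue_type for r in site.residues)
    idx = [r.seq_index for r in site.residues]
    gaps = tuple(b - a for a, b in zip(idx, idx[1:]))
    source = f"{site.ion.structure_id}:{site.residues[0].chain_id}"
    if mbp_id is None:
        mbp_id = f"{site.ion.element}_{''.join(ligands)}_{'-'.join(map(str, gaps))}_{source}"
    return MetalBindingPattern(
        mbp_id=mbp_id, element=site.ion.element, ligands=ligands, gaps=gaps, source=source
    )


def dedupe(patterns: Iterable[MetalBindingPattern]) -> MBPLibrary:
    """Collapse exact duplicates (same element, ligands and gaps), keeping the
    first occurrence.  Idempotent."""
    seen: dict[tuple, MetalBindingPattern] = {}
    n_dup = 0
    for p in patterns:
        if p.key in seen:
            n_dup += 1
        else:
            seen[p.key] = p
    if n_dup:
        logger.info("dedupe: collapsed %d duplicate pattern(s)", n_dup)
    return MBPLibrary(patterns=tuple(seen.values()))


_HEADER = "mbp_id\telement\tligands\tgaps\tsource"


def save_library(library: MBPLibrary, path: str | Path) -> None:
    """Write the library as canonical TSV (lossless round-trip)."""
    lines = [_HEADER]
    for p in library.patterns:
        lines.append(
            f"{p.mbp_id}\t{p.element}\t{''.join(p.ligands)}\t"
            f"{','.join(map(str, p.gaps))}\t{p.source}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_library(path: str | Path) -> MBPLibrary:
    """Read a library TSV; malformed rows are reported with line numbers."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _HEADER:
        raise LibraryFormatError(f"{path}:1: expected header {_HEADER!r}")
    patterns: list[MetalBindingPattern] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise LibraryFormatError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        mbp_id, element, ligands, gaps_s, source = parts
        try:
            gaps = tuple(int(g) for g in gaps_s.split(",")) if gaps_s else ()
            patterns.append(
                MetalBindingPattern(
                    mbp_id=mbp_id,
                    element=element,
                    ligands=tuple(ligands),
                    gaps=gaps,
                    source=source,
                )
            )
        except (ValueError, PatternError) as exc:
            raise LibraryFormatError(f"{path}:{lineno}: {exc}") from exc
    return MBPLibrary(patterns=tuple(patterns))
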