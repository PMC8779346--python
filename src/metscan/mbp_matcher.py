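"""Spacing-tolerant search for metal-binding patterns in sequences.

This is the false-positive filter of the pipeline: a candidate protein is
kept for a metal only if some pattern of that metal places *all* of its
ligand residues in the sequence with each inter-ligand spacing conserved
within a tolerance.

Tolerance rule
--------------
For a pattern gap of ``g`` residues the allowed deviation is ±20% of ``g``
(rounded down), but never less than ±1 residue: gaps short enough that 20%
rounds down to zero fall back to the absolute ±1 rule.  The 20% window is
applied to each inter-ligand gap, not to the protein length — the per-gap
reading is the only one under which a separate short-spacing fallback is
meaningful.  A whole-pattern-span tolerance mode is available as an
alternative (``MatchPolicy.mode = "span"``): individual gaps float freely
(observed gaps only need to stay >= 1) while the first-to-last ligand span
must stay within the tolerance computed on the pattern's total span.

The search itself is a banded placement walk: candidate positions for each
ligand are extended gap by gap, visiting only positions inside each gap's
tolerance window, so it enumerates exactly the placements a brute-force
scan over all increasing position tuples would accept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domain_scan import DomainHit, ProteinRecord
from .mbp_library import MBPLibrary, MetalBindingPattern

logger = logging.getLogger(__name__)

__all__ = [
    "MatchPolicy",
    "MBPMatch",
    "ConsistencyError",
    "gap_tolerance",
    "match_mbp",
    "filter_candidates",
    "write_matches_tsv",
]


class ConsistencyError(ValueError):
    """Raised when candidate protein ids are missing from the proteome."""


@dataclass(frozen=True)
class MatchPolicy:
    """Tolerance policy for pattern placement.

    relative_tolerance
        Fraction of each pattern gap allowed as deviation (default 0.20).
    short_gap_abs
        Absolute deviation granted when the relative window rounds down to
        zero (default ±1).
    short_gap_threshold
        Optional explicit gap length at or below which the absolute rule
        applies; None (default) triggers it automatically exactly where
        floor(relative_tolerance × gap) < 1.
    mode
        "per_gap" (default) constrains every inter-ligand gap; "span"
        constrains only the first-to-last ligand span.
    search_window
        When True, ``filter_candidates`` restricts matching to domain-hit
        envelopes.
    substitution_groups
        Optional residue equivalence classes (e.g. ("D","E")) accepted in
        place of exact ligand identity; off by default.
    """

    relative_tolerance: float = 0.20
    short_gap_abs: int = 1
    short_gap_threshold: int | None = None
    mode: str = "per_gap"
    search_window: bool = False
    substitution_groups: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.relative_tolerance <= 1):
            raise ValueError("relative_tolerance must be in [0, 1]")
        if self.short_gap_abs < 0:
            raise ValueError("short_gap_abs must be >= 0")
        if self.short_gap_threshold is not None and self.short_gap_threshold < 1:
            raise ValueError("short_gap_threshold must be >= 1")
        if self.mode not in ("per_gap", "span"):
            raise ValueError("mode must be 'per_gap' or 'span'")

    def equivalent(self, ligand: str, residue: str) -> bool:
        if residue == ligand:
            return True
        if self.substitution_groups:
            for group in self.substitution_groups:
                if ligand in group and residue in group:
                    return True
        return False


@dataclass(frozen=True)
class MBPMatch:
    """A surviving placement of a pattern onto a protein sequence."""

    protein_id: str
    mbp_id: str
    positions: tuple[int, ...]  # 1-based, strictly increasing
    deviations: tuple[int, ...]  # observed gap − pattern gap, per gap

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("match positions must be strictly increasing")
        if len(self.deviations) != len(self.positions) - 1:
            raise ValueError("one deviation per gap required")


def gap_tolerance(gap: int, policy: MatchPolicy | None = None) -> int:
    """Allowed absolute deviation (in residues) for one pattern gap.

    floor(relative_tolerance × gap) when that is at least 1; otherwise the
    short-spacing absolute allowance.  With an explicit
    ``short_gap_threshold``, gaps at or below it get at least the absolute
    allowance.
    """
    if gap < 1:
        raise ValueError(f"gap must be >= 1, got {gap}")
    if policy is None:
        policy = MatchPolicy()
    base = math.floor(policy.relative_tolerance * gap)
    if policy.short_gap_threshold is not None:
        return max(base, policy.short_gap_abs) if gap <= policy.short_gap_threshold else base
    return base if base >= 1 else policy.short_gap_abs


def _candidate_positions(
    sequence: str, ligand: str, policy: MatchPolicy, lo: int, hi: int
) -> list[int]:
    """1-based positions in [lo, hi] where the ligand (or an allowed
    substitute) occurs."""
    lo = max(lo, 1)
    hi = min(hi, len(sequence))
    return [
        i + 1
        for i in range(lo - 1, hi)
        if policy.equivalent(ligand, sequence[i])
    ]


def match_mbp(
    sequence: str,
    mbp: MetalBindingPattern,
    policy: MatchPolicy | None = None,
    protein_id: str = "",
    window: tuple[int, int] | None = None,
) -> list[MBPMatch]:
    """All placements of ``mbp`` on ``sequence`` allowed by the policy.

    Returns every increasing position tuple where ligand identities match
    and every gap deviation is within its tolerance (per-gap mode) or the
    total span deviation is within the span tolerance (span mode).  Matches
    are ordered by position tuple (lexicographic, hence by first position).
    An empty list means no placement survives — absence is a value.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if policy is None:
        policy = MatchPolicy()
    sequence = sequence.upper()
    k = len(mbp.ligands)
    win_lo, win_hi = (1, len(sequence)) if window is None else window

    if policy.mode == "per_gap":
        tols = [gap_tolerance(g, policy) for g in mbp.gaps]
        # minimal / maximal residues the remaining pattern needs after ligand i
        min_rest = [0] * k
        for i in range(k - 2, -1, -1):
            min_rest[i] = min_rest[i + 1] + max(1, mbp.gaps[i] - tols[i])
        starts = _candidate_positions(
            sequence, mbp.ligands[0], policy, win_lo, win_hi - min_rest[0]
        )
        results: list[tuple[int, ...]] = []
        stack: list[tuple[int, tuple[int, ...]]] = [(0, (p,)) for p in reversed(starts)]
        while stack:
            i, positions = stack.pop()
            if i == k - 1:
                results.append(positions)
                continue
            p = positions[-1]
            lo = max(p + 1, p + mbp.gaps[i] - tols[i])
            hi = min(p + mbp.gaps[i] + tols[i], win_hi - min_rest[i + 1])
            nxt = _candidate_positions(sequence, mbp.ligands[i + 1], policy, lo, hi)
            for q in reversed(nxt):
                stack.append((i + 1, positions + (q,)))
    else:  # span mode
        span_gap_total = sum(mbp.gaps)
        span_tol = gap_tolerance(span_gap_total, policy)
        results = []
        starts = _candidate_positions(
            sequence, mbp.ligands[0], policy, win_lo, win_hi - (k - 1)
        )
        stack = [(0, (p,)) for p in reversed(starts)]
        while stack:
            i, positions = stack.pop()
            if i == k - 1:
                if abs((positions[-1] - positions[0]) - span_gap_total) <= span_tol:
                    results.append(positions)
                continue
            p = positions[-1]
            remaining = k - 1 - (i + 1)  # ligands still to place after the next one
            lo = p + 1
            hi = min(positions[0] + span_gap_total + span_tol - remaining, win_hi - remaining)
            nxt = _candidate_positions(sequence, mbp.ligands[i + 1], policy, lo, hi)
            for q in reversed(nxt):
                stack.append((i + 1, positions + (q,)))

    results.sort()
    return [
        MBPMatch(
            protein_id=protein_id,
            mbp_id=mbp.mbp_id,
            positions=pos,
            deviations=tuple(
                (b - a) - g for a, b, g in zip(pos, pos[1:], mbp.gaps)
            ),
        )
        for pos in results
    ]


def filter_candidates(
    candidates: Mapping[str, set[str] | Sequence[str]],
    proteome: Sequence[ProteinRecord],
    library: MBPLibrary,
    policy: MatchPolicy | None = None,
    hits: Sequence[DomainHit] | None = None,
) -> list[tuple[str, str, MBPMatch]]:
    """Apply the pattern filter to domain-scan candidates.

    A (protein, metal) pair survives iff at least one pattern of that metal
    matches the protein's sequence; all surviving matches are returned as
    ``(protein_id, element, match)`` tuples in deterministic order.  When
    ``policy.search_window`` is set and ``hits`` are supplied, matching is
    restricted to the protein's domain-hit envelopes.
    """
    if policy is None:
        policy = MatchPolicy()
    by_id = {p.protein_id: p for p in proteome}
    missing = sorted(
        {pid for pids in candidates.values() for pid in pids if pid not in by_id}
    )
    if missing:
        raise ConsistencyError(
            f"{len(missing)} candidate protein(s) absent from proteome: {missing[:10]}"
        )

    envelopes: dict[str, list[tuple[int, int]]] = {}
    if policy.search_window and hits is not None:
        for h in hits:
            envelopes.setdefault(h.protein_id, []).append((h.env_from, h.env_to))

    out: list[tuple[str, str, MBPMatch]] = []
    n_pairs_in = n_pairs_kept = 0
    for element in sorted(candidates):
        patterns = library.by_element(element)
        for pid in sorted(candidates[element]):
            n_pairs_in += 1
            seq = by_id[pid].sequence
            pair_matches: list[MBPMatch] = []
            for mbp in patterns:
                if policy.search_window and hits is not None:
                    for window in envelopes.get(pid, []):
                        pair_matches.extend(
                            match_mbp(seq, mbp, policy, protein_id=pid, window=window)
                        )
                else:
                    pair_matches.extend(match_mbp(seq, mbp, policy, protein_id=pid))
            if pair_matches:
                n_pairs_kept += 1
                # dedupe identical placements found through overlapping windows
                seen: set[tuple[str, tuple[int, ...]]] = set()
                for m in pair_matches:
                    key = (m.mbp_id, m.positions)
                    if key not in seen:
                        seen.add(key)
                        out.append((pid, element, m))
    logger.info(
        "pattern filter: %d/%d candidate (protein, metal) pairs survive",
        n_pairs_kept, n_pairs_in,
    )
    return out


_TSV_HEADER = "protein_id\telement\tmbp_id\tpositions\tdeviations"


def write_matches_tsv(
    matches: Iterable[tuple[str, str, MBPMatch]], path: str | Path
) -> None:
    lines = [_TSV_HEADER]
    for pid, element, m in matches:
        lines.append(
            f"{pid}\t{element}\t{m.mbp_id}\t"
            f"{','.join(map(str, m.positions))}\t{','.join(map(str, m.deviations))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
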