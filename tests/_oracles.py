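"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exhaustive enumeration, all-pairs
distance scans, and plain set algebra.  None of it shares code with the
package's search/detection/census paths.
"""

from __future__ import annotations

import math
from collections import defaultdict

import gemmi

from metscan.constants import METALS, residue_to_one_letter


def oracle_gap_tolerance(gap: int, relative: float = 0.20, short_abs: int = 1) -> int:
    """The spacing rule restated from scratch: ±relative of the gap, floored,
    falling back to the absolute short-spacing allowance when that floor
    reaches zero."""
    window = int(math.floor(relative * gap))
    return window if window >= 1 else short_abs


def brute_force_matches(
    sequence: str,
    ligands: tuple[str, ...],
    gaps: tuple[int, ...],
    relative: float = 0.20,
    short_abs: int = 1,
) -> set[tuple[int, ...]]:
    """All increasing 1-based position tuples with exact ligand identity and
    every gap deviation within tolerance, by exhaustive recursion over the
    full candidate-position lists."""
    sequence = sequence.upper()
    candidates = [
        [i + 1 for i, c in enumerate(sequence) if c == lig] for lig in ligands
    ]
    tol = [oracle_gap_tolerance(g, relative, short_abs) for g in gaps]
    out: set[tuple[int, ...]] = set()

    def extend(prefix: tuple[int, ...]) -> None:
        i = len(prefix)
        if i == len(ligands):
            out.add(prefix)
            return
        for p in candidates[i]:
            if prefix:
                if p <= prefix[-1]:
                    continue
                if abs((p - prefix[-1]) - gaps[i - 1]) > tol[i - 1]:
                    continue
            extend(prefix + (p,))

    extend(())
    return out


def n_candidate_tuples(sequence: str, ligands: tuple[str, ...]) -> int:
    n = 1
    for lig in ligands:
        n *= sequence.upper().count(lig)
    return n


def brute_force_sites(
    path, cutoff: float = 3.0, min_ligands: int = 2
) -> list[tuple[str, str, tuple[tuple[int, str], ...]]]:
    """All-pairs metal-atom distance scan on a structure file.

    Returns (element, chain, ((seq_index, residue_one_letter), ...)) per
    detected site, single best chain per ion, ligands sorted by index.
    A donor is any N/O/S atom except the backbone amide N.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]

    # flatten every atom with its residue context
    polymer_atoms = []  # (chain, seq_index, one, atom)
    metal_atoms = []  # (element, position)
    for chain in model:
        seq_index = 0
        for residue in chain:
            one = residue_to_one_letter(residue.name)
            if one is not None:
                seq_index += 1
                for atom in residue:
                    polymer_atoms.append((chain.name, seq_index, one, atom))
            else:
                for atom in residue:
                    if atom.element.name in METALS:
                        metal_atoms.append((atom.element.name, atom.pos))

    sites = []
    for element, pos in metal_atoms:
        per_chain: dict[str, dict[int, str]] = defaultdict(dict)
        for chain_name, seq_index, one, atom in polymer_atoms:
            el = atom.element.name
            if el not in ("N", "O", "S") or atom.name == "N":
                continue
            if pos.dist(atom.pos) <= cutoff:
                per_chain[chain_name][seq_index] = one
        if not per_chain:
            continue
        best = min(per_chain, key=lambda c: (-len(per_chain[c]), c))
        ligands = tuple(sorted(per_chain[best].items()))
        if len(ligands) >= min_ligands:
            sites.append((element, best, tuple((i, r) for i, r in ligands)))
    return sites


def census_oracle(
    proteome_ids: list[str],
    predictions: set[tuple[str, str]],
    essential: frozenset[str],
    non_essential: frozenset[str],
) -> dict:
    """Plain set-algebra recomputation of the census core quantities."""
    n = len(proteome_ids)
    by_metal: dict[str, set[str]] = defaultdict(set)
    for pid, metal in predictions:
        by_metal[metal].add(pid)
    metals_of: dict[str, set[str]] = defaultdict(set)
    for pid, metal in predictions:
        metals_of[pid].add(metal)
    emb = set().union(*[by_metal[m] for m in essential if m in by_metal], set())
    non_emb = set().union(*[by_metal[m] for m in non_essential if m in by_metal], set())
    predicted = {pid for pid, _m in predictions}
    unique = {
        m: {pid for pid in by_metal[m] if len(metals_of[pid]) == 1} for m in by_metal
    }
    recurrent = {pid for pid, ms in metals_of.items() if len(ms) >= 2}
    pct = lambda s: 100.0 * len(s) / n if n else 0.0
    return {
        "per_metal_percent": {m: pct(v) for m, v in by_metal.items()},
        "emb_percent": pct(emb),
        "non_emb_percent": pct(non_emb),
        "total_percent": pct(predicted),
        "unique_counts": {m: len(v) for m, v in unique.items()},
        "recurrent": recurrent,
        "n_unique_total": sum(len(v) for v in unique.values()),
        "n_predicted": len(predicted),
    }
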