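"""Profile-HMM candidate screening of proteomes.

Before the spacing-tolerant pattern filter runs, each proteome is scanned
against a library of metal-binding domain profiles (HMMER3 format) and only
proteins hitting at least one profile at E ≤ threshold (default 0.05,
full-sequence E-value) are nominated as candidates for the metals that
profile flags.  The profile→metal assignment is user-supplied configuration
(TSV), because no fixed enumeration of metal-binding domains ships with the
package.

The scan engine is pyhmmer (a HMMER3 implementation); profiles built by any
hmmbuild-compatible tool, including the synthetic-profile generator in
:mod:`metscan.synthetic_data`, work unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyhmmer
from Bio import SeqIO

from .constants import AA_SET, METALS

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "DomainScanPolicy",
    "DomainScanError",
    "read_fasta",
    "write_fasta",
    "read_hmms",
    "load_domain_map",
    "save_domain_map",
    "scan_proteome",
    "candidates_by_metal",
    "write_hits_tsv",
]


class DomainScanError(ValueError):
    """Raised for malformed HMM files or domain-map tables."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry with optional functional annotation."""

    protein_id: str
    sequence: str
    ec_number: str | None = None
    localization: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        unknown = set(seq) - AA_SET - {"X"}
        if unknown:
            raise ValueError(
                f"{self.protein_id}: non-amino-acid characters {sorted(unknown)}"
            )
        if "X" in seq:
            logger.debug("%s: sequence contains X (unknown residue)", self.protein_id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A profile hit on a protein at full-sequence E-value."""

    protein_id: str
    domain_id: str
    evalue: float
    env_from: int  # 1-based inclusive envelope
    env_to: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (1 <= self.env_from <= self.env_to):
            raise ValueError("envelope must satisfy 1 <= env_from <= env_to")


@dataclass(frozen=True)
class DomainScanPolicy:
    """E-value acceptance threshold and the profile→metal assignment."""

    evalue_threshold: float = 0.05
    domain_to_metals: Mapping[str, tuple[str, ...]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.domain_to_metals is None:
            object.__setattr__(self, "domain_to_metals", {})
        for domain_id, metals in self.domain_to_metals.items():
            bad = [m for m in metals if m not in METALS]
            if bad:
                raise ValueError(f"domain {domain_id}: unknown metal(s) {bad}")


def _accession_from_description(description: str) -> str:
    """UniProt-style ``db|ACC|NAME`` headers yield ACC; otherwise the first
    whitespace-delimited token."""
    token = description.split()[0]
    if token.count("|") == 2:
        return token.split("|")[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                protein_id=_accession_from_description(rec.description),
                sequence=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_hmms(path: str | Path) -> list[pyhmmer.plan7.HMM]:
    path = Path(path)
    try:
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            return list(fh)
    except (ValueError, EOFError, OSError) as exc:
        raise DomainScanError(f"cannot parse {path} as HMMER3: {exc}") from exc


_MAP_HEADER = "domain_id\tmetals"


def load_domain_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read the profile→metals TSV (columns: domain_id, comma-joined metals)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _MAP_HEADER:
        raise DomainScanError(f"{path}:1: expected header {_MAP_HEADER!r}")
    mapping: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DomainScanError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        domain_id, metals_s = parts
        metals = tuple(m for m in metals_s.split(",") if m)
        bad = [m for m in metals if m not in METALS]
        if bad:
            raise DomainScanError(f"{path}:{lineno}: unknown metal(s) {bad}")
        mapping[domain_id] = metals
    return mapping


def save_domain_map(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [_MAP_HEADER]
    for domain_id in sorted(mapping):
        lines.append(f"{domain_id}\t{','.join(mapping[domain_id])}")
    Path(path).write_text("\n".join(lines) + "\n")


def scan_proteome(
    proteome: Sequence[ProteinRecord],
    profiles: Sequence[pyhmmer.plan7.HMM],
    policy: DomainScanPolicy | None = None,
) -> list[DomainHit]:
    """hmmsearch every profile against the proteome; keep hits with
    full-sequence E-value ≤ the policy threshold.

    Envelope coordinates come from the best-scoring domain of each hit.
    Hits whose profile has no metal assignment are kept (and logged) — the
    metal join happens in :func:`candidates_by_metal`.
    """
    if policy is None:
        policy = DomainScanPolicy()
    if not proteome:
        logger.warning("scan_proteome: empty proteome, no hits")
        return []
    alphabet = pyhmmer.easel.Alphabet.amino()
    digital = [
        pyhmmer.easel.TextSequence(
            name=rec.protein_id.encode(), sequence=rec.sequence
        ).digitize(alphabet)
        for rec in proteome
    ]
    hits: list[DomainHit] = []
    unmapped: set[str] = set()
    def _name(x) -> str:
        return x.decode() if isinstance(x, bytes) else str(x)

    for top_hits in pyhmmer.hmmsearch(profiles, digital, cpus=1):
        query = _name(top_hits.query.name)
        for hit in top_hits:
            if hit.evalue > policy.evalue_threshold:
                continue
            name = _name(hit.name)
            dom = hit.best_domain
            hits.append(
                DomainHit(
                    protein_id=name,
                    domain_id=query,
                    evalue=hit.evalue,
                    env_from=dom.env_from,
                    env_to=dom.env_to,
                )
            )
            if query not in policy.domain_to_metals:
                unmapped.add(query)
    if unmapped:
        logger.warning(
            "scan_proteome: %d profile(s) with hits have no metal assignment: %s",
            len(unmapped), sorted(unmapped),
        )
    hits.sort(key=lambda h: (h.protein_id, h.domain_id, h.evalue))
    logger.info(
        "scan_proteome: %d hit(s) at E <= %g over %d proteins x %d profiles",
        len(hits), policy.evalue_threshold, len(proteome), len(profiles),
    )
    return hits


def candidates_by_metal(
    hits: Iterable[DomainHit],
    policy: DomainScanPolicy,
) -> dict[str, set[str]]:
    """Join hits with the profile→metal map: a protein is a candidate for
    every metal any of its hit profiles flags.  Keys sorted for
    deterministic iteration."""
    out: dict[str, set[str]] = {}
    for hit in hits:
        for metal in policy.domain_to_metals.get(hit.domain_id, ()):
            out.setdefault(metal, set()).add(hit.protein_id)
    return {metal: out[metal] for metal in sorted(out)}


_TSV_HEADER = "protein_id\tdomain_id\tevalue\tenv_from\tenv_to"


def write_hits_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    lines = [_TSV_HEADER]
    for h in hits:
        lines.append(
            f"{h.protein_id}\t{h.domain_id}\t{h.evalue:.3e}\t{h.env_from}\t{h.env_to}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
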