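"""Download-free synthetic fixtures with ground truth.

Three generators close the testing loop for every pipeline stage:

* :func:`make_structure` — a minimal structure (mmCIF + PDB) with one metal
  ion at the origin, planted donor atoms at an exact coordination distance,
  and every other atom beyond a decoy floor, so the expected metal site is
  known by construction.
* :func:`make_proteome` — a FASTA proteome of i.i.d. background sequences
  with motif instances planted at controlled per-gap perturbations, an
  annotation table, and a ground-truth record stating which plants must
  survive the spacing filter under a named policy.
* :func:`make_toy_hmms` — profile HMMs built from ungapped alignments of
  sampled instances of each planted motif, standing in for a curated
  domain library.

Planted motifs are instances of a per-pattern *template*: ligand residues
at the pattern spacing, interiors drawn once as a non-ligand consensus and
then re-sampled per instance with a small substitution rate.  Interiors
never contain the pattern's own ligand residues, so no accidental earlier
placement exists inside a planted span.  Background composition defaults to
uniform over the 20 residues with the common ligand residues (C, H, D, E,
M) down-weighted 2x, keeping accidental full-pattern matches rare at test
scale.  All randomness flows from explicit seeds; the same seed gives
byte-identical output files.

Synthetic structures use a schematic poly-alanine backbone with only the
planted donor atoms displaced toward the metal; no physical plausibility is
claimed or needed for distance-based site detection.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pyhmmer

from .constants import (
    AA_ONE_LETTER,
    DONOR_CAPABLE_RESIDUES,
    METALS,
    ONE_TO_THREE,
    PLANT_DONOR_ATOM,
)
from .domain_scan import ProteinRecord
from .mbp_library import MetalBindingPattern
from .mbp_matcher import MatchPolicy, gap_tolerance
from .structure_sites import CoordinatingResidue, MetalIon, MetalSite

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpecError",
    "SyntheticStructureSpec",
    "PlantSpec",
    "SyntheticProteomeSpec",
    "GroundTruthEntry",
    "GroundTruth",
    "ProteomeBundle",
    "MotifTemplate",
    "default_residue_frequencies",
    "build_structure",
    "expected_site",
    "make_structure",
    "make_proteome",
    "make_toy_hmms",
]

MAX_PLANTED_DONORS = 30


class SyntheticSpecError(ValueError):
    """Raised for infeasible or inconsistent generator specifications."""


# --------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Recipe for one synthetic metal-site structure."""

    element: str
    ligand_plan: tuple[tuple[str, int], ...]  # (one-letter residue, 1-based seq index)
    chain_length: int
    coordination_distance: float = 2.1
    decoy_min_distance: float = 5.0
    structure_id: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element not in METALS:
            raise SyntheticSpecError(f"unknown metal {self.element!r}")
        if len(self.ligand_plan) < 1:
            raise SyntheticSpecError("ligand_plan must not be empty")
        if len(self.ligand_plan) > MAX_PLANTED_DONORS:
            raise SyntheticSpecError(
                f"{len(self.ligand_plan)} donors exceed the coordination sphere "
                f"capacity ({MAX_PLANTED_DONORS})"
            )
        idx = [i for _r, i in self.ligand_plan]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SyntheticSpecError("ligand seq_index values must be strictly increasing")
        if idx[0] < 1 or idx[-1] > self.chain_length:
            raise SyntheticSpecError("ligand seq_index values must lie within chain_length")
        bad = [r for r, _i in self.ligand_plan if r not in DONOR_CAPABLE_RESIDUES]
        if bad:
            raise SyntheticSpecError(
                f"residue type(s) {bad} have no side-chain donor atom to plant"
            )
        if not (0 < self.coordination_distance < self.decoy_min_distance):
            raise SyntheticSpecError(
                "need 0 < coordination_distance < decoy_min_distance"
            )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _mk_atom(name: str, element: str, x: float, y: float, z: float) -> gemmi.Atom:
    a = gemmi.Atom()
    a.name = name
    a.element = gemmi.Element(element)
    a.pos = gemmi.Position(x, y, z)
    a.occ = 1.0
    a.b_iso = 20.0
    return a


def build_structure(spec: SyntheticStructureSpec) -> gemmi.Structure:
    """Assemble the synthetic structure in memory (chain A polymer, chain B ion)."""
    planted = {seq_index: r for r, seq_index in spec.ligand_plan}
    directions = _fibonacci_directions(max(1, len(spec.ligand_plan)))
    donor_dir = {
        seq_index: directions[j] for j, (_r, seq_index) in enumerate(spec.ligand_plan)
    }

    st = gemmi.Structure()
    st.name = spec.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    y0 = spec.decoy_min_distance + 2.0
    for i in range(1, spec.chain_length + 1):
        one = planted.get(i)
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[one] if one else "ALA"
        res.seqid = gemmi.SeqId(i, " ")
        x = (i - 1) * 3.0
        res.add_atom(_mk_atom("N", "N", x, y0, 0.0))
        res.add_atom(_mk_atom("CA", "C", x + 1.0, y0, 0.0))
        res.add_atom(_mk_atom("C", "C", x + 2.0, y0, 0.0))
        res.add_atom(_mk_atom("O", "O", x + 2.0, y0 + 1.0, 0.0))
        if one:
            d = donor_dir[i] * spec.coordination_distance
            donor = PLANT_DONOR_ATOM[one]
            res.add_atom(_mk_atom(donor, _donor_element(donor), d[0], d[1], d[2]))
        chain.add_residue(res)
    model.add_chain(chain)

    ion_chain = gemmi.Chain("B")
    ion_res = gemmi.Residue()
    ion_res.name = spec.element.upper()
    ion_res.seqid = gemmi.SeqId(spec.chain_length + 1, " ")
    ion_res.het_flag = "H"
    ion_res.add_atom(_mk_atom(spec.element.upper(), spec.element, 0.0, 0.0, 0.0))
    ion_chain.add_residue(ion_res)
    model.add_chain(ion_chain)

    st.add_model(model)
    st.setup_entities()
    return st


def _donor_element(atom_name: str) -> str:
    return {"S": "S", "N": "N", "O": "O"}[atom_name[0]]


def expected_site(spec: SyntheticStructureSpec) -> MetalSite:
    """The metal site :func:`detect_metal_sites` must report, by construction."""
    ion = MetalIon(
        element=spec.element,
        structure_id=spec.structure_id,
        chain_id="B",
        position=(0.0, 0.0, 0.0),
    )
    residues = tuple(
        CoordinatingResidue(
            residue_type=r,
            chain_id="A",
            seq_index=i,
            donor_atom=PLANT_DONOR_ATOM[r],
            distance=spec.coordination_distance,
        )
        for r, i in spec.ligand_plan
    )
    return MetalSite(ion=ion, residues=residues, chain_length=spec.chain_length)


def make_structure(
    spec: SyntheticStructureSpec, out_dir: str | Path
) -> tuple[Path, Path, MetalSite]:
    """Write the structure as mmCIF and PDB; return paths and expected site."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = build_structure(spec)
    cif_path = out_dir / f"{spec.structure_id}.cif"
    pdb_path = out_dir / f"{spec.structure_id}.pdb"
    cif_path.write_text(st.make_mmcif_document().as_string())
    pdb_path.write_text(st.make_pdb_string())
    return cif_path, pdb_path, expected_site(spec)


# --------------------------------------------------------------------------
# proteomes


def default_residue_frequencies() -> dict[str, float]:
    """Uniform composition with common ligand residues down-weighted 2x."""
    weights = {aa: 1.0 for aa in AA_ONE_LETTER}
    for aa in "CHDEM":
        weights[aa] = 0.5
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


@dataclass(frozen=True)
class MotifTemplate:
    """Fixed consensus realisation of a pattern, shared between planted
    instances and the profile alignments built over them.

    The consensus carries ``flank`` conserved non-ligand residues on each
    side of the pattern span — a planted instance is a domain, not a bare
    binding site, and the flanking context is what gives short patterns
    enough profile length for a reliable domain hit.
    """

    mbp: MetalBindingPattern
    consensus: str
    ligand_offsets: tuple[int, ...]  # 0-based within the consensus
    flank: int = 10

    @classmethod
    def from_mbp(cls, mbp: MetalBindingPattern, seed: int = 0, flank: int = 10) -> "MotifTemplate":
        rng = np.random.default_rng(
            (zlib.crc32(mbp.mbp_id.encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF
        )
        non_ligand = [aa for aa in AA_ONE_LETTER if aa not in set(mbp.ligands)]
        length = mbp.span + 2 * flank
        offsets = [flank]
        for g in mbp.gaps:
            offsets.append(offsets[-1] + g)
        chars = list(rng.choice(non_ligand, size=length))
        for off, lig in zip(offsets, mbp.ligands):
            chars[off] = lig
        return cls(
            mbp=mbp, consensus="".join(chars), ligand_offsets=tuple(offsets), flank=flank
        )

    @property
    def non_ligand_alphabet(self) -> list[str]:
        return [aa for aa in AA_ONE_LETTER if aa not in set(self.mbp.ligands)]

    def instance(
        self,
        rng: np.random.Generator,
        sub_prob: float = 0.15,
        perturbations: Sequence[int] | None = None,
    ) -> tuple[str, tuple[int, ...]]:
        """One motif instance: (sequence, 0-based ligand offsets).

        ``perturbations[i]`` inserts (positive) or deletes (negative) that
        many interior residues in gap i, changing the observed spacing by
        exactly that amount.  Flanks and gap interiors are the consensus
        with per-position substitutions (never to a ligand residue).
        """
        gaps = self.mbp.gaps
        if perturbations is None:
            perturbations = [0] * len(gaps)
        if len(perturbations) != len(gaps):
            raise SyntheticSpecError("one perturbation per gap required")
        non_ligand = self.non_ligand_alphabet

        def mutate(segment: str) -> list[str]:
            return [
                c if rng.random() >= sub_prob else str(rng.choice(non_ligand))
                for c in segment
            ]

        lig_offsets = self.ligand_offsets
        pieces: list[str] = ["".join(mutate(self.consensus[: self.flank]))]
        offsets: list[int] = [self.flank]
        pieces.append(self.mbp.ligands[0])
        for i, (g, d) in enumerate(zip(gaps, perturbations)):
            new_gap = g + d
            if new_gap < 1:
                raise SyntheticSpecError(
                    f"perturbation {d} on gap {g} collapses the spacing below 1"
                )
            interior = mutate(self.consensus[lig_offsets[i] + 1 : lig_offsets[i + 1]])
            if d > 0:
                mid = len(interior) // 2
                insert = list(rng.choice(non_ligand, size=d))
                interior = interior[:mid] + insert + interior[mid:]
            elif d < 0:
                for _ in range(-d):
                    interior.pop(int(rng.integers(0, len(interior))))
            pieces.append("".join(interior))
            pieces.append(self.mbp.ligands[i + 1])
            offsets.append(offsets[-1] + new_gap)
        pieces.append("".join(mutate(self.consensus[lig_offsets[-1] + 1 :])))
        return "".join(pieces), tuple(offsets)


@dataclass(frozen=True)
class PlantSpec:
    """How many copies of one pattern to plant and how to perturb them.

    Either ``copies`` (exact count) or ``rate`` (per-protein Bernoulli
    probability, so the count is binomial) must be given.
    """

    mbp: MetalBindingPattern
    copies: int | None = None
    rate: float | None = None
    per_gap_perturbation: tuple[int, ...] | None = None
    sub_prob: float = 0.15

    def __post_init__(self) -> None:
        if (self.copies is None) == (self.rate is None):
            raise SyntheticSpecError("exactly one of copies/rate must be set")
        if self.copies is not None and self.copies < 0:
            raise SyntheticSpecError("copies must be >= 0")
        if self.rate is not None and not (0 <= self.rate <= 1):
            raise SyntheticSpecError("rate must be in [0, 1]")
        if (
            self.per_gap_perturbation is not None
            and len(self.per_gap_perturbation) != len(self.mbp.gaps)
        ):
            raise SyntheticSpecError(
                "per_gap_perturbation length must equal the pattern's gap count"
            )


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Recipe for a synthetic proteome with planted motifs."""

    n_proteins: int
    length_range: tuple[int, int] = (150, 400)
    residue_frequencies: Mapping[str, float] | None = None
    plants: tuple[PlantSpec, ...] = ()
    co_plant: tuple[MetalBindingPattern, float] | None = None
    annotation_plan: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticSpecError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise SyntheticSpecError("length_range must satisfy 1 <= lo <= hi")
        for plant in self.plants:
            if plant.mbp.span > lo:
                raise SyntheticSpecError(
                    f"pattern {plant.mbp.mbp_id} span {plant.mbp.span} exceeds the "
                    f"minimum protein length {lo}"
                )
        if self.co_plant is not None:
            mbp, rate = self.co_plant
            if not (0 <= rate <= 1):
                raise SyntheticSpecError("co_plant rate must be in [0, 1]")
            if mbp.span > lo:
                raise SyntheticSpecError("co_plant pattern exceeds minimum protein length")
        if self.annotation_plan is not None:
            for name, probs in self.annotation_plan.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise SyntheticSpecError(
                        f"annotation_plan[{name!r}] probabilities sum to {total}, not 1"
                    )


@dataclass(frozen=True)
class GroundTruthEntry:
    """One planted motif and its fate under the named policy."""

    protein_id: str
    mbp_id: str
    element: str
    positions: tuple[int, ...]  # 1-based ligand positions in the final sequence
    perturbations: tuple[int, ...]
    survives: bool
    co_planted: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """All plants with survive/reject labels, tied to one match policy."""

    entries: tuple[GroundTruthEntry, ...]
    relative_tolerance: float
    short_gap_abs: int

    def surviving_pairs(self) -> set[tuple[str, str]]:
        return {(e.protein_id, e.element) for e in self.entries if e.survives}

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(e.protein_id, e.element) for e in self.entries}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "policy": {
                "relative_tolerance": self.relative_tolerance,
                "short_gap_abs": self.short_gap_abs,
            },
            "entries": [
                {
                    "protein_id": e.protein_id,
                    "mbp_id": e.mbp_id,
                    "element": e.element,
                    "positions": list(e.positions),
                    "perturbations": list(e.perturbations),
                    "survives": e.survives,
                    "co_planted": e.co_planted,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            entries=tuple(
                GroundTruthEntry(
                    protein_id=e["protein_id"],
                    mbp_id=e["mbp_id"],
                    element=e["element"],
                    positions=tuple(e["positions"]),
                    perturbations=tuple(e["perturbations"]),
                    survives=e["survives"],
                    co_planted=e.get("co_planted", False),
                )
                for e in payload["entries"]
            ),
            relative_tolerance=payload["policy"]["relative_tolerance"],
            short_gap_abs=payload["policy"]["short_gap_abs"],
        )


@dataclass
class ProteomeBundle:
    """In-memory result of :func:`make_proteome` plus writers."""

    spec: SyntheticProteomeSpec
    records: list[ProteinRecord]
    annotations: dict[str, tuple[str | None, str | None]]
    ground_truth: GroundTruth
    templates: dict[str, MotifTemplate]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from .census import write_annotations
        from .domain_scan import write_fasta

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "proteome.fasta",
            "annotations": out_dir / "annotations.tsv",
            "ground_truth": out_dir / "ground_truth.json",
        }
        write_fasta(self.records, paths["fasta"])
        write_annotations(self.annotations, paths["annotations"])
        self.ground_truth.to_json(paths["ground_truth"])
        return paths


def _survives(mbp: MetalBindingPattern, perturbations: Sequence[int], policy: MatchPolicy) -> bool:
    return all(
        abs(d) <= gap_tolerance(g, policy) for g, d in zip(mbp.gaps, perturbations)
    )


def make_proteome(
    spec: SyntheticProteomeSpec,
    policy: MatchPolicy | None = None,
) -> ProteomeBundle:
    """Generate the proteome, annotations, and ground truth.

    Each plant occupies its own host protein (sampled without replacement);
    a co-plant, when configured, adds an unperturbed essential-metal motif
    downstream of the primary plant in the same protein at the stated rate.
    Survive/reject labels are computed from the perturbations and the gap
    tolerances of ``policy`` (defaults).
    """
    if policy is None:
        policy = MatchPolicy()
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    freqs = dict(spec.residue_frequencies or default_residue_frequencies())
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters])
    probs = probs / probs.sum()

    def background(n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    n = spec.n_proteins
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    ids = [f"SYNP{i + 1:05d}" for i in range(n)]
    sequences = [background(int(L)) for L in lengths]

    # resolve plant counts, then assign distinct hosts
    counts: list[int] = []
    for plant in spec.plants:
        if plant.copies is not None:
            counts.append(plant.copies)
        else:
            counts.append(int(rng.binomial(n, plant.rate)))
    total = sum(counts)
    if total > n:
        raise SyntheticSpecError(
            f"{total} plants requested for {n} proteins (one plant per protein)"
        )
    hosts = rng.permutation(n)[:total]
    templates: dict[str, MotifTemplate] = {}
    entries: list[GroundTruthEntry] = []

    cursor = 0
    for plant, count in zip(spec.plants, counts):
        template = templates.setdefault(
            plant.mbp.mbp_id, MotifTemplate.from_mbp(plant.mbp, spec.seed)
        )
        perturbations = tuple(plant.per_gap_perturbation or [0] * len(plant.mbp.gaps))
        for host in hosts[cursor : cursor + count]:
            motif, offsets = template.instance(rng, plant.sub_prob, perturbations)
            seq = sequences[host]
            off = int(rng.integers(0, len(seq) + 1))
            sequences[host] = seq[:off] + motif + seq[off:]
            positions = tuple(off + o + 1 for o in offsets)
            survives = _survives(plant.mbp, perturbations, policy)
            entries.append(
                GroundTruthEntry(
                    protein_id=ids[host],
                    mbp_id=plant.mbp.mbp_id,
                    element=plant.mbp.element,
                    positions=positions,
                    perturbations=perturbations,
                    survives=survives,
                )
            )
            if spec.co_plant is not None and rng.random() < spec.co_plant[1]:
                co_mbp = spec.co_plant[0]
                co_template = templates.setdefault(
                    co_mbp.mbp_id, MotifTemplate.from_mbp(co_mbp, spec.seed)
                )
                co_motif, co_offsets = co_template.instance(rng, plant.sub_prob, None)
                seq = sequences[host]
                plant_end = positions[-1]  # insert strictly after the primary plant
                co_off = int(rng.integers(plant_end, len(seq) + 1))
                sequences[host] = seq[:co_off] + co_motif + seq[co_off:]
                entries.append(
                    GroundTruthEntry(
                        protein_id=ids[host],
                        mbp_id=co_mbp.mbp_id,
                        element=co_mbp.element,
                        positions=tuple(co_off + o + 1 for o in co_offsets),
                        perturbations=tuple([0] * len(co_mbp.gaps)),
                        survives=True,
                        co_planted=True,
                    )
                )
        cursor += count

    annotations: dict[str, tuple[str | None, str | None]] = {}
    if spec.annotation_plan is not None:
        ec_probs = dict(spec.annotation_plan.get("ec_class", {"none": 1.0}))
        loc_probs = dict(spec.annotation_plan.get("localization", {"none": 1.0}))
        ec_keys = sorted(ec_probs)
        loc_keys = sorted(loc_probs)
        ec_p = np.array([ec_probs[k] for k in ec_keys])
        loc_p = np.array([loc_probs[k] for k in loc_keys])
        for pid in ids:
            ec_cls = str(rng.choice(ec_keys, p=ec_p))
            loc = str(rng.choice(loc_keys, p=loc_p))
            ec = None if ec_cls == "none" else f"{ec_cls}.1.1.1"
            annotations[pid] = (ec, None if loc == "none" else loc)

    records = [
        ProteinRecord(
            protein_id=pid,
            sequence=seq,
            ec_number=annotations.get(pid, (None, None))[0],
            localization=annotations.get(pid, (None, None))[1],
        )
        for pid, seq in zip(ids, sequences)
    ]
    ground_truth = GroundTruth(
        entries=tuple(entries),
        relative_tolerance=policy.relative_tolerance,
        short_gap_abs=policy.short_gap_abs,
    )
    logger.info(
        "make_proteome: %d proteins, %d plants (%d surviving labels)",
        n, len(entries), sum(e.survives for e in entries),
    )
    return ProteomeBundle(
        spec=spec,
        records=records,
        annotations=annotations,
        ground_truth=ground_truth,
        templates=templates,
    )


# --------------------------------------------------------------------------
# toy profile HMMs


def make_toy_hmms(
    templates: Mapping[str, MotifTemplate] | Sequence[MotifTemplate],
    out_path: str | Path | None = None,
    n_rows: int = 20,
    sub_prob: float = 0.15,
    seed: int = 0,
) -> list[pyhmmer.plan7.HMM]:
    """Build one profile HMM per motif template (HMMER3 text format).

    Each profile is trained on an ungapped alignment of ``n_rows`` sampled
    instances of the template: ligand columns fully conserved, interior
    columns consensus-dominated.  Profile names equal the pattern ids, so
    the natural domain→metal map is ``{mbp_id: (element,)}``.
    """
    if isinstance(templates, Mapping):
        templates = list(templates.values())
    if not templates:
        raise SyntheticSpecError("need at least one motif template")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    alphabet = pyhmmer.easel.Alphabet.amino()
    background = pyhmmer.plan7.Background(alphabet)
    builder = pyhmmer.plan7.Builder(alphabet, seed=(seed & 0x7FFFFFFF) or 1)
    hmms: list[pyhmmer.plan7.HMM] = []
    for template in templates:
        rows = [
            pyhmmer.easel.TextSequence(
                name=f"row{j}".encode(),
                sequence=template.instance(rng, sub_prob)[0],
            )
            for j in range(n_rows)
        ]
        msa = pyhmmer.easel.TextMSA(
            name=template.mbp.mbp_id.encode(), sequences=rows
        ).digitize(alphabet)
        hmm, _profile, _opt = builder.build_msa(msa, background)
        hmms.append(hmm)
    if out_path is not None:
        with open(out_path, "wb") as fh:
            for hmm in hmms:
                hmm.write(fh, binary=False)
    return hmms
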