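"""Metalloproteome census statistics.

Aggregates filtered (protein, metal) predictions into the summary an
organism-level survey reports: per-metal percentage content, the split into
essential-metal-binding (EMB) and non-essential-metal-binding (non-EMB)
proteomes, unique vs recurrent proteins, enzyme-class and localization
breakdowns, and the overlap analysis asking how many non-EMB proteins also
carry an essential-metal motif.

Denominator conventions (emitted alongside every percentage so the
arithmetic is auditable):

* per-metal, EMB, non-EMB and unique percentages — total proteome size
  (number of FASTA records);
* EC-class table — number of predicted proteins with an EC annotation,
  per EMB/non-EMB side;
* localization table and enzyme fraction — predicted-set size per side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .constants import ESSENTIAL_METALS, NON_ESSENTIAL_METALS
from .domain_scan import ProteinRecord
from .mbp_library import MBPLibrary
from .mbp_matcher import MatchPolicy, MBPMatch, match_mbp

logger = logging.getLogger(__name__)

__all__ = [
    "CensusReport",
    "OverlapReport",
    "build_census",
    "emb_overlap",
    "multi_species_summary",
    "read_annotations",
    "write_annotations",
    "write_census_json",
    "write_census_markdown",
]

LOCALIZATION_VOCAB = ("membrane", "cytoplasm", "ribosome", "other")


@dataclass(frozen=True)
class OverlapReport:
    """Essential-metal motifs found inside the non-EMB predicted set."""

    overlap_percent: float  # % of non-EMB-predicted proteins with >=1 EMB motif
    n_non_emb: int
    n_overlapping: int
    per_metal_share: dict[str, float] = field(default_factory=dict)  # pie, sums to 100
    per_metal_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CensusReport:
    """All aggregate statistics for one proteome."""

    proteome_size: int
    per_metal_counts: dict[str, int]
    per_metal_percent: dict[str, float]
    emb_count: int
    emb_percent: float
    non_emb_count: int
    non_emb_percent: float
    total_predicted_count: int
    total_predicted_percent: float
    unique_counts: dict[str, int]
    unique_percent: dict[str, float]
    recurrent_ids: tuple[str, ...]
    enzyme_fraction: dict[str, float]  # side -> fraction of predicted with an EC
    ec_class_table: dict[str, dict[str, float]]  # EC class digit -> side -> %
    localization_table: dict[str, dict[str, float]]  # compartment -> side -> %
    denominators: dict[str, int]
    overlap: OverlapReport | None = None


def _predicted_sets(
    predictions: Iterable[tuple[str, str, MBPMatch]],
) -> dict[str, set[str]]:
    by_metal: dict[str, set[str]] = {}
    for pid, element, _match in predictions:
        by_metal.setdefault(element, set()).add(pid)
    return by_metal


def _union(by_metal: Mapping[str, set[str]], metals: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for m in metals:
        out |= by_metal.get(m, set())
    return out


def _side_tables(
    ids: set[str],
    annotated: Mapping[str, ProteinRecord],
) -> tuple[float, dict[str, float], dict[str, float], dict[str, int]]:
    """Enzyme fraction, EC-class % and localization % for one side."""
    n = len(ids)
    enzymes = [pid for pid in ids if annotated[pid].ec_number]
    enzyme_fraction = len(enzymes) / n if n else 0.0
    ec_pct: dict[str, float] = {}
    if enzymes:
        class_counts: dict[str, int] = {}
        for pid in enzymes:
            classes = {
                ec.strip().split(".")[0]
                for ec in annotated[pid].ec_number.split(";")
                if ec.strip()
            }
            for c in classes:
                class_counts[c] = class_counts.get(c, 0) + 1
        ec_pct = {
            c: 100.0 * class_counts[c] / len(enzymes) for c in sorted(class_counts)
        }
    loc_pct: dict[str, float] = {}
    if n:
        loc_counts = {c: 0 for c in LOCALIZATION_VOCAB + ("unannotated",)}
        for pid in ids:
            loc = annotated[pid].localization
            if loc in LOCALIZATION_VOCAB:
                loc_counts[loc] += 1
            elif loc:
                loc_counts["other"] += 1
            else:
                loc_counts["unannotated"] += 1
        loc_pct = {c: 100.0 * v / n for c, v in loc_counts.items()}
    denoms = {"predicted": n, "enzymes": len(enzymes)}
    return enzyme_fraction, ec_pct, loc_pct, denoms


def build_census(
    proteome: Sequence[ProteinRecord],
    predictions: Sequence[tuple[str, str, MBPMatch]],
    annotations: Mapping[str, tuple[str | None, str | None]] | None = None,
    essential: frozenset[str] = ESSENTIAL_METALS,
    non_essential: frozenset[str] = NON_ESSENTIAL_METALS,
) -> CensusReport:
    """Aggregate predictions into a :class:`CensusReport`.

    ``annotations`` optionally maps protein_id → (ec_number, localization)
    and overrides any annotation carried on the records themselves.
    Predictions must reference proteome members only.
    """
    ids = {p.protein_id for p in proteome}
    offenders = sorted({pid for pid, _e, _m in predictions if pid not in ids})
    if offenders:
        raise ValueError(
            f"{len(offenders)} predicted protein(s) absent from proteome: {offenders[:10]}"
        )
    n_total = len(proteome)

    annotated: dict[str, ProteinRecord] = {p.protein_id: p for p in proteome}
    if annotations:
        for pid, (ec, loc) in annotations.items():
            if pid in annotated:
                rec = annotated[pid]
                annotated[pid] = ProteinRecord(
                    protein_id=pid, sequence=rec.sequence, ec_number=ec, localization=loc
                )

    by_metal = _predicted_sets(predictions)
    all_metals = sorted(set(by_metal) | set(essential) | set(non_essential))
    per_metal_counts = {m: len(by_metal.get(m, set())) for m in all_metals}
    pct = lambda c: (100.0 * c / n_total) if n_total else 0.0
    per_metal_percent = {m: pct(c) for m, c in per_metal_counts.items()}

    emb_ids = _union(by_metal, essential)
    non_emb_ids = _union(by_metal, non_essential)
    predicted_ids = emb_ids | non_emb_ids | _union(by_metal, by_metal.keys())

    # unique vs recurrent over all metals
    metal_count: dict[str, int] = {}
    for m, pids in by_metal.items():
        for pid in pids:
            metal_count[pid] = metal_count.get(pid, 0) + 1
    recurrent_ids = tuple(sorted(pid for pid, c in metal_count.items() if c >= 2))
    unique_counts = {
        m: sum(1 for pid in by_metal.get(m, set()) if metal_count[pid] == 1)
        for m in all_metals
    }
    unique_percent = {m: pct(c) for m, c in unique_counts.items()}

    sides = {"EMB": emb_ids, "non_EMB": non_emb_ids}
    enzyme_fraction: dict[str, float] = {}
    ec_table: dict[str, dict[str, float]] = {}
    loc_table: dict[str, dict[str, float]] = {}
    denominators: dict[str, int] = {"proteome": n_total}
    for side, side_ids in sides.items():
        frac, ec_pct, loc_pct, denoms = _side_tables(side_ids, annotated)
        enzyme_fraction[side] = frac
        for c, v in ec_pct.items():
            ec_table.setdefault(c, {})[side] = v
        for c, v in loc_pct.items():
            loc_table.setdefault(c, {})[side] = v
        denominators[f"{side}_predicted"] = denoms["predicted"]
        denominators[f"{side}_enzymes"] = denoms["enzymes"]

    return CensusReport(
        proteome_size=n_total,
        per_metal_counts=per_metal_counts,
        per_metal_percent=per_metal_percent,
        emb_count=len(emb_ids),
        emb_percent=pct(len(emb_ids)),
        non_emb_count=len(non_emb_ids),
        non_emb_percent=pct(len(non_emb_ids)),
        total_predicted_count=len(predicted_ids),
        total_predicted_percent=pct(len(predicted_ids)),
        unique_counts=unique_counts,
        unique_percent=unique_percent,
        recurrent_ids=recurrent_ids,
        enzyme_fraction=enzyme_fraction,
        ec_class_table={c: ec_table[c] for c in sorted(ec_table)},
        localization_table=loc_table,
        denominators=denominators,
    )


def emb_overlap(
    predictions: Sequence[tuple[str, str, MBPMatch]],
    library: MBPLibrary,
    proteome: Sequence[ProteinRecord],
    policy: MatchPolicy | None = None,
) -> OverlapReport:
    """Essential-metal motifs inside the non-EMB predicted set.

    For each protein predicted for at least one non-essential metal, every
    essential-metal pattern in the library is matched against its sequence.
    ``overlap_percent`` is the fraction (of non-EMB-predicted proteins)
    carrying at least one essential-metal motif; ``per_metal_share`` gives
    the composition of the overlapping set by essential metal (a protein
    counts once per metal whose motif it carries; shares sum to 100).
    """
    if policy is None:
        policy = MatchPolicy()
    by_id = {p.protein_id: p for p in proteome}
    by_metal = _predicted_sets(predictions)
    non_emb_ids = sorted(_union(by_metal, library.non_essential_set))

    per_metal_counts: dict[str, int] = {}
    overlapping: set[str] = set()
    ess_patterns = {
        m: library.by_element(m) for m in sorted(library.essential_set)
    }
    for pid in non_emb_ids:
        seq = by_id[pid].sequence
        for metal, patterns in ess_patterns.items():
            if any(match_mbp(seq, mbp, policy) for mbp in patterns):
                per_metal_counts[metal] = per_metal_counts.get(metal, 0) + 1
                overlapping.add(pid)
    n = len(non_emb_ids)
    total_incidences = sum(per_metal_counts.values())
    share = {
        m: 100.0 * c / total_incidences for m, c in sorted(per_metal_counts.items())
    } if total_incidences else {}
    return OverlapReport(
        overlap_percent=(100.0 * len(overlapping) / n) if n else 0.0,
        n_non_emb=n,
        n_overlapping=len(overlapping),
        per_metal_share=share,
        per_metal_counts=dict(sorted(per_metal_counts.items())),
    )


def _mean_tables(dicts: Sequence[Mapping[str, float]]) -> dict[str, float]:
    keys = sorted({k for d in dicts for k in d})
    return {k: sum(d.get(k, 0.0) for d in dicts) / len(dicts) for k in keys}


def multi_species_summary(reports: Mapping[str, CensusReport]) -> dict:
    """Unweighted arithmetic mean of every percentage cell across species."""
    if not reports:
        raise ValueError("need at least one report")
    rs = list(reports.values())
    nested_ec = sorted({c for r in rs for c in r.ec_class_table})
    sides = ("EMB", "non_EMB")
    ec_avg = {
        c: {
            s: sum(r.ec_class_table.get(c, {}).get(s, 0.0) for r in rs) / len(rs)
            for s in sides
        }
        for c in nested_ec
    }
    loc_keys = sorted({c for r in rs for c in r.localization_table})
    loc_avg = {
        c: {
            s: sum(r.localization_table.get(c, {}).get(s, 0.0) for r in rs) / len(rs)
            for s in sides
        }
        for c in loc_keys
    }
    return {
        "n_species": len(rs),
        "species": sorted(reports),
        "per_metal_percent": _mean_tables([r.per_metal_percent for r in rs]),
        "unique_percent": _mean_tables([r.unique_percent for r in rs]),
        "emb_percent": sum(r.emb_percent for r in rs) / len(rs),
        "non_emb_percent": sum(r.non_emb_percent for r in rs) / len(rs),
        "total_predicted_percent": sum(r.total_predicted_percent for r in rs) / len(rs),
        "enzyme_fraction": _mean_tables([r.enzyme_fraction for r in rs]),
        "ec_class_table": ec_avg,
        "localization_table": loc_avg,
        "overlap_percent": (
            sum(r.overlap.overlap_percent for r in rs if r.overlap)
            / max(1, sum(1 for r in rs if r.overlap))
        ),
    }


_ANN_HEADER = "protein_id\tec_number\tlocalization"


def read_annotations(path: str | Path) -> dict[str, tuple[str | None, str | None]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _ANN_HEADER:
        raise ValueError(f"{path}:1: expected header {_ANN_HEADER!r}")
    out: dict[str, tuple[str | None, str | None]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        pid, ec, loc = parts
        out[pid] = (ec or None, loc or None)
    return out


def write_annotations(
    annotations: Mapping[str, tuple[str | None, str | None]], path: str | Path
) -> None:
    lines = [_ANN_HEADER]
    for pid in sorted(annotations):
        ec, loc = annotations[pid]
        lines.append(f"{pid}\t{ec or ''}\t{loc or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def _report_dict(report: CensusReport) -> dict:
    d = {
        "proteome_size": report.proteome_size,
        "per_metal_counts": report.per_metal_counts,
        "per_metal_percent": report.per_metal_percent,
        "emb": {"count": report.emb_count, "percent": report.emb_percent},
        "non_emb": {"count": report.non_emb_count, "percent": report.non_emb_percent},
        "total_predicted": {
            "count": report.total_predicted_count,
            "percent": report.total_predicted_percent,
        },
        "unique_counts": report.unique_counts,
        "unique_percent": report.unique_percent,
        "recurrent_ids": list(report.recurrent_ids),
        "enzyme_fraction": report.enzyme_fraction,
        "ec_class_table": report.ec_class_table,
        "localization_table": report.localization_table,
        "denominators": report.denominators,
        "conventions": {
            "percent_denominator": "total proteome size",
            "ec_table_denominator": "predicted enzymes per side",
            "localization_denominator": "predicted proteins per side",
            "spacing_tolerance": "per-gap ±20% (floor), minimum ±1",
            "overlap_denominator": "non-EMB predicted proteins",
        },
    }
    if report.overlap is not None:
        d["overlap"] = {
            "overlap_percent": report.overlap.overlap_percent,
            "n_non_emb": report.overlap.n_non_emb,
            "n_overlapping": report.overlap.n_overlapping,
            "per_metal_share": report.overlap.per_metal_share,
            "per_metal_counts": report.overlap.per_metal_counts,
        }
    return d


def write_census_json(report: CensusReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_report_dict(report), indent=2, sort_keys=True) + "\n")


def write_census_markdown(report: CensusReport, path: str | Path) -> None:
    r1 = lambda x: f"{x:.1f}"
    lines = [
        "# Metalloproteome census",
        "",
        f"Proteome size: {report.proteome_size}",
        "",
        f"- EMB proteins: {report.emb_count} ({r1(report.emb_percent)}%)",
        f"- non-EMB proteins: {report.non_emb_count} ({r1(report.non_emb_percent)}%)",
        f"- total predicted: {report.total_predicted_count} "
        f"({r1(report.total_predicted_percent)}%)",
        f"- recurrent (>=2 metals): {len(report.recurrent_ids)}",
        "",
        "## Per-metal content (% of proteome)",
        "",
        "| metal | count | % | unique count | unique % |",
        "|---|---|---|---|---|",
    ]
    for m in sorted(report.per_metal_counts):
        lines.append(
            f"| {m} | {report.per_metal_counts[m]} | {r1(report.per_metal_percent[m])} "
            f"| {report.unique_counts[m]} | {r1(report.unique_percent[m])} |"
        )
    lines += [
        "",
        "## Enzyme classes (% of predicted enzymes)",
        "",
        "| EC class | EMB | non-EMB |",
        "|---|---|---|",
    ]
    for c, row in report.ec_class_table.items():
        lines.append(f"| {c} | {r1(row.get('EMB', 0.0))} | {r1(row.get('non_EMB', 0.0))} |")
    lines += [
        "",
        "## Localization (% of predicted proteins)",
        "",
        "| compartment | EMB | non-EMB |",
        "|---|---|---|",
    ]
    for c in LOCALIZATION_VOCAB + ("unannotated",):
        row = report.localization_table.get(c, {})
        lines.append(f"| {c} | {r1(row.get('EMB', 0.0))} | {r1(row.get('non_EMB', 0.0))} |")
    if report.overlap is not None:
        lines += [
            "",
            "## Essential-metal motifs in the non-EMB set",
            "",
            f"{report.overlap.n_overlapping} of {report.overlap.n_non_emb} "
            f"non-EMB proteins ({r1(report.overlap.overlap_percent)}%) carry at "
            "least one essential-metal motif.",
            "",
            "| metal | proteins | share of overlap (%) |",
            "|---|---|---|",
        ]
        for m, c in report.overlap.per_metal_counts.items():
            lines.append(f"| {m} | {c} | {r1(report.overlap.per_metal_share[m])} |")
    Path(path).write_text("\n".join(lines) + "\n")
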