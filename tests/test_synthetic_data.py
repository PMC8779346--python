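"""Generator guarantees: determinism, round-trips, ground-truth consistency."""

import numpy as np
import pytest
from scipy import stats

from metscan.domain_scan import DomainScanPolicy, scan_proteome
from metscan.mbp_library import MetalBindingPattern, dedupe, site_to_mbp
from metscan.mbp_matcher import MatchPolicy, filter_candidates, gap_tolerance
from metscan.structure_sites import detect_metal_sites, read_structure
from metscan.synthetic_data import (
    MotifTemplate,
    PlantSpec,
    SyntheticProteomeSpec,
    SyntheticSpecError,
    SyntheticStructureSpec,
    make_proteome,
    make_structure,
    make_toy_hmms,
)


def test_spec_validation():
    with pytest.raises(SyntheticSpecError):
        SyntheticStructureSpec(element="Zn", ligand_plan=(("H", 5), ("H", 3)),
                               chain_length=10)  # not increasing
    with pytest.raises(SyntheticSpecError):
        SyntheticStructureSpec(element="Zn", ligand_plan=(("A", 3),), chain_length=10)
    with pytest.raises(SyntheticSpecError):
        SyntheticStructureSpec(element="Zn", ligand_plan=(("H", 3),), chain_length=10,
                               coordination_distance=6.0, decoy_min_distance=5.0)
    with pytest.raises(SyntheticSpecError):
        PlantSpec(mbp=MetalBindingPattern(mbp_id="m", element="Zn",
                                          ligands=("C", "C"), gaps=(3,)))
    mbp = MetalBindingPattern(mbp_id="m", element="Zn", ligands=("C", "C"), gaps=(3,))
    with pytest.raises(SyntheticSpecError):
        PlantSpec(mbp=mbp, copies=2, per_gap_perturbation=(0, 0))
    with pytest.raises(SyntheticSpecError):
        SyntheticProteomeSpec(n_proteins=5, length_range=(10, 20),
                              plants=(PlantSpec(mbp=mbp, copies=1),),
                              annotation_plan={"ec_class": {"1": 0.5}})


def test_motif_too_long_for_proteins_rejected():
    wide = MetalBindingPattern(mbp_id="w", element="Zn", ligands=("C", "C"), gaps=(80,))
    with pytest.raises(SyntheticSpecError):
        SyntheticProteomeSpec(n_proteins=5, length_range=(50, 60),
                              plants=(PlantSpec(mbp=wide, copies=1),))


def test_structure_round_trip_random_specs(tmp_path, rng):
    from metscan.constants import DONOR_CAPABLE_RESIDUES

    for i in range(30):
        chain_length = int(rng.integers(20, 50))
        k = int(rng.integers(2, 6))
        idx = sorted(rng.choice(range(1, chain_length + 1), size=k, replace=False))
        residues = rng.choice(sorted(DONOR_CAPABLE_RESIDUES), size=k)
        spec = SyntheticStructureSpec(
            element=str(rng.choice(["Zn", "Cd", "Fe", "Pb"])),
            ligand_plan=tuple((str(r), int(j)) for r, j in zip(residues, idx)),
            chain_length=chain_length,
            structure_id=f"RT{i:03d}",
        )
        cif, pdb, expected = make_structure(spec, tmp_path)
        want = site_to_mbp(expected, mbp_id="want")
        for path in (cif, pdb):
            sites = detect_metal_sites(read_structure(path))
            assert len(sites) == 1
            got = site_to_mbp(sites[0], mbp_id="want")
            assert got == want


def test_same_seed_byte_identical_outputs(tmp_path, zinc_finger_mbp):
    spec = SyntheticProteomeSpec(
        n_proteins=40, plants=(PlantSpec(mbp=zinc_finger_mbp, copies=5),),
        annotation_plan={"ec_class": {"1": 0.3, "none": 0.7},
                         "localization": {"membrane": 0.5, "none": 0.5}},
        seed=7,
    )
    outs = []
    for sub in ("a", "b"):
        bundle = make_proteome(spec)
        paths = bundle.write(tmp_path / sub)
        outs.append(paths)
    for key in ("fasta", "annotations", "ground_truth"):
        assert outs[0][key].read_bytes() == outs[1][key].read_bytes()

    sspec = SyntheticStructureSpec(element="Zn", ligand_plan=(("H", 3), ("C", 9)),
                                   chain_length=12, structure_id="DET")
    c1, p1, _ = make_structure(sspec, tmp_path / "s1")
    c2, p2, _ = make_structure(sspec, tmp_path / "s2")
    assert c1.read_bytes() == c2.read_bytes()
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_changes_sequences(zinc_finger_mbp):
    mk = lambda s: make_proteome(SyntheticProteomeSpec(
        n_proteins=10, plants=(PlantSpec(mbp=zinc_finger_mbp, copies=2),), seed=s))
    a, b = mk(1), mk(2)
    assert [r.sequence for r in a.records] != [r.sequence for r in b.records]


def test_planted_positions_consistent_with_fasta(planted_bundle):
    """Ground-truth positions point at the pattern's ligand residues, and the
    survive label is recomputable from the perturbations and gap tolerances."""
    by_id = {r.protein_id: r for r in planted_bundle.records}
    templates = planted_bundle.templates
    policy = MatchPolicy()
    for entry in planted_bundle.ground_truth.entries:
        seq = by_id[entry.protein_id].sequence
        mbp = templates[entry.mbp_id].mbp
        for pos, lig in zip(entry.positions, mbp.ligands):
            assert seq[pos - 1] == lig
        want = all(
            abs(d) <= gap_tolerance(g, policy)
            for g, d in zip(mbp.gaps, entry.perturbations)
        )
        assert entry.survives == want


def test_unperturbed_plant_retained_overperturbed_rejected(cadmium_mbp):
    lib = dedupe([cadmium_mbp])
    for pert, expect in [((0, 0, 0), True), ((0, 4, 0), False)]:
        spec = SyntheticProteomeSpec(
            n_proteins=1, length_range=(120, 150),
            plants=(PlantSpec(mbp=cadmium_mbp, copies=1, per_gap_perturbation=pert),),
            seed=3,
        )
        bundle = make_proteome(spec)
        entry = bundle.ground_truth.entries[0]
        assert entry.survives is expect
        out = filter_candidates({"Cd": {entry.protein_id}}, bundle.records, lib)
        assert bool(out) is expect


def test_recovered_fraction_within_binomial_ci(zinc_finger_mbp):
    """Plant rate 0.1 over 500 proteins: the recovered fraction lies in the
    central 95% band of Binomial(500, 0.1)."""
    lib = dedupe([zinc_finger_mbp])
    spec = SyntheticProteomeSpec(
        n_proteins=500, plants=(PlantSpec(mbp=zinc_finger_mbp, rate=0.1),), seed=99,
    )
    bundle = make_proteome(spec)
    candidates = {"Zn": {r.protein_id for r in bundle.records}}
    out = filter_candidates(candidates, bundle.records, lib)
    recovered = len({pid for pid, _e, _m in out})
    lo = stats.binom.ppf(0.025, 500, 0.1)
    hi = stats.binom.ppf(0.975, 500, 0.1)
    assert lo <= recovered <= hi
    # every surviving plant is recovered
    assert {(p, e) for p, e, _ in out} >= bundle.ground_truth.surviving_pairs()


def test_co_plant_rate_within_binomial_ci(cadmium_mbp, ef_hand_mbp):
    n_plants = 400
    rate = 0.3
    spec = SyntheticProteomeSpec(
        n_proteins=500, length_range=(150, 250),
        plants=(PlantSpec(mbp=cadmium_mbp, copies=n_plants),),
        co_plant=(ef_hand_mbp, rate), seed=5,
    )
    bundle = make_proteome(spec)
    n_co = sum(1 for e in bundle.ground_truth.entries if e.co_planted)
    lo = stats.binom.ppf(0.025, n_plants, rate)
    hi = stats.binom.ppf(0.975, n_plants, rate)
    assert lo <= n_co <= hi


def test_toy_profiles_hit_their_own_instances(planted_bundle, tmp_path):
    hmms = make_toy_hmms(planted_bundle.templates, tmp_path / "p.hmm", seed=42)
    mapping = {t.mbp.mbp_id: (t.mbp.element,) for t in planted_bundle.templates.values()}
    policy = DomainScanPolicy(domain_to_metals=mapping)
    rng = np.random.default_rng(0)
    # fresh instances embedded in fresh background must be found
    from metscan.domain_scan import ProteinRecord
    from metscan.synthetic_data import default_residue_frequencies

    freqs = default_residue_frequencies()
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters])

    def bg(n):
        return "".join(rng.choice(letters, size=n, p=probs / probs.sum()))

    records = []
    for i, template in enumerate(planted_bundle.templates.values()):
        motif, _offsets = template.instance(rng)
        records.append(ProteinRecord(protein_id=f"F{i}", sequence=bg(80) + motif + bg(80)))
    hits = scan_proteome(records, hmms, policy)
    assert {h.protein_id for h in hits} == {r.protein_id for r in records}


def test_perturbation_collapsing_gap_rejected(cadmium_mbp):
    template = MotifTemplate.from_mbp(cadmium_mbp, seed=0)
    rng = np.random.default_rng(0)
    with pytest.raises(SyntheticSpecError):
        template.instance(rng, perturbations=(-2, 0, 0))  # gap 2 -> 0


def test_interiors_never_contain_ligand_residues(cadmium_mbp):
    template = MotifTemplate.from_mbp(cadmium_mbp, seed=1)
    rng = np.random.default_rng(1)
    for _ in range(20):
        motif, offsets = template.instance(rng)
        interior = [c for i, c in enumerate(motif) if i not in set(offsets)]
        assert "C" not in interior
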