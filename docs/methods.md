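# Methods

## Pipeline model

`metscan` predicts metal-binding proteins by requiring two independent
lines of evidence per (protein, metal) pair:

1. a profile-HMM hit to a metal-binding domain at full-sequence E ≤ 0.05,
   which nominates the protein as a candidate for the metals that domain is
   mapped to, and
2. a complete metal-binding pattern (MBP) of that metal placed in the
   protein sequence with conserved spacing.

The first stage gives sensitivity (domains are detectable far below the
identity needed to align individual ligand residues); the second removes
false positives by demanding the actual coordination chemistry — all ligand
residue types present, in order, at near-native spacing.

### Metal-site detection

Structures are read with gemmi (mmCIF or PDB; dialects are interchangeable
and tested to give identical sites). A residue coordinates an ion when at
least one donor atom lies within the contact cutoff of the ion.

* **Cutoff** — 3.0 Å by default. First-shell metal–donor distances cluster
  near 2.0–2.4 Å; 3.0 Å accepts long first-shell contacts while excluding
  second-shell atoms. Configurable per run.
* **Donor atoms** — any N, O or S atom except the backbone amide N; the
  backbone carbonyl O is included. This covers canonical coordination
  chemistry while keeping every pattern expressible in sequence terms.
* **Sequence index** — 1-based position in the chain's polymer residue
  sequence, not the author residue number. Author numbering carries
  insertion codes and gaps that break spacing arithmetic.
* **Multi-chain sites** — an MBP must be searchable in one sequence, so
  only the chain contributing the most ligands is kept (ties by chain
  name); dropped cross-chain ligands are logged.
* **Alternate locations** — highest-occupancy conformer, ties broken by
  altloc label order.
* **Non-standard residues** — mapped to standard parents through a fixed
  table (MSE→MET, SEC→CYS, phosphoresidues, ...); unmappable residues are
  excluded from sites.
* **min_ligands = 2** — a site must define at least one spacing to become a
  pattern; under-coordinated ions are dropped and logged.

Detection is order-independent, monotone in the cutoff, and equal to a
brute-force all-pairs distance scan (both properties under test).

### Patterns and the library

`site_to_mbp` reads ligands and gaps directly off the sorted residue
indices. Patterns are exact residue types: the filter requires all ligands
of the pattern, which implies identity matching. An optional
substitution-group mode (e.g. D↔E) exists but is off by default. Identical
ligand strings with different gap vectors are distinct patterns — spacing
is the signal. The library deduplicates exact (element, ligands, gaps)
triples only; no clustering of near-duplicates is attempted, and patterns
from homologous structures collapse only when they are literally identical.

### The spacing tolerance rule

For a pattern gap of g residues the allowed deviation is

    tol(g) = ⌊0.20 · g⌋   if ⌊0.20 · g⌋ ≥ 1, else 1.

The ±20% window is applied **per inter-ligand gap**, not to the protein
length: a per-gap reading is the only one under which a separate
"±1 for short spacing" fallback has meaning (at 20% of protein length every
gap's window would dwarf 1). The short-spacing rule engages automatically
exactly where the relative window floors to zero, i.e. gaps ≤ 4 at
defaults, avoiding a second hard-coded constant; an explicit
`short_gap_threshold` can override this. Floor (not round) keeps the window
conservative and consistent with an absolute ±1 allowance.

A whole-pattern-span mode (`MatchPolicy.mode="span"`) is provided as the
alternative reading: individual gaps float freely (observed spacing ≥ 1)
while the first-to-last ligand span must stay within the tolerance computed
on the pattern's total span. Per-gap is the default; the mode in force is
recorded in the scan manifest and the census conventions block.

### The search

`match_mbp` walks candidate ligand placements gap by gap, visiting only
positions inside each gap's tolerance window (a banded search). It returns
*every* admissible placement, ordered lexicographically by position tuple;
the census counts proteins, not matches, so match multiplicity cannot
distort statistics. The naive exhaustive enumeration over all increasing
position tuples is kept in the test suite as the oracle; the two are
verified equal on thousands of random instances, and at zero tolerance the
search reduces to exact gapped-string matching (checked against a regex
oracle).

### Domain screening

The scan engine is pyhmmer (a HMMER3 implementation); any hmmbuild-
compatible profile file works. The E-value compared against the threshold
is the full-sequence (per-target) E-value; per-domain conditional E-values
are not used. Envelope coordinates of the best domain are carried on each
hit so matching can optionally be restricted to hit envelopes
(`--window`). The domain→metal assignment is user-supplied TSV
configuration — no fixed enumeration of metal-binding domains ships with
the package. Raising the threshold never removes candidates, and every
protein in the final predictions has at least one domain hit (both under
test).

### Census conventions

* Per-metal, EMB, non-EMB and unique percentages are relative to total
  proteome size (number of FASTA records).
* EC-class rows are percentages of predicted *enzymes* per side
  (EMB / non-EMB); the EC class is the first digit of the EC string, and a
  multi-EC protein counts once per distinct class.
* Localization rows are percentages of predicted proteins per side, over
  the vocabulary {membrane, cytoplasm, ribosome, other, unannotated};
  terms outside the vocabulary fold into "other", missing annotations into
  "unannotated".
* The overlap analysis is computed over non-EMB-predicted proteins: the
  fraction carrying ≥ 1 essential-metal motif, with the per-metal
  composition of the overlapping set normalised to 100% (a protein counts
  once per essential metal whose motif it carries).
* Every percentage is emitted alongside its denominator; reports are
  written as JSON (full precision) and Markdown (one decimal).
* Multi-species summaries are unweighted arithmetic means per cell, with
  the species count recorded.

Unique + recurrent proteins partition the predicted set, percentages are
invariant under proteome reordering, and adding a prediction never lowers a
per-metal percentage — all verified against an independently coded
set-algebra oracle.

## Synthetic data

The generator emulates the pipeline's real inputs at desk scale:

* **Structures** — a schematic poly-alanine chain whose backbone sits
  beyond a decoy floor (default 5.0 Å) from a metal ion at the origin;
  planted residues carry their canonical side-chain donor atom at an exact
  coordination distance (default 2.1 Å) on well-separated sphere
  directions. By construction the expected site is known exactly. No
  physical plausibility is claimed — only distance geometry matters to the
  detector.
* **Proteomes** — background sequences i.i.d. from a composition that is
  uniform over the 20 residues with the common ligand residues (C, H, D,
  E, M) down-weighted 2×, keeping the expected number of accidental
  full-pattern matches far below one per fixture. Default protein lengths
  150–400 aa. Each planted motif is an instance of a per-pattern
  *template*: ligand columns fixed, interiors drawn once as a non-ligand
  consensus and re-sampled per instance at a 15% substitution rate, with
  10 conserved non-ligand flanking residues on each side. The flanks make
  a planted instance a *domain* rather than a bare site — without them,
  short patterns (span ≲ 12) produce profiles too weak for any instance
  to reach E ≤ 0.05, which no real domain library exhibits. Interiors and
  flanks never contain the pattern's own ligand letters, so no accidental
  earlier placement exists inside a planted span.
* **Perturbations** — `per_gap_perturbation[i]` inserts or deletes exactly
  that many interior residues in gap i. The ground-truth survive label is
  `all(|dᵢ| ≤ tol(gᵢ))` under the named policy, recomputable from the
  stored perturbations.
* **Plant counts** — exact (`copies`) or per-protein Bernoulli (`rate`,
  giving a binomial count); each plant gets its own host protein, and an
  optional co-plant adds an unperturbed essential-metal motif downstream
  of the primary plant at a stated rate (for the overlap analysis).
* **Profiles** — one per template, built with the pyhmmer Builder from an
  ungapped 20-row alignment of sampled instances.
* **Determinism** — all randomness flows from explicit seeds; the same
  seed yields byte-identical FASTA, mmCIF, PDB, TSV and JSON outputs.

What passing tests show — and do not show. The generator's sequences are
i.i.d.; real proteomes have composition bias, repeats and homologous
families, so the measured domain-scan false-positive rate (< 1% here) and
the zero accidental-match rate of the spacing filter are best-case figures.
The structural fixtures have no second-shell atoms, no waters and no
cross-chain sites beyond those explicitly planted, so detection accuracy on
real crystallographic data (altloc soup, occupancy < 1, modified residues
outside the mapping table) will be lower. What the tests do establish is
the internal correctness of every stage: search equals enumeration,
detection equals the all-pairs scan, labels round-trip exactly.

## Problem sizes

Defaults used by the test suite and the acceptance script: 1,000 random
matcher instances (sequences ≤ 200 aa, ≤ 4 ligands), 100 random structure
specs read in both dialects, a 500-protein proteome with plant rates
0.05–0.08 per pattern group and co-plant rate 0.3, and 200 random census
prediction sets. These sizes give binomial confidence bands tight enough to
detect systematic errors while the whole suite runs in seconds.

## Known limitations

* No geometry classification (tetrahedral/octahedral) and no scoring of
  matches; the filter is a hard accept/reject.
* Nucleic-acid ligands and metal clusters are out of scope; each ion is
  treated independently.
* The domain→metal map is configuration, not inference: an unmapped profile
  contributes hits but no candidates (logged).
* GO/pathway enrichment is out of scope; the census aggregates only
  user-supplied EC and localization tables.

## The demo fixture

The README example uses this simulation spec:

```yaml
seed: 7
proteome:
  n_proteins: 200
  length_range: [150, 300]
  plants:
    - {element: Zn, ligands: CCHH, gaps: [4, 14, 5], copies: 15}
    - {element: Cd, ligands: CCCC, gaps: [2, 6, 2], copies: 12}
    - {element: Cd, ligands: CCCC, gaps: [2, 6, 2], copies: 5,
       per_gap_perturbation: [0, 4, 0]}
  co_plant: {element: Ca, ligands: DDDE, gaps: [2, 2, 3], rate: 0.3}
  annotation_plan:
    ec_class: {"1": 0.1, "2": 0.2, "none": 0.7}
    localization: {membrane: 0.5, cytoplasm: 0.2, ribosome: 0.1,
                   other: 0.1, none: 0.1}
structures:
  - {element: Zn, ligand_plan: [[C, 3], [C, 6], [H, 20], [H, 24]],
     chain_length: 40}
  - {element: Ca, ligand_plan: [[D, 5], [D, 8], [E, 12]], chain_length: 30}
```

The five cadmium plants perturbed by +4 on a gap of 6 (tolerance ±1) are
the designed rejects; everything else survives.
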