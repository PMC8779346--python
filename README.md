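# metscan

Structure-based prediction of metalloproteomes — the set of proteins in a
proteome predicted to bind a given metal ion — with a census of the result.

## The problem

Most metal-binding proteins are annotated from sequence homology alone,
which misses the strongest signal available: in a 3D structure the metal's
coordinating residues and their exact sequence spacing are directly
observable. `metscan` implements a pipeline that turns that structural
signal into proteome-wide predictions:

1. **Extract** metal-binding patterns (MBPs) from metal-containing
   structures. An MBP is the ordered list of coordinating residue types
   together with their inter-residue sequence spacings — e.g. a structural
   zinc site with cysteines at positions 3 and 6 and histidines at 20 and
   24 becomes the pattern `C–x3–C–x14–H–x4–H` (ligands `CCHH`, gaps
   `3,14,4`). A residue coordinates the ion when one of its donor atoms
   (side-chain N/O/S or the backbone carbonyl O) lies within a distance
   cutoff (default 3.0 Å).
2. **Screen** a proteome with profile HMMs of metal-binding domains
   (HMMER3 format, scanned with pyhmmer) at a full-sequence E-value
   threshold (default 0.05), nominating candidate proteins per metal.
3. **Filter** candidates with the spacing-tolerant MBP search: a candidate
   survives for a metal only if some MBP of that metal places *all* of its
   ligands in the sequence with each inter-ligand gap g conserved within
   ±⌊0.20·g⌋ residues, never less than ±1 (the short-spacing rule).
4. **Census** the survivors: per-metal percentage content; the split into
   essential-metal binders (EMB: Zn, Cu, Ca, Co, Fe, Mg, Mn, Ni) and
   non-essential/toxic-metal binders (non-EMB: Cd, Hg, Pb, Ba, Cr, As);
   unique vs recurrent proteins; EC-class and localization breakdowns; and
   the overlap analysis asking how many non-EMB proteins also carry an
   essential-metal motif (the molecular basis of toxic-metal substitution
   in essential-metal sites).

Because curated structure and domain databases cannot be bundled, the
package ships a first-class synthetic-data generator: structures with
planted coordination geometry, proteomes with motif instances planted at
controlled spacing perturbations, toy profile HMMs, and a ground-truth
record stating which plants must survive the filter. Every stage is tested
against that closed loop and against independent brute-force oracles.

## Worked example

Generate a 200-protein synthetic proteome with planted zinc-finger-like
(`CCHH`, gaps 4,14,5), cadmium (`CCCC`, gaps 2,6,2) and calcium EF-hand-like
(`DDDE`, gaps 2,2,3) motifs — 5 of the 17 cadmium plants perturbed beyond
tolerance — plus two structures, then run the pipeline (the fixture YAML is
shown in `docs/methods.md`):

```sh
metscan simulate fixture.yaml --out bundle
metscan extract bundle/structures/*.cif --out library_structs.tsv
metscan scan bundle/proteome.fasta library.tsv \
    bundle/profiles.hmm bundle/domain_map.tsv \
    --annotations bundle/annotations.tsv --out scan
```

`extract` prints the patterns read off the structures:

```
mbp_id                    element  ligands  gaps    source
Zn_CCHH_3-14-4_SYN0001:A  Zn       CCHH     3,14,4  SYN0001:A
Ca_DDE_3-4_SYN0002:A      Ca       DDE      3,4     SYN0002:A
```

`scan` logs the prediction funnel and writes the census:

```
scan_proteome: 41 hit(s) at E <= 0.05 over 200 proteins x 3 profiles
pattern filter: 36/41 candidate (protein, metal) pairs survive
```

From `scan/census.md` (seed 7): EMB proteins 21 (10.5%), non-EMB proteins
12 (6.0%), total predicted 30 (15.0%), 6 recurrent proteins. Per metal:
Zn 15 (7.5%), Cd 12 (6.0%), Ca 9 (4.5%). The five over-perturbed cadmium
plants are exactly the candidates rejected by the spacing filter (41 − 36),
and 3 of the 12 non-EMB proteins (25.0%) carry an essential-metal (Ca)
motif — the planted co-occurrence rate was 0.3.

All percentages are emitted with their denominators (proteome size for
content percentages, predicted-set size for the annotation tables) so the
arithmetic is auditable; `census.json` holds the same numbers
machine-readably.

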