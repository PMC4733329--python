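# Methods

## The procedure

`macrodissect` dissects one deposited macromolecular structure into typed
subunits and decides, for every unordered subunit pair, whether the two
form a binary interaction. The pipeline has four annotation stages followed
by interface detection:

1. **Nucleic subunits.** Every chain is classified from its component
   composition (protein / DNA / RNA / hybrid / other). Each RNA chain is one
   subunit. A DNA chain becomes a subunit when at least one of its
   nucleotides is base-paired with a nucleotide of a *different* DNA chain,
   judged from `_ndb_struct_na_base_pair` records when the source is mmCIF.
   Chains containing both DNA and RNA bases (hybrids) are reported and
   excluded from interaction detection.
2. **Domain subunits.** Domain regions are read from a tab-separated
   classification file (the `dir.cla` dialect: domain id, entry id,
   `chain:range` region, family string, numeric id). Curated assignments
   and precomputed HMM-based family predictions are accepted in the same
   dialect; a trailing `superfamily` column marks predictions. Region
   boundaries are author residue numbers and are resolved onto the
   deposited chain; a domain whose boundary residue is missing from the
   structure is rejected and reported rather than guessed.
3. **Unstructured subunits.** On a domain-bearing chain, every maximal
   unannotated interval becomes exactly one span: a *linker* when domains
   flank both sides, an *N-terminal* region when the only domains lie
   C-wards, a *C-terminal* region otherwise. Domains plus unstructured
   spans tile the chain exactly.
4. **Peptides and undefined chains.** A protein chain with no located
   domain becomes a single whole-chain subunit: *peptide* if shorter than
   `peptide_max_len` resolved residues (default 20, exclusive bound,
   following the peptide-length convention of domain-sequence compendia),
   *undefined chain* otherwise.

Subunits are labelled per chain as chain letter + 1-based ordinal in
sequence order (`A1`, `A2`, …); labels are stable across exports.

## Contact definitions and filters

* **Residue–residue** (both subunits protein): the pair qualifies when the
  smallest Euclidean distance between heavy atoms, one from each residue,
  is ≤ `pp_distance_cutoff` (default 6.0 Å). A protein–protein interaction
  requires ≥ `min_pp_contact_pairs` (default 10) surviving pairs.
* **Residue–nucleotide**: qualifies when an oxygen or nitrogen atom of the
  nucleic *base* lies within `nucleic_distance_cutoff` (default 3.5 Å) of
  any heavy atom of the residue. Base atoms are identified by name: no
  sugar prime mark and not part of the phosphate group
  (`P`, `OP1`–`OP3`); `nucleic_atom_scope="nucleotide"` widens the set to
  all O/N atoms of the nucleotide.
* **Nucleotide–nucleotide**: qualifies when some N–N or O–N atom pair is
  within the same 3.5 Å cutoff; O–O pairs never qualify. The O/N atoms
  considered are the base-moiety set above (configurable as for the
  protein–nucleic rule).
* Nucleic-mediated interactions need ≥ `min_nucleic_contact_pairs`
  (default 1) qualifying pairs. The published pair-count threshold is
  stated only for protein–protein interfaces; a single 3.5 Å
  hydrogen-bond-scale contact is individually meaningful, hence the
  default of 1, kept configurable.
* **Adjacency exclusion**: when two subunits are sequence-adjacent spans
  of one chain (their index intervals abut), every contact pair whose
  residues are ≤ `adjacency_min_separation` (default 10) sequence positions
  apart is discarded before the pair count is taken — such pairs are
  covalent-proximity artifacts, and counting them first would let false
  positives carry an interface over threshold. The exclusion applies to
  all adjacent intra-chain kind combinations (domain–linker,
  domain–terminus, linker–terminus).

## Numerical and representational choices

* Distances are compared with a 1 × 10⁻⁹ Å tolerance at every cutoff so
  that fixtures placed exactly at a boundary behave identically across
  platforms; distances exactly at a cutoff qualify.
* The contact engine flattens each subunit's eligible atoms and queries a
  k-d tree (`scipy.spatial.cKDTree`); per unit pair it keeps the minimal
  qualifying distance and the atom names achieving it, breaking exact
  distance ties by atom-name order. The engine's output is exactly the
  brute-force all-pairs result; the test suite and the acceptance script
  verify this pair-for-pair on randomized structures.
* Interval logic runs on gap-free 0-based sequence indices; author
  numbering (with insertion codes) is kept only for boundary resolution
  and output.
* Alternate locations: per atom name the highest-occupancy location wins,
  ties going to the alphabetically first altloc. Multi-model files use
  model 1 only. mmCIF chains are identified by auth asym IDs so PDB and
  mmCIF parses of one entry agree.
* Modified residues tabulated as amino acids or nucleotides (MSE, PSU, …)
  occupy polymer positions and are kept; waters and free ligands never
  enter a chain model. Unknown two-letter components starting with `D`
  fall back to DNA typing, so inputs remain parseable without a chemical
  component dictionary or network access.
* Overlapping domain assignments are resolved deterministically: curated
  sources beat predictions, longer domains beat shorter, remaining ties go
  to the smaller start index; losers are reported. Discontinuous domains
  keep one span with several segments — one network node, contacts pooled
  across segments.
* When a plain PDB input provides no base-pair records, DNA-chain pairing
  falls back to a geometric Watson–Crick test: two DNA chains are paired
  when some A·T / G·C / A·U-compatible nucleotide pair has its purine N1
  within 3.5 Å of the pyrimidine N3.
* DNA chains without an inter-chain partner are not silently dropped: they
  are flagged `unpaired` and excluded from the default network, with an
  `--include-unpaired-dna` switch, so single-stranded-DNA binders can keep
  their DNA partner on request.
* Structures are processed as deposited (asymmetric unit); no symmetry
  expansion. Symmetric interactions between crystallographic chain copies
  are all reported.

## Interaction-type codes

Eight kinds give 36 unordered types. Codes use the symbols D, C, N, L, U,
P, DNA, RNA; protein–protein codes follow that fixed order (`D-N`, `L-P`),
mixed codes put the nucleic symbol first (`DNA-D`, `RNA-L`), and
`DNA` precedes `RNA`. This matches the established interaction-search
syntax for nucleic-mediated types.

## What the synthetic generators emulate

The fixture module builds structures whose distances, composition and
sequence positions are planned, because those are the only properties the
pipeline consumes:

* protein chains on extended (3.8 Å Cα spacing) or helical
  (1.5 Å rise / 100° twist) traces, ≥ 4 heavy atoms per residue;
* DNA duplexes whose pairing nitrogens sit at 2.9 Å (hydrogen-bond
  distance) with 3.4 Å base-pair rise, full base/sugar/phosphate atom
  naming, and mmCIF output carrying one base-pair row per pair;
* docked chain pairs whose residue-level contact map is planned exactly:
  residues are strung along x at 20 Å spacing with a probe atom realizing
  each unit pair's minimal distance, so only planned same-column pairs can
  ever be within cutoff range and the brute-force contact map equals the
  plan by construction;
* random two-chain atom clouds for engine-versus-brute-force equivalence
  checks.

All generators are deterministic under a fixed seed. They are *not*
physically relaxed conformations: no rotamers, no realistic backbone
torsions, no crystal packing. Passing tests therefore demonstrate that the
rules are implemented exactly as defined, not that the thresholds are
biophysically optimal for any particular real complex; on real deposits
the accuracy of domain boundaries and base-pair records inherits from the
annotation sources.

## Problem sizes

The randomized equivalence checks use two-chain fixtures of 18–30 units
per chain (a few hundred atoms), ≥ 100 fixtures in the acceptance script,
cycled over the three contact definitions; partition recovery uses 50
random layouts on chains of 30–120 residues. These sizes exercise every
code path (all three definitions, both span shapes, boundary distances)
while keeping a full run in seconds.

## Known limitations

* The HMM domain scan itself is out of scope; predictions are consumed as
  a prepared input file in the same dialect as curated assignments.
* No biological-assembly expansion, no ligand-mediated interfaces, no
  hydrogen-bond geometry (angles) or surface-based interface definitions.
* Base-pair-record quality gates the DNA-subunit rule on mmCIF inputs;
  the geometric fallback recognizes only Watson–Crick-compatible pairing.
* The whole-structure reading keeps the first model of multi-model files;
  conformational heterogeneity across models is ignored.
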