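# Methods

## Solvent-accessible surface area

SASA is computed by the Shrake–Rupley dot method. Each atom sphere is
expanded by the probe radius and covered with a deterministic golden-section
spiral of `n_points` quasi-uniform points; a point is exposed when it lies
outside every neighbour's expanded sphere, and the atom's SASA is
4π(r + r_p)² times the exposed fraction. There is no random number generator
anywhere in the surface calculation, so results are exactly reproducible for
fixed parameters. Neighbour candidates come from a KD-tree query with cutoff
(r_i + r_p) + max_j(r_j + r_p), which cannot miss an occluder; correctness
was preferred over speed throughout.

Parameters, with defaults and rationale:

- `probe_radius` = 1.4 Å — the standard water probe. Configurable and
  recorded in run provenance.
- `n_points` = 9,600 — the mesh density used for all reported analyses.
  Accuracy at this density: exact on an isolated sphere (every lattice point
  is exposed), ≤ 0.1% against the two-sphere spherical-cap closed form, and
  within 2% of a Monte-Carlo surface-integration oracle on random ≤ 20-atom
  systems (the residual is dominated by the oracle's own sampling noise; the
  comparison is restricted to atoms whose Monte-Carlo estimate has a relative
  standard error below 0.5%, since the relative error of a nearly buried
  atom's area is noise in the reference, not signal in the method).
- `threshold_pct` = 25 — a residue is a surface residue when its relative
  SASA is *strictly* greater than this percentage.
- Radii: a named Bondi-style van der Waals table (C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20, P 1.80, Se 1.90 Å), selected by name and recorded in
  provenance; unknown elements fall back to 1.80 Å with a logged warning.
  Hydrogens are excluded by default (the crystal structures this pipeline
  targets do not resolve them).

Because the probe radius, radii set and dot-placement scheme of the original
surface-count analyses are not fully pinned by their description, absolute
surface counts on real structures may shift by a few residues under
different choices; every output therefore embeds the full parameter set so
discrepancies are attributable.

## Relative SASA and the reference peptide

Maximal per-residue SASA is computed with the *same engine* on a 41-residue
reference peptide in which each of the 20 standard amino acids, taken in
alphabetical one-letter order, is flanked by glycines (G-X₁-G-…-X₂₀-G). The
chain is built in an extended β-strand state (φ = −135°, ψ = +135°,
ω = 180°) from ideal backbone internal coordinates (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; standard bond angles) by natural-extension placement. Side
chains are grafted from the ideal conformers of the PDB chemical component
dictionary, rigid-body fitted onto each backbone N/CA/C triad. The conformer
coordinates are frozen into the package (`_residue_templates.py`, with a
regeneration script) because parsing the full component dictionary at run
time costs over a minute per process. The guest-residue order is irrelevant
in a true extended strand but is pinned for determinism; using the
dictionary's ideal side-chain conformer rather than an explicit
most-extended rotamer is a deliberate choice — it is deterministic,
clash-free in the Gly-flanked strand, and requires no rotamer library.

Relative SASA is 100·SASA/maxSASA. Values above 100% occur for unusually
exposed residues (e.g. chain termini, fully isolated residues) and are
reported as-is, never clamped; the surface rule uses a strict `>`.
For multimeric structures (the OTC trimer), SASA is computed on the full
deposited assembly after heteroatom/water removal and surface counts are
reported per chain; when variants are mapped onto a homotrimer, a residue
counts as surface if it is exposed in *any* subunit (the most exposed copy
is used).

## Structures and numbering

PDB parsing is delegated to gemmi behind a small atom/residue/chain model;
only the first MODEL of a multi-model file is read. Fixed-column coordinate
fields are validated first so a malformed record fails with its line number.
Heteroatoms and waters are removed before any surface calculation.
Alternate locations are resolved to the highest-occupancy conformer (ties:
alphabetically first alt-loc). Author residue numbering is taken at face
value; mapping to pre-protein (HGVS) coordinates is an explicit per-chain
`numbering_offset` input (pre-protein position = author number + offset),
because deposited mature-enzyme structures (e.g. OTC without its targeting
peptide) need not share the pre-protein frame and the correct offset is a
statement about the deposition, not something the pipeline can infer.

## Variant ledger

Variant tokens are HGVS protein substitutions in one- or three-letter form;
nonsense, frameshift and indel tokens are rejected as unsupported. Predicted
stability changes are consumed as an input table (kcal/mol, positive =
destabilising, the Rosetta sign convention): ΔΔG < 0 is classed more stable,
0–2 (both bounds inclusive) similar, > 2 destabilising, absent unknown. The
candidate filter requires surface exposure in at least one structural state,
a similar/more-stable class (unknown passes only with an explicit
`allow_unknown_ddg` flag), no experimental annotation explaining the
phenotype, and — when a functional-site residue list is supplied — a minimum
heavy-atom distance above a configurable cutoff (default 8 Å; "distant from
active sites" is stated only qualitatively in the source analyses, so the
cutoff is an explicit, recorded operationalisation). Variants whose
reference residue disagrees with the structure are kept in the ledger and
listed in a discordance report; variants unresolved in every state are
categorised unmapped and excluded from surface counts.

## Conservation

The conservation score of query position *i* is the percentage of homologs
whose residue at the aligned column equals the query residue. The query
itself is excluded from the denominator (the homolog counts 233 for CPS1 and
270 for OTC are read as excluding the human query; an `include_query` switch
exists for sensitivity checks). Gaps and ambiguity codes (X, B, Z, …) never
match. Reported scores are integers rounded half-up; full precision is kept
internally. Per-taxon residue sets list the distinct residues each group
shows at the column, ordered by within-group frequency; ambiguity codes
collapse to 'X' and are shown only when they reach 5% of a group. A
secondary similarity-aware score (counting conservative substitutions) is
not implemented; group sets make conservative replacement patterns visible
instead.

## Variable segments

Global pairwise alignment uses BLOSUM62 with affine gap penalties, pinned to
open = −11 and extend = −1 under the convention that a gap of length L costs
open + (L−1)·extend. ("Gap existence 11, extension 1" bookkeeping differs
between tools; one convention had to be pinned, and the exhaustive-
enumeration oracle in the tests uses the same one.) Alignment is performed
by Biopython's PairwiseAligner; tie-breaking among co-optimal tracebacks is
the aligner's canonical first alignment, which is deterministic. The VS of a
pre-protein runs from the annotated MPP cleavage site to the residue
preceding the first position aligned to the first residue of the
conserved-domain reference (a sequence that has neither targeting signal nor
VS). MPP cleavage sites are annotation inputs; cleavage-site prediction is
out of scope. Pairwise identity is the complement of the p-distance under
pairwise deletion: matches over columns where neither sequence is gapped.
Peptide masses are average-isotopic, via Biopython's mass tables, reported
in kDa to three decimals.

## Synthetic data

The generators produce fixtures whose ground truth is established at
generation time, not assumed:

- Sphere systems carry analytic truth (single sphere; two-sphere
  spherical-cap closed form) or Monte-Carlo truth (uniform random directions
  on each expanded sphere, seed-pinned, with reported binomial standard
  errors; < 0.5% relative SE at 10⁶ samples on ≤ 20-atom systems).
- Collapsed toy structures place ideal residues on a jittered compact grid
  and are re-jittered until every residue's Monte-Carlo relative SASA clears
  the 25% threshold by a 3-point margin, so surface/buried labels are
  verified truths. Extended peptides are fully exposed by construction.
- Simulated alignments fix the query and let each homolog match column *j*
  with probability c_j, else draw uniformly from the other 19 residues —
  the estimator's sampling distribution is then exactly binomial, which the
  recovery tests exploit.
- Variant tables draw positions from labelled surface/buried pools and ΔΔG
  values from a declared distribution, and emit the expected candidate set
  by direct application of the filter rule.
- NAGS-like records are MTS + VS + shared conserved-domain reference, with
  VS lengths and proline fractions drawn uniformly from the group ranges of
  the study populations (mammals: length 37–64, proline 17.4–32.3%;
  fish/amphibians/reptiles: 31–40, 2.3–11.1%; 90 and 61 records). The
  reference starts with tryptophan and W is excluded from the synthetic
  MTS/VS alphabet, making the conserved-domain start an unambiguous
  alignment anchor so truth spans are exactly recoverable; real sequences
  enjoy no such guarantee, and boundaries there can shift by a few residues
  with alignment parameters.

What the synthetic data does *not* emulate: real protein packing (collapsed
clusters are not bonded chains), phylogenetic correlation between homologs
(alignment columns are independent), within-group sequence similarity of
variable segments (records are mutually random, so pairwise identity ranges
of real, homologous VS sets are not reproduced), or the coordinates of the
actual CPS1/OTC structures. Passing the synthetic suites therefore
demonstrates correctness of the algorithms and filters, not agreement with
any particular deposited structure; the structure-dependent comparisons run
only when the deposited files are supplied under `data/reference/`.

## Numerical and degenerate-input choices

- Dot lattice: golden-section spiral with z_i = 1 − 2(i+0.5)/n; exact on
  isolated spheres, centroid norm < 10⁻⁶ at n = 9,600.
- Accessibility tables keyed by (chain, residue number, insertion code);
  duplicate pre-protein positions across chains resolve to the most exposed
  copy.
- Empty structures yield empty tables and zero counts; an empty VS (post-MPP
  sequence starting at the conserved domain) is reported with end < start
  and excluded from group statistics with a warning; proline content of an
  empty segment is an error, not 0.
- Conservation positions are 1-based on the ungapped query; requests outside
  it raise.
- Profile scores round half-up (67, not 66, for 2/3).
- The run-configuration hash covers parameters and input file *contents*,
  not paths or output locations, so equal inputs give byte-identical
  outputs regardless of where they live.

## Problem sizes in the checks

The shipped tests and the acceptance script run on generated inputs sized to
the study they mirror where that is cheap (233-homolog alignments, 90 + 61
sequence records, 100 variant fixtures) and on small systems where only
algorithmic accuracy is at stake (≤ 20-atom oracle comparisons, 5–27-residue
peptides). Monte-Carlo oracles use 10⁶ samples per atom in accuracy
comparisons and 2 × 10⁴ during fixture label verification.

## Known limitations

- No analytic (Lee–Richards / power-diagram) SASA mode.
- No ΔΔG computation, loop/terminus modelling, cleavage-site or
  polyproline-II prediction, alignment construction, or figure rendering:
  these are consumed as inputs or out of scope.
- The β-strand reference peptide pins one of several defensible maximal-SASA
  conventions; relative SASA values are comparable only within a convention.
- Surface counts on real structures depend on the pinned probe/radii choices
  (see above); the provenance block exists precisely to make such
  discrepancies attributable.
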