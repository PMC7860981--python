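# ureasurf

Surface-residue analysis of the mitochondrial urea-cycle enzymes.

The three mitochondrial urea-cycle enzymes — N-acetylglutamate synthase
(NAGS), carbamylphosphate synthetase 1 (CPS1) and ornithine transcarbamylase
(OTC) — appear to cluster at the inner mitochondrial membrane rather than
diffuse freely in the matrix. Disease-causing missense variants that strike
*solvent-exposed* residues, yet neither destabilise the protein nor touch
catalytic sites, are prime candidates for disrupting those protein–protein
and protein–membrane contacts. `ureasurf` implements the computational side
of that argument as a reusable pipeline for structural bioinformaticians and
clinical variant analysts:

1. **Solvent accessibility.** Per-atom SASA by the Shrake–Rupley dot method:
   each atom's sphere is expanded by the probe radius *r*<sub>p</sub> and
   covered with a deterministic quasi-uniform lattice of *n* points; the
   exposed area is 4π(*r* + *r*<sub>p</sub>)² times the unoccluded point
   fraction. Relative SASA normalises each residue by its maximal SASA,

   relSASA = 100 · SASA / maxSASA(aa),

   where maxSASA comes from a Gly-flanked 41-mer reference peptide
   (G-X₁-G-…-X₂₀-G) built as an extended β-strand; residues with
   relSASA > 25% are classified as surface.
2. **Variant ledger.** HGVS protein variants (e.g. `p.R40H`) are located on
   apo and liganded structures, classified by predicted stability change
   (ΔΔG in kcal/mol: < 0 more stable, 0–2 similar, > 2 destabilising) and
   filtered to candidate interaction residues: surface in ≥ 1 state, not
   destabilising, not experimentally explained, and optionally distant
   (> 8 Å) from annotated functional sites.
3. **Conservation.** Per-position conservation from a multiple sequence
   alignment as the percentage of homologs carrying the query's residue,
   with per-taxon observed-residue summaries.
4. **Variable segment (VS).** For NAGS pre-proteins, the proline-rich
   segment between the MPP cleavage site and the start of homology with a
   conserved-domain reference is delimited by global pairwise alignment
   (BLOSUM62, affine gaps), and group statistics (length, proline %,
   pairwise identity) contrast mammalian with non-mammalian sequences.

A synthetic-data module generates ground-truthed fixtures for every stage:
sphere systems with closed-form or Monte-Carlo reference areas, labelled toy
structures, alignments with prescribed conservation, variant tables with
known candidate sets, and VS-bearing sequence sets.

## Worked example

```python
from ureasurf.sasa import SasaParams, max_sasa_table, accessibility_table
from ureasurf.peptide import build_peptide

params = SasaParams(probe_radius=1.4, n_points=9600, threshold_pct=25.0)
table = max_sasa_table(params)
for aa in "GAKRW":
    print(f"max SASA {aa}: {table[aa]:.1f} A^2")

for acc in accessibility_table(build_peptide("ADKLF"), params):
    print(f"{acc.chain_id} {acc.seq_num} {acc.aa}  sasa={acc.sasa:.2f}  "
          f"rel={acc.rel_sasa:.1f}%  surface={acc.is_surface}")
```

prints

```
max SASA G: 86.6 A^2
max SASA A: 106.6 A^2
max SASA K: 188.7 A^2
max SASA R: 233.3 A^2
max SASA W: 202.5 A^2
A 1 A  sasa=140.26  rel=131.6%  surface=True
A 2 D  sasa=146.41  rel=96.0%  surface=True
A 3 K  sasa=160.98  rel=85.3%  surface=True
A 4 L  sasa=161.22  rel=97.4%  surface=True
A 5 F  sasa=231.26  rel=125.5%  surface=True
```

The maximal-SASA values grow with side-chain size (Gly < Ala < Trp); every
residue of a fully extended pentapeptide is on the surface, and the chain
termini exceed 100% relative SASA because an isolated terminus is more
exposed than the same residue inside the reference strand (values above 100%
are reported, never clamped).

The same analyses are available from the shell:

```sh
ureasurf surface --structure-apo apo.pdb --structure-liganded holo.pdb \
    --variants variants.tsv --ddg ddg.tsv --msa homologs.fasta \
    --query-id HUMAN --probe 1.4 --points 9600 --threshold 25 --out out/
ureasurf vs --fasta nags.fasta --annot annotations.tsv \
    --reference conserved.fasta --out out_vs/
ureasurf fixtures --spec spec.json --seed 1 --out fixtures/
```

Every tabular output embeds a hash of the run configuration and input
contents, so identical inputs give byte-identical outputs and every surface
count is attributable to its pinned parameters (radii set, probe, mesh
density, threshold).

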