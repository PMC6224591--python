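# immunopep

Comparative immunopeptidome analysis for micropolymorphic HLA class I
allotypes.

Closely related HLA-B allotypes — differing by a handful of residues in the
peptide-binding cleft, such as the HLA-B*57:01 / B*57:03 / B*58:01 trio —
can present overlapping yet measurably different peptide repertoires. This
package implements the full comparison pipeline for mass-spectrometry-derived
HLA ligand datasets, for immunologists and proteomics analysts who want each
stage reproducible and testable:

1. **Filtering** (`immunopep.io`): identification tables are filtered at a
   confidence cutoff (default 95, the score band matching a ~5% local FDR),
   cleaned of endogenous-HLA ligands, generic contaminants and HLA-protein
   fragments, and deduplicated to a non-redundant repertoire with full
   provenance counts.
2. **Motifs and enrichment** (`immunopep.motif`): length distributions,
   position-frequency matrices, ≥10%-prevalence motif summaries, and
   enrichment of each (position, residue) cell over the human Swiss-Prot
   background using a binomial z-score
   `z = (p_obs − p_ref) / sqrt(p_ref (1 − p_ref) / n)`; significant cells are
   reported as a fold change `FC = p_obs / p_ref` (enriched) or converted
   fold change `FC_con = −1/FC` (depleted), with −100 marking absence.
   C-terminal-anchored indexing (PΩ, PΩ-2) makes anchors comparable across
   lengths.
3. **Covariation** (`immunopep.covariation`): inter-position statistical
   coupling — the count-weighted RMS log-ratio shift of site j's residue
   frequencies when site i is conditioned on a residue — with per-position
   conservation on the diagonal and a column-shuffle permutation null.
4. **Physicochemical PCA** (`immunopep.physchem`): peptides encoded as
   24 features per position (molecular weight, hydropathy, surface area,
   isoelectric point + 20 identity indicators), standardised, decomposed by
   PCA, and clustered by k-means on PC1/PC2 with silhouette-based choice of k.
5. **Overlap** (`immunopep.overlap`): repertoire overlap under a
   confidence-rescue rule — identifications at confidence > 20 count if the
   same peptide reaches ≥ 95 in a compared dataset.
6. **MRM quantification** (`immunopep.mrm`): targeted-MS detections validated
   by transition co-elution, MS/MS triggers, a ±1.5 min retention-time
   window and a spectral-library dot product > 0.7 (square-root intensities,
   fragment union); abundances normalised to co-purified β2m and expressed
   as proportion of each peptide's maximum.
7. **Thermal melts** (`immunopep.melt`): Tm (temperature of 50% unfolding)
   from dye-based melt curves by Boltzmann-sigmoid fitting with post-peak
   truncation; replicate mean/sd summaries and ΔTm classification
   (stabilising / destabilising at |ΔTm| > 1 °C).
8. **Synthetic data** (`immunopep.simulate`): seeded generators for all three
   input streams, so every stage is testable without any downloads.

## Worked example

The numbered drivers under `analysis/` run the whole comparison on the
bundled three-allotype synthetic cohort (run them in order; outputs land in
`results/`):

```sh
cd analysis
python 01_simulate_cohort.py
python 03_motifs_and_enrichment.py
```

prints, for the anchor analysis:

```
W-RposE: n9=1022, modal length 9, P2 motif ['S', 'T', 'A', 'V'], PΩ motif ['W', 'F']; PΩ-2 Arg: enriched (value 2.12, z 8.7)
F-RnegP: n9=982, modal length 9, P2 motif ['S', 'T', 'A', 'V'], PΩ motif ['F', 'W']; PΩ-2 Arg: depleted (value -27.69, z -7.4)
W-EposR: n9=994, modal length 9, P2 motif ['S', 'T', 'A', 'V'], PΩ motif ['W', 'F']; PΩ-2 Arg: absent (value -100.00, z -7.7)
```

All three synthetic allotypes share the P2 Ser/Thr/Ala/Val bias and an
aromatic C terminus, but only the first was generated with a PΩ-2 arginine
preference — and only there does the enrichment profile call Arg enriched
(fold change 2.12 over the proteome background); the other two show strong
depletion or outright absence. `04_covariation.py` then recovers the
injected P2–PΩ pairing against its permutation null, `05_physchem_pca.py`
shows the cluster-bias inversion between the Trp-major and Phe-major
datasets (cluster occupancies 69/31 vs 34/66) with PΩ features driving PC1,
and `08_thermal_stability.py` reproduces the ΔTm substitution grid for the
published HLA-B57-family melting temperatures, e.g. PΩ Tyr→Trp on LTVQVARVY:
+2.8 °C (B*57:01) and +8.6 °C (B*57:03), both classified stabilising.

A `click` CLI wraps the same stages (`immunopep simulate|filter|motif|
enrich|covary|pca|overlap|mrm|melt|report`), each a thin call into
`immunopep.pipeline.run_pipeline`.

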