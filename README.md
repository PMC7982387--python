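# rhizogeo

Phylogeography and symbiotic effectiveness of chickpea-nodulating
*Mesorhizobium*, as a tested, reusable pipeline.

Chickpea (*Cicer arietinum*) is nodulated almost exclusively by
*Mesorhizobium*. Surveys of cultured strains typically type isolates by
multilocus sequence analysis (MLSA) of housekeeping genes, group them into
genospecies against published reference strains, and then ask two questions:
is the collection spatially structured (isolation by distance, elevation
effects), and does taxonomy or geography predict how much nitrogen-fixation
benefit a strain confers in the greenhouse?  `rhizogeo` implements that whole
analysis chain for anyone working with per-locus alignments, strain
coordinates and randomized-complete-block inoculation trials - plus a
synthetic-data generator that emulates such a survey end to end, so every
stage is exercised and validated without access to the original isolates.

## What it computes

* **Alignment statistics** - per-locus and concatenated site classes:
  conserved, variable, parsimony-informative (≥2 states each in ≥2
  sequences), singletons, and columns excluded for gaps/ambiguities.
* **Distance hierarchy** - nucleotide level: p-distance
  (pairwise-deletion proportion of differing sites) and the Tamura–Nei (1993)
  model distance

  d = −(2g_A g_G / g_R)·ln w₁ − (2g_T g_C / g_Y)·ln w₂
      − 2(g_R g_Y − g_A g_G g_Y/g_R − g_T g_C g_R/g_Y)·ln w₃,

  with w₁ = 1 − g_R P₁/(2g_A g_G) − Q/(2g_R), w₂ analogous for pyrimidines,
  w₃ = 1 − Q/(2 g_R g_Y), from the two transition proportions P₁, P₂, the
  transversion proportion Q and pooled base frequencies; haplotype level:
  allele-sharing distance (fraction of loci with different alleles); species
  level: same/different genospecies; plus great-circle geographic, elevation
  and trait distances.
* **Genospecies assignment** - nearest reference by average nucleotide
  identity (ANI = 1 − p-distance) with a 0.95 floor, and chi-squared
  composition tests between samples.
* **Diversity** - Shannon H = −Σ pᵢ ln pᵢ and Gini–Simpson D = 1 − Σ pᵢ²
  over genospecies, mean pairwise distances per source, and a bootstrap
  comparison against a reference population (B resamples of the observed
  sample size, lower-tail p with the +1 permutation correction).
* **Spatial inference** - Mantel and partial Mantel permutation tests,
  principal coordinates analysis (Gower double-centering), regression of
  genetic coordinates on geographic coordinates and altitude with sequential
  F-tests, and a sliding-window distance-decay resampler (40-km windows,
  10-km steps, one random pair per window against a distance-agnostic
  baseline).
* **Symbiosis** - PC1 of the scaled greenhouse traits as the symbiotic
  response score, exact variance components of the balanced RCBD, Monte-Carlo
  Dunnett comparisons of shoot dry weight against the uninoculated control,
  and genospecies contrasts (Welch t + one-sided Wilcoxon).

## Worked example

```python
import rhizogeo as rg

ds = rg.simulate_dataset(seed=1)          # 39 strains, 4 genospecies, 3 loci
print(rg.site_stats_table(ds.mla).to_string(index=False))

assignment = rg.assign_genospecies(ds.mla, ds.references, ds.reference_labels)
print("composition:", dict(assignment.counts()))
print("Shannon H = %.3f   Simpson D = %.3f"
      % (rg.shannon(assignment.counts()), rg.simpson(assignment.counts())))

order = list(ds.mla.strain_ids)
nt  = rg.p_distance_matrix(ds.mla.concatenated)
hap = rg.allele_sharing_distance(rg.call_haplotypes(ds.mla))
geo = rg.geographic_distance_matrix(ds.metadata).reorder(order)
print(rg.mantel(hap, geo, n_perm=9999, seed=1))

profile = rg.sliding_window_decay(nt, hap, geo, seed=1)
print("distance-decay Spearman rho = %.3f" % rg.decay_spearman(profile))
```

prints

```
        locus  n_sequences  length  conserved  variable  parsimony_informative  singletons  excluded
          16S           39    1045        841       204                    165          39         0
         atpD           39     390        303        87                     75          12         0
         recA           39     307        237        70                     59          11         0
16S+atpD+recA           39    1742       1381       361                    299          62         0
composition: {'gsI': 26, 'gsII': 8, 'gsIII': 2, 'gsIV': 3}
Shannon H = 0.945   Simpson D = 0.505
<Mantel: r=0.3909, p=0.0001 (9999 perms, two-sided)>
distance-decay Spearman rho = 0.416
```

The three housekeeping loci concatenate to 1742 bp; the four genospecies have
the uneven 26/8/2/3 composition, giving the low diversity indices typical of
such collections; the haplotype-level Mantel test detects the isolation by
distance built into the generator, and the sliding-window profile shows the
corresponding positive distance decay.

A command-line interface wraps the same stages
(`rhizogeo all --seed 1 --outdir run/` runs simulation plus every analysis
and writes TSV artifacts; see `rhizogeo --help`).

## Layout

```
src/rhizogeo/
  seqio.py       alignments, concatenation, site statistics
  gendist.py     distance matrices at every hierarchy level
  genospecies.py reference-panel assignment, composition tests
  diversity.py   Shannon/Simpson, mean pairwise, bootstrap comparison
  spatial.py     Mantel, partial Mantel, PCoA (+regression), sliding window
  symbiosis.py   response PCA, variance components, Dunnett, contrasts
  synthdata.py   synthetic survey generator with truth records
  cli.py         click-based pipeline entry point
docs/methods.md  model assumptions, parameter choices, limitations
```
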