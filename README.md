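# ribocodon

Codon-resolution analysis of ribosome-profiling (Ribo-seq) libraries, built
for studying translation elongation kinetics — which codons the ribosome
dwells on, in which of its tRNA-binding sites, and whether a perturbation
(for example the loss of a tRNA anticodon modification such as mcm⁵s²U)
slows decoding of specific codons enough to matter for protein output.

It is aimed at researchers who want a tested, reproducible implementation of
the classic poly-A-tailed footprint analysis stack: per-read-length P-site
offset calibration, metacodon/bulk occupancy, single-codon occupancy with
Kolmogorov–Smirnov comparison between strains, ribosome-queuing metaplots,
and ORF-windowed expression with gene-set enrichment — plus a synthetic
footprint simulator that provides ground truth for every stage.

## The model and statistics

**Coordinates.** Everything is ORF-relative: position 0 is the first
nucleotide of the start codon. Footprints of length *L* (25–31 nt) carry a
length-specific P-site offset (5′ end → first nt of the P-site codon).
Offsets are calibrated from the start-codon metagene — the modal upstream
5′-end peak marks initiating ribosomes with the start codon in their P site
— and expressed as frame shifts into the 28-mer frame
(25:0, 26:0, 27:0, 28:0, 29:−1, 30:−1, 31:−2; the 28-mer offset is 12 nt).
Reads end in an in-vitro poly-A tail; a read whose inferred tail boundary
coincides with a genomic A has ambiguous length and is excluded from
length-specific analyses.

**Metacodon / bulk occupancy.** For codon *c* with in-frame instances at
first-nt positions *x*, the metacodon vector is

    M_c[i] = Σ_instances  n(x − 21 + i),   i = 0 … 20,

where *n* is the pooled frame-shifted 5′-end count track and 21 nt is the
28-mer P-site offset (12 nt) plus the distance from the P site to the first
window position. Peaks map to ribosomal sites as
{0:−2, 3:−1, 6:A, 9:P, 12:E, 15:+1, 18:+2}. The vector is normalized to the
mean peak height of the outer sites (±1, ±2), where codon identity should
not affect dwell; the normalized peak heights are the **bulk codon
occupancies**, a proxy for relative dwell time per site.

**Single-codon occupancy.** For codon instance *i* of gene *j* in site *k*,

    O(i, j, k) = (in-frame reads placing i in site k) / (mean in-frame read density of gene j),

counting only in-frame reads, excluding the first 4 codons and codons with
no in-frame reads from both numerator records and the denominator's codon
count. Genome-wide per-codon distributions of *O* are compared between
strains with the two-sample K-S test (exact for small samples).

**Queuing.** Instances of AAA/CAA with ≥2-fold occupancy increase and ≥32
reads seed a metaplot of ORF-mean-normalized density, origin at the
codon-in-A-site position; a stacked trailing ribosome appears as a secondary
peak one footprint width (~28 nt) upstream.

**Expression.** RPKM = reads per kilobase of ORF window per million
ORF-assigned reads, over the unsplit read pool in the window from 12 nt
upstream of the start codon to 14 nt upstream of the stop codon with the
first 8 codons excluded. Gene-set enrichment uses the upper-tail
hypergeometric test; distribution shifts of a target set use the K-S test
against the rest of the genome.

## Worked example

Simulate a wild-type library and a "mutant" in which AAA dwells 1.5× longer
in the A site, then recover both the read anatomy and the perturbation:

```python
import ribocodon as rc

orfs = rc.build_synthetic_reference(n_orfs=20, length_range_codons=(120, 200), seed=1)
truth_wt  = rc.SimulationTruth(gene_flux=rc.uniform_flux(orfs), seed=1)
truth_mut = rc.SimulationTruth(gene_flux=rc.uniform_flux(orfs),
                               dwell_multiplier={("A", "AAA"): 1.5}, seed=2)

tracks, tables = {}, {}
for name, truth, seed in (("wt", truth_wt, 11), ("mut", truth_mut, 12)):
    reads = rc.simulate_footprints(orfs, truth, 500_000, seed=seed)
    sized = rc.reads_to_sized_counts(reads)
    calib = rc.calibrate_psite(sized, orfs)
    tracks[name] = rc.pool_and_frameshift(sized, orfs, calib)
    tables[name] = rc.assemble_bulk_table(tracks[name], orfs, sample_id=name)

print("calibrated offsets:", calib.psite_offset_by_length)
change = rc.occupancy_change(tables["mut"], tables["wt"]).set_index(["codon", "site"])
print("AAA A-site ratio:  %.3f" % change.loc[("AAA", "A"), "ratio"])

occ = {n: rc.occupancy_table(tracks[n], orfs) for n in tracks}
grid = rc.ks_heatmap(occ["mut"], occ["wt"])
print(grid.nsmallest(3, "p_value")[["codon", "site", "D", "p_value"]])
```

Output:

```
calibrated offsets: {25: 12, 26: 12, 27: 12, 28: 12, 29: 13, 30: 13, 31: 14}
AAA A-site ratio:  1.480
codon site        D  p_value
  AAA    A 1.000000 0.000000
  CAA   +2 0.396226 0.000342
  CAA   -2 0.346154 0.002749
```

The start-codon metagene recovers the simulated P-site geometry exactly;
the bulk occupancy ratio for AAA in the A site (1.48) recovers the
configured 1.5× dwell multiplier within sampling noise while other sites
stay near 1; and the K-S grid ranks (AAA, A site) far below every other
codon–site pair (its p-value underflows at this depth; the runners-up are
ordinary multiple-testing noise at p ≈ 10⁻³–10⁻⁴ across 427 comparisons).

A command-line pipeline wraps the same stages
(`ribocodon --config cfg.yaml --seed 5 --out outdir all`), writing each
stage's TSV outputs plus a manifest with row counts and the config hash.

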