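# triodel

Read-depth discovery of rare inherited biallelic (homozygous) gene deletions
in parent-child trios from whole-genome sequencing cohorts.

The pipeline works on a samples × regions matrix of mean per-base coverage:

1. **Normalize** depths to diploid-scaled dosage with two-stage median
   normalization (per-sample library scale, then per-region baseline across a
   reference cohort); uninformative regions are masked.
2. **Call** integer copy numbers per sample per region (half-integer bin
   edges, upward tie-break, capped at CN 4).
3. **Genotype trios**: retain (proband CN 0, father CN 1, mother CN 1)
   patterns; flag de novo candidates (proband CN 0 with exactly one parent
   CN ≥ 2) separately.
4. **Filter by rarity**: per-region heterozygous-deletion frequency (*fdel*)
   in a control cohort must be strictly below 0.5%.
5. **Merge** contiguous region-level calls into distinct deletion events
   (gap ≤ 100 kb, no intervening un-called unmasked region; identical spans
   across samples are consolidated).
6. **Filter by size**: events of at least 8 kb are retained.
7. **Annotate** events with gene symbols, OMIM-morbid / AR flags, segmental-
   duplication overlap and autozygosity evidence (containment in ≥ 2 Mb ROH
   runs), and summarize morbid-gene enrichment by (fdel × size) strata.

A companion simulator generates control and trio cohorts with deletion
alleles segregating under Hardy-Weinberg and Mendelian transmission
(lognormal sample/region depth effects, Poisson or negative-binomial count
noise, optional injected de novo losses), emitting ground truth for
end-to-end recovery testing. Singleton probands can be screened at loci
discovered in the trio phase (`triodel screen`).

## CLI

All inputs and outputs are plain text (TSV / BED / PED / YAML); coordinates
are 0-based half-open, autosomes 1–22 only.

```sh
triodel simulate --config sim.yaml --outdir sim/   # depth TSV, PED, regions, truth
triodel depth    --regions regions.tsv --coverage S1=s1.depth.txt --out depth.tsv
triodel call     --depth depth.tsv --out-cn cn.tsv --out-ratio ratio.tsv
triodel freq     --cn controls_cn.tsv --out fdel.tsv
triodel trio     --cn cases_cn.tsv --ped pedigree.ped --fdel fdel.tsv --out calls.tsv
triodel merge    --calls calls.tsv --regions regions.tsv --fdel fdel.tsv --out events.tsv
triodel annotate --events events.tsv --regions regions.tsv --gene-flags genes.tsv \
                 --segdup segdup.bed --roh roh.bed --out annotated.tsv
triodel screen   --cn cn.tsv --ped pedigree.ped --targets loci.txt --out hits.tsv
triodel run      --config config.yaml              # full workflow in one step
```

`triodel run` reads a YAML config naming the region table, pedigree, case and
control depth matrices, optional annotation tables, and thresholds
(`max_fdel`, `min_size`, `max_gap`, `min_region_median`, `roh_min`), and
writes `events.tsv`/`events.bed`, the fdel table, de novo candidates, target
loci for the singleton screen, and a run log with per-stage in/out counts.

Example simulator config:

```yaml
seed: 1
n_controls: 2000
n_trios: 300
n_regions: 500
noise: negbin
spiked_events:
  - region_ids: [R00001, R00002, R00003]
    allele_freq: 0.003
    force_parent_het: true
    n_forced_trios: 40
```

## Library use

```python
import triodel as t

cfg = t.SimConfig(seed=1, n_trios=300, n_controls=2000, n_regions=500, noise="negbin",
                  spiked_events=[t.SpikedEvent(("R00001", "R00002", "R00003"), 0.003,
                                               force_parent_het=True, n_forced_trios=40)])
ctrl_depths, ctrl_truth = t.simulate_cohort(cfg)
trio_depths, trio_truth = t.simulate_trios(cfg)
result = t.discover_events(trio_depths, ctrl_depths,
                           t.TrioSet(trios=list(trio_truth.trios)),
                           cfg.resolve_regions())
for event in result.events:
    print(event.chrom, event.start, event.end, event.sample_ids, event.fdel_max)
```
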