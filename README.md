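# paleoibd

Identity-by-descent (IBD) sharing analyses for ancient-DNA cohorts:
segment filtering and pairwise total-IBD matrices, group-level sharing
statistics with seeded permutation nulls, proximity-stratified sharing
contrasts, kinship inference (pairwise mismatch rate and simulated IBD
envelopes), a pedigree IBD simulator with crossover-interference
modelling, a sex-biased-admixture Z statistic, and a synthetic-cohort
generator so the whole pipeline runs with no external data.

## Library overview

| module                 | contents |
|------------------------|----------|
| `paleoibd.segments`    | `IBDSegment`, TSV readers/writers, `merge_adjacent_states`, `filter_segments` (≥ 12 cM, ≥ 220 SNPs/cM, both inclusive), `summarize_pairs`, `IBDMatrix` |
| `paleoibd.groupstats`  | per-group-pair mean sharing (zeros included, denominator = all possible pairs), within-vs-between statistic, normalized continuity ratio, `empirical_p` (proportion of null ≥ observed, no +1 smoothing) |
| `paleoibd.permtests`   | `label_shuffle_test`, `continuity_test` (column reassignment), `contribution_test` (row reassignment, exhaustive or sampled); zero denominators are replaced by 0.01 cM and the permutation kept |
| `paleoibd.proximity`   | haversine distances, mortuary- vs geographic-proximity pair classification (200 km threshold), Wilcoxon rank-sum comparisons (exact for small tie-free sets) |
| `paleoibd.kinship`     | pairwise mismatch rate of pseudo-haploid genotypes, density-mode baseline, kinship coefficient `1 − pmr/baseline` with degree bins, bivariate-normal envelope classification |
| `paleoibd.pedsim`      | gene-dropping simulator for 14 pedigree relationships over a bundled sex-averaged genetic map (~3546 cM), gamma-renewal crossovers (shape 1 = Poisson), envelope building |
| `paleoibd.sexbias`     | `z = (P_A − P_X)/√(σ_A² + σ_X²)` on ancestry-proportion tables |
| `paleoibd.cohort`      | seeded synthetic cohorts (metadata + segments + genotypes) with group-pair Poisson sharing intensities; `coexistence` / `replacement` / `continuity` presets |

## CLI

```bash
paleoibd simulate --preset continuity --seed 1 --out-dir cohort1/
paleoibd matrix --segments cohort1/segments.tsv --meta cohort1/meta.tsv \
    --min-cm 12 --min-density 220 --out matrix.csv
paleoibd groupstats --matrix matrix.csv --meta cohort1/meta.tsv --out stats.tsv
paleoibd permtest continuity --matrix matrix.csv --meta cohort1/meta.tsv \
    --n-perm 10000 --seed 42 --out result.json
paleoibd proximity --segments cohort1/segments.tsv --meta cohort1/meta.tsv \
    --focal central --threshold-km 200 --out pairs.tsv
paleoibd kinship --geno cohort1/genotypes.tsv --out kin.tsv
paleoibd pedsim --relationships all --n-rep 100 --seed 7 --out envelopes.tsv
paleoibd sexbias --in ancestry.tsv --out ancestry_z.tsv
```

For `permtest continuity|contribution` the group labels must be Fc/Fe
(source-tradition rows, focal vs reference region) and Sc/So
(successor-tradition columns); `permtest within-between` needs exactly two
labels. Labels come from the metadata `group` column or a `--groups` YAML
mapping ids to labels.

## File formats

* segment TSV: `iid1 iid2 ch start_cM end_cM length_cM n_snps state`
* metadata TSV: `iid group region lat lon date_lo date_hi sex`
* matrix CSV: ids in the header row and first column, symmetric numeric body
* genotype TSV: one row per individual, 0/1/9-coded pseudo-haploid calls
* ancestry TSV: `target source P_A sigma_A P_X sigma_X`

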