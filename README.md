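# spheretrace

A tested, reusable pipeline for metabolically comparing two groups of
samples (e.g., tumor genotypes) from expression and stable-isotope tracing
data:

1. **EC-collapsed gene-set enrichment** (`spheretrace.gsea`) — microarray
   probes are collapsed onto enzyme-activity nodes (EC numbers) by keeping
   the probeset with the maximum absolute signal-to-noise ratio per node,
   KEGG-style modules are scored with the running-sum enrichment statistic,
   normalized against a phenotype-permutation null (NES), size-filtered
   (3–500 represented nodes), and two datasets' NES profiles are compared
   with an |NES| > 1.2 intersection rule.
2. **Isotopologue arithmetic** (`spheretrace.mid`) — natural-abundance
   correction by forward-convolution least squares, relative amounts
   normalized to an internal standard and cell number, and a single
   labeling index per metabolite (fractional contribution or 1 − M0).
3. **Labeling statistics** (`spheretrace.labeling`) — hierarchical or
   k-medoids sample clustering with adjusted-Rand agreement against known
   groups, per-metabolite two-tailed t tests at an uncorrected threshold,
   and chi-square over-representation of a metabolite category among the
   significant hits.
4. **Nucleotide source partitioning** (`spheretrace.sources`) — dual-tracer
   DNA deoxycytidine channels are split into pre-existing, de novo
   (glucose-derived carbon shifts) and salvage (three heavy nitrogens)
   pools, with the de novo share of newly synthesized material as the
   headline comparison.
5. **Synthetic ground truth** (`spheretrace.synthetic`) — seeded generators
   for every input: expression matrices with planted module signal,
   isotopologue panels under a binomial-mixture labeling model with natural
   abundance and lognormal noise, and dual-tracer panels with known source
   fractions. Parameter recovery against these truths is the pipeline's
   principal acceptance surface.

## CLI

Every stage is a subcommand of `spheretrace`:

```sh
# synthetic inputs with known truth
spheretrace simulate expression --n-probes 300 --samples-per-group 20 20 \
    --planted M0000:+1 --effect-size 2.0 --seed 1 --out data/
spheretrace simulate dualtracer --f-preexisting 0.4 --f-denovo 0.3 \
    --f-salvage 0.3 --group mut --seed 1 --out data/

# analyses
spheretrace gsea --expr data/expression.gct --cls data/phenotype.cls \
    --probe-map data/probe_map.tsv --ec-map data/ec_map.tsv \
    --gmt data/modules.gmt --n-perm 1000 --seed 1 --out enrichment.tsv
spheretrace concordance --a enrich_a.tsv --b enrich_b.tsv --tau 1.2 --out conc.json
spheretrace mid --input data/mid.csv --samples data/mid_samples.csv \
    --correct-na --mode fractional --tracer-enrichment 0.5 --out out/
spheretrace labeling-stats --index out/labeling_index.tsv \
    --labels data/mid_labels.csv --alpha 0.05 --k 2 --out stats/
spheretrace nucleotide-sources --input data/dualtracer.csv \
    --labels data/dualtracer_labels.csv --denovo-min-shift 3 --out sources/
```

A whole run can be driven from one YAML config (flags override config
values; every seed is explicit — reruns are byte-identical):

```sh
spheretrace demo-config --seed 1 --out run.yaml
spheretrace run --config run.yaml --out results/
```

`results/manifest.json` records versions, parameters, seeds and SHA-256
checksums of every artifact.

## File formats

GCT 1.2 or TSV expression matrices; two-class CLS phenotype files; GMT
module collections; two-column TSV probe→gene and gene→EC maps (a gene may
map to several ECs); long-format MID CSV (`metabolite, formula,
isotopologue_index, sample, intensity`) with a per-sample CSV
(`sample, internal_standard_intensity, cell_count`); dual-tracer CSV
(`sample, carbon_shift, n15_count, intensity`); TSV/JSON results.
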