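# stagematch

Molecular life-stage association for taxa whose immature stages cannot be
identified morphologically. Given two gene trees (typically a nuclear locus
such as CAD and the mitochondrial COI barcode) sampled from a mixture of
identified adults and unidentified larvae/pupae, `stagematch` delimits
molecular clusters with two re-implemented single-locus species delimiters —
single-threshold GMYC and maximum-likelihood PTP — tests reciprocal
monophyly across the genes, and applies a five-criterion consensus vote to
decide which larvae belong to which adult morphospecies. Species that the
genes cannot tell apart are pooled into *species complexes*; clusters
containing only immatures become larva-only OTUs. The intended users are
taxonomists and molecular ecologists associating life stages by DNA
barcoding with more than one marker.

## The models

**GMYC (generalized mixed Yule coalescent, single threshold).** On an
ultrametric haplotype tree, branching events older than a threshold age *T*
are speciations and younger events are within-species coalescences. During
an inter-event interval the total branching rate is

    b_i = λ_div · k_i^{p_div} + λ_coal · Σ_j [ n_{i,j} (n_{i,j} − 1) ]^{p_coal}

with `k_i` species lineages and `n_{i,j}` sampled lineages within species
*j*; the log-likelihood is `Σ_i [ log b_i − b_i x_i ]` over inter-event
waiting times `x_i` (with exponents 1 and a single species this is exactly
the Kingman coalescent density). *T* is scanned over midpoints between
distinct node ages; at each candidate the four parameters are maximized
numerically. Delimited entities are the subtrees crossing the best
threshold, and a likelihood-ratio test compares the mixed model against a
single-coalescent null.

**PTP (Poisson tree process).** On a substitution-scaled tree, branch
lengths are modelled as two exponential classes — between-species and
within-species — and a delimitation is a partition of the tips into
subtrees. The maximum-likelihood partition is found by exhaustive
enumeration of all subtree partitions (small trees) or a seeded greedy
hill-climb (any size).

**Association.** For each candidate species, five yes/no criteria: PTP and
GMYC cluster criteria on each gene (larvae are conspecific with an adult
species if they share a delimited cluster containing only that one
identified adult species) plus reciprocal monophyly (the species' adults
and the same larvae form an exclusive, supported clade on both genes, using
a 0.95 posterior-probability threshold by default). Association succeeds
when ≥ 3 of 5 criteria hold; non-evaluable criteria count as unfulfilled.

## Worked example

The package ships a coalescent-within-Yule simulator that doubles as a
fixture factory. A six-species, two-gene dataset, end to end:

```python
from stagematch import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    outdir="demo", seed=7,
    simulate=SimConfig(n_species=6, samples_per_species=8, depth_ratio=120,
                       missing_gene_prob={"CAD": 0.2, "COI": 0.1},
                       seq_length={"CAD": 200, "COI": 180}, seed=7),
)
summary = run_pipeline(cfg)
print(summary["counts"])
```

prints

```
{'n_otus': 6, 'n_species_level': 6, 'n_otu_level': 0,
 'n_larvae_species': 33, 'n_larvae_otu': 0}
```

i.e. all six species came out as clean single-species OTUs and all 33
sequenced larvae were associated at species level. `demo/` then holds the
delimited partitions (`cluster_counts.tsv`: here CAD PTP split one species,
9 clusters, while both GMYC runs found exactly 6), the per-OTU association
table (Table-5-style: per-criterion cells, criteria count, success flag),
haplotype tables, alignment statistics and a JSON run log. The first rows
of `association_table.tsv`:

```
otu   species  n_larvae  CAD_PTP  CAD_GMYC  COI_PTP  COI_GMYC  RECIP_MONO  n_fulfilled  success  level
sp01  sp01     7         no       yes       yes      yes       no          3            True     species
sp02  sp02     3         yes      yes       yes      yes       no          4            True     species
```

The same pipeline runs from the shell: `stagematch run --config run.yaml`,
and the individual stages are exposed as `stagematch gmyc|ptp|monophyly|
collapse|simulate`.

Real datasets enter through `read_gene_tree` (newick/NEXUS, node supports
from labels or BEAST-style comments, optional outgroup rooting+pruning),
`read_specimen_table` (TSV with life stage, species label and per-gene
availability) and `Alignment.from_fasta`; collapsing identical sequences to
haplotypes before GMYC is one call (`collapse_haplotypes`).

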