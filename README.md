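# onfhost

Alignment-free virus–host prediction from oligonucleotide frequencies (ONF).

Given viral genomes or contigs and a set of candidate prokaryotic host
genomes, `onfhost` computes pairwise dissimilarities between every virus and
host from their k-mer composition and predicts each virus's host taxonomy.
Eleven measures are implemented in two families:

| family | measures |
| --- | --- |
| observed frequencies only | `Eu`, `Ma`, `Ch`, `d2`, `JS` |
| background-corrected | `d2star`, `d2S`, `Hao`, `Teeling`, `EuF`, `Willner` |

The background-corrected measures remove the k-mer counts expected under a
per-genome Markov chain (default order 2, or BIC-selected) before comparing,
so two sequences are matched on their over/under-represented words rather
than on raw composition. All scores are oriented so that smaller means more
similar. `d2star` at k = 6 is the recommended default.

Host selection supports: nearest host, consensus of the top-n hosts
(per-rank modal taxon), a maximum-dissimilarity threshold for refusing
low-confidence predictions, a host-list filter (e.g. restrict candidates to
one habitat), and a one-sided Wilcoxon rank-sum test for taxa whose hosts
score systematically lower than the rest (Bonferroni corrected).

## Command line

One FASTA file = one genome (or one multi-contig genome project); a
directory of FASTA files = one collection.

```sh
# make a fully synthetic benchmark (hosts, viruses, taxonomy, truth)
onfhost simulate --out fixture/ --n-hosts 50 --seed 1

# score and predict
onfhost predict \
    --virus-dir fixture/viruses --host-dir fixture/hosts \
    --taxonomy fixture/taxonomy.tsv --truth fixture/truth.tsv \
    --measure d2star -k 6 --order 2 \
    --consensus 30 --threshold 0.3 \
    --out run/

# score an existing predictions file against truth
onfhost evaluate --predictions run/d2star_k6_r2.predictions.tsv \
    --truth fixture/truth.tsv --taxonomy fixture/taxonomy.tsv --out acc.tsv

# rank-sum taxon report from a stored matrix
onfhost ranksum --matrix run/d2star_k6_r2.matrix.tsv \
    --taxonomy fixture/taxonomy.tsv --rank genus --out ranksum.tsv
```

`predict` writes, per measure: the full score matrix
(`<measure>_k<k>_r<r>.matrix.tsv`), predictions, an accuracy report when
truth is given, and a JSON run manifest. `--order auto` selects the
background order by BIC over the query viruses. `--host-filter list.txt`
restricts candidate hosts to the ids in the file.

Taxonomy tables are TSV with columns
`host_id, genus, family, order, class, phylum, domain`; truth tables add a
`host_id` column after `virus_id`. Use the literal string `unknown` for
missing ranks — unknown labels never win a consensus vote and never count
as correct.

## Python API

```python
from onfhost import (
    read_genome, MeasureConfig, compute_matrix,
    predict_nearest, accuracy_by_level,
)

viruses = [read_genome(p) for p in virus_paths]
hosts = [read_genome(p) for p in host_paths]
config = MeasureConfig("d2star", k=6, order=2)
matrix = compute_matrix(viruses, hosts, config)
predictions = predict_nearest(matrix, taxonomy, threshold=0.3)
```

The `onfhost.synthetic_data` module generates benchmarks with tunable
virus–host compositional similarity (`alpha`), host relatedness
(`host_similarity`) and chain order; `onfhost.evaluation` provides ROC/AUC,
score-distribution t-tests, the empirical random-guess baseline, and
fragment-length / sequencing-error robustness sweeps.

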