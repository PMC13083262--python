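# tdmdquant

Quantitative analysis of **target-directed microRNA degradation (TDMD)** — the
pathway in which an extensively pairing "trigger" RNA marks an AGO–miRNA
complex for ubiquitylation by the ZSWIM8–CUL3 E3 ligase, leading to decay of
the miRNA rather than the target.

The package is aimed at groups studying ZSWIM8-dependent miRNA turnover who
need three kinds of quantification under one roof:

1. **Isoform-resolved small-RNA-seq** (`tdmdquant.pipeline`,
   `tdmdquant.stability`): FASTQ reads are adapter-trimmed, quality-filtered
   (mean Q > 30), assigned by exact string match of their first 13 nt against
   a miRNA dictionary (species sharing a 13-nt prefix are collapsed into one
   entry), and tabulated by read length over 13–31 nt. Differential analysis
   between *Zswim8*-knockout and control libraries (3 vs 3) then proceeds
   through an expression filter (> 5 reads in ≥ 2 knockout libraries and
   ≥ 30 reads over all six), median-of-ratios size factors, per-miRNA log₂
   fold changes with negative-binomial Wald tests, BH adjustment, a
   three-way classification of potentially ZSWIM8-sensitive miRNAs
   (significance, separation from the co-produced passenger strand, prior
   annotation), per-isoform fold changes centered on the median 22-nt fold
   change, and a one-sided Wilcoxon test for accumulation of isoforms
   shorter than 19 nt.

2. **Binding-assay quantification** (`tdmdquant.binding`): the
   ligand-depletion ("quadratic") titration isotherm

   ```
   F_bound = ((DF·[stock] + [target_T] + K_D)
              − √((DF·[stock] + [target_T] + K_D)² − 4·DF·[stock]·[target_T]))
             / (2·[target_T]) · F_max
   ```

   and its constrained least-squares fit (F_max ∈ (0, 1], K_D in log space,
   gridded starts); co-IP gel quantification with blank-rectangle background
   subtraction, 0 nM-lane subtraction and T6B normalization; trigger versus
   seed-only fold enrichment with censoring for bands at the quantification
   floor; log-linear interpolation of the bait concentration reaching a
   given pull-down level; single-site (hyperbolic) fits and double-filter
   fraction-bound quantification.

3. **Duplex-architecture annotation** (`tdmdquant.duplex`): seed match
   (guide nt 2–8), best contiguous 3′-pairing register across internal-loop
   combinations, flank lengths, and classification into `seed_only`,
   `supplementary`, `tdmd_like`, `full`, or `no_site`.

A synthetic-data module (`tdmdquant.simulate`) generates every input with
embedded ground truth — dictionaries, negative-binomial count tables, FASTQ
reads, gel intensities, titration series — so the entire workflow is
testable without sequencing data.

## Worked example

```python
import numpy as np
from tdmdquant import simulate, stability

mirdict = simulate.make_mirna_dictionary(n_hairpins=100, prefix_collision_rate=0.05, seed=7)
truth = simulate.make_simulation_truth(mirdict, seed=7, frac_sensitive=0.1, lfc_sensitive=1.5)
table = simulate.simulate_isoform_counts(mirdict, truth)

pm = stability.passenger_map_from_dictionary(mirdict)
res = stability.analyze(table, truth.design, passenger_map=pm)

print(res.per_mirna.sort_values("padj").head(5)[["summed_lfc", "summed_se", "padj", "excluded"]].round(3))
st = res.short_test
print(f"short-isoform test: p={st.p:.2e}, median centered lfc={st.effect_median:+.3f}")
```

```
            summed_lfc  summed_se   padj  excluded
mirna
mir0054-5p       1.465      0.080  0.005      True
mir0074-5p       1.580      0.087  0.005      True
mir0085-5p       1.459      0.099  0.007      True
mir0022-5p       1.321      0.107  0.011      True
mir0057-5p       1.420      0.132  0.012      True
short-isoform test: p=1.23e-25, median centered lfc=+0.042
```

Ten of the 100 simulated miRNAs carry a true knockout effect of log₂ = 1.5;
the top of the adjusted-significance ranking recovers them (all five shown
are truly sensitive), their estimated fold changes sit near the simulated
value, and they are marked `excluded` so their isoforms do not contaminate
the length analysis. The short-isoform test detects the simulated
accumulation of < 19-nt isoforms after knockout (positive median centered
fold change, small p).

The same workflow is available from the shell:

```bash
tdmdquant simulate dict --n-hairpins 100 --seed 7 --out-prefix dict
tdmdquant simulate counts --dict-fasta dict.fa --dict-tsv dict.tsv --seed 7 --out counts.tsv
tdmdquant simulate fastq --counts counts.tsv --dict-fasta dict.fa --dict-tsv dict.tsv \
    --adapter TGGAATTCTCGGGTGCCAAGG --out-dir fq
tdmdquant map --dict-fasta dict.fa --dict-tsv dict.tsv --adapter TGGAATTCTCGGGTGCCAAGG \
    --out mapped.tsv fq/*.fastq
tdmdquant de --counts mapped.tsv --design "ko_1=KO,ko_2=KO,ko_3=KO,ctrl_1=control,ctrl_2=control,ctrl_3=control" \
    --dict-fasta dict.fa --dict-tsv dict.tsv --out-prefix results
```

## Documentation

The model, its assumptions, default parameters and known limitations are
described in [docs/methods.md](docs/methods.md).
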