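# itfscreen

Analysis toolkit for **pooled inducible transcription-factor (TF)
overexpression screens read out by single-cell RNA-seq**. A pool of
embryonic stem cell lines, each carrying one doxycycline-inducible TF
construct, is induced and profiled; the task is to work out *which* TF each
cell expresses ectopically and *how strongly* that TF pushes the cell away
from the undifferentiated state.

`itfscreen` implements the two halves of that computation:

1. **Barcode-free demultiplexing via junction tags.** The ectopic
   transcript contains vector–ORF junctions that never occur in the
   endogenous gene. A forward tag is built as the last 7 nt of vector
   sequence upstream of the start codon plus the first 21 nt of the CDS
   (28 nt total); a reverse tag is the reverse complement of the last
   21 nt of the CDS (including the stop codon) plus the first 7 nt of
   downstream vector. Tags colliding with the reference genome or with
   each other are lengthened on the ORF side until unique. Reads are
   scanned for tags, aggregated per (cell barcode, UMI) molecule, and each
   cell is called `single` / `multi` / `control` / `unassigned` using a
   minimum-UMI threshold chosen by sweeping 1–5 and maximizing the number
   of single-TF cells — ambient contamination contributes 1–2 UMIs, real
   induction many, so the single-TF count peaks at an intermediate
   threshold.

2. **The differentiation index.** Counts are normalized (log1p-CP10K by
   default, pluggable), the induced-TF genes are excluded, PCA (50 PCs) is
   fitted on all cells jointly, and every cell's Euclidean distance to the
   *control-cell centroid* is z-normalized with the mean and standard
   deviation of the control cells' own distances:

   `d_i = (‖s_i − c‖ − μ_ctrl) / σ_ctrl`

   Control cells score mean 0, sd 1 by construction; a TF whose cells'
   indexes exceed controls (one-sided Mann–Whitney U, BH-adjusted
   p < 0.01) is called *potent*. The index can be restricted to GMT gene
   sets (≥15 genes after exclusions) to resolve lineages; per-(TF, set)
   medians feed percentile ranks and a Pearson TF–TF similarity matrix
   with average-linkage clustering.

Cell QC (strict: >1000 detected genes, <10% mitochondrial reads, >10,000
molecules), pseudobulk group means, marker panels relative to control, and
moving-window smoothing of per-gene scores are included, along with seeded
synthetic generators for tag-bearing reads and expression cohorts so the
whole pipeline is testable without any sequencing data.

## Worked example

```python
import itfscreen as itf

# --- demultiplexing on a simulated 80-construct screen -------------------
orfs, vec = itf.simulate.example_tag_inputs(n_tfs=80, seed=0)
table = itf.build_tag_table(orfs, vec)          # 80 28-nt tag pairs

reads, truth = itf.simulate.simulate_tag_reads(
    itf.ReadSimParams(n_cells=1000, seed=7), table)
hits = itf.scan_reads(reads, table)
counts = itf.umi_count_table(itf.aggregate_umis(hits, reads))
sweep = itf.sweep_umi_thresholds(counts)
print(sweep.to_string(index=False))
```

```
 threshold  n_single  n_multi  n_zero
         1       498      502       0
         2       751      248       1
         3       994        0       6
         4       975        0      25
         5       916        0      84
```

Half the cells carry an ambient second TF at 1–2 UMIs, so they look
multi-TF at thresholds 1–2; at threshold 3 the contaminants vanish while
true inductions (Poisson mean 8 UMIs) survive — `select_threshold(sweep)`
returns **3**, and `classify_cells` at that threshold calls 994 of 1000
cells single-TF.

```python
# --- differentiation index on a simulated cohort -------------------------
pops = tuple(itf.PopulationSpec(f"Tf{i+1:02d}", 100, 50, 2.0) for i in range(3)) \
     + tuple(itf.PopulationSpec(f"Null{i+1:02d}", 100, is_null=True) for i in range(3))
counts2, cells2, truth2 = itf.simulate_expression_cohort(
    itf.ExprSimParams(n_genes=2000, n_control_cells=2000, populations=pops, seed=3))
controls = cells2.loc[cells2.label == "control", "cell_barcode"].tolist()
index, ref = itf.differentiation_index_pipeline(
    counts2, controls, exclude_genes=truth2["itf_genes"])
print(itf.test_potency(index, cells2)
      [["tf_name", "n_cells", "median_index", "p_adj", "potent"]]
      .round(3).to_string(index=False))
```

```
tf_name  n_cells  median_index  p_adj  potent
 Null01      100        -0.109  0.545   False
 Null02      100         0.009  0.545   False
 Null03      100         0.138  0.301   False
   Tf01      100         5.227  0.000    True
   Tf02      100         5.207  0.000    True
   Tf03      100         4.363  0.000    True
```

Populations with a planted expression shift (2.0 in log-mean on 50 of
2000 genes) sit 4–5 control standard deviations from the control centroid
and are flagged potent; null populations hug index 0 and are not.

A `click` CLI wraps the same functions:
`itfscreen build-tags | scan | assign | diffindex | pseudobulk | smooth |
simulate` (see `itfscreen --help`).

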