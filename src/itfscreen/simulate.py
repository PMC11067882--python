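"""Seeded synthetic inputs: tag-bearing reads and expression cohorts.

Two generators make every pipeline stage testable without any download:

* :func:`simulate_tag_reads` emulates the demultiplexing problem — each
  cell expresses one true construct whose transcripts (UMIs) carry the
  junction tag, and with some probability the cell additionally picks up
  1–2 ambient molecules of a *different* construct (the mechanism behind
  spurious multi-TF cells). Reads embed the tag at a random offset with
  optional substitution noise.

* :func:`simulate_expression_cohort` emulates the scoring problem —
  control cells drawn from a baseline negative binomial expression model,
  plus labeled populations that either equal the baseline (null) or have a
  log-scale mean shift applied to a random subset of genes (potent).

Both are pure functions of (params, seed) and return the ground truth
needed to recompute every downstream expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .scan import TaggedRead
from .tags import TagSpec, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadSimParams:
    """Conditions for the tag-read simulation."""

    n_cells: int = 1000
    true_umi_mean: float = 8.0          # Poisson mean, resampled to >= 1
    contamination_prob: float = 0.5     # P(cell gains an ambient second TF)
    contamination_umis: tuple[int, int] = (1, 2)  # uniform support
    reads_per_umi: int = 3
    substitution_error_rate: float = 0.0
    read_length: int = 90
    barcode_len: int = 16
    umi_len: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ValueError("contamination_prob must be in [0, 1]")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1]")
        if min(self.n_cells, self.reads_per_umi, self.read_length) <= 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """One labeled cell population in an expression cohort."""

    name: str
    n_cells: int
    shifted_gene_count: int = 0
    shift_size: float = 0.0  # added to log-mean of the shifted genes
    is_null: bool = False


@dataclass(frozen=True)
class ExprSimParams:
    """Conditions for the expression-cohort simulation."""

    n_genes: int = 2000
    n_control_cells: int = 2000
    populations: tuple[PopulationSpec, ...] = ()
    dispersion: float = 0.3  # NB overdispersion: var = m + dispersion * m^2
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _unique_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    while len(seen) < n:
        seen.add(_random_seq(rng, length))
    return sorted(seen)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.nonzero(hit)[0]:
        chars[i] = rng.choice(_BASES[_BASES != chars[i]])
    return "".join(chars)


def simulate_tag_reads(
    params: ReadSimParams,
    tags: list[TagSpec],
) -> tuple[list[TaggedRead], dict[str, pd.DataFrame]]:
    """Generate tag-bearing reads plus per-read and per-cell ground truth.

    Each cell draws one true TF uniformly from the tag table and
    Poisson(true_umi_mean) UMIs resampled to be at least 1; with
    ``contamination_prob`` it also receives 1 or 2 (uniform) ambient UMIs
    of one random other TF. Every UMI emits ``reads_per_umi`` reads with
    the forward or reverse tag (random orientation) embedded at a random
    offset in random background sequence, then per-base substitution
    noise. Deterministic given the seed.
    """
    if not tags:
        raise ValueError("tag table is empty")
    rng = np.random.default_rng(params.seed)
    tag_by_name = {t.tf_name: t for t in tags}
    tf_names = sorted(tag_by_name)
    barcodes = _unique_seqs(rng, params.n_cells, params.barcode_len)

    reads: list[TaggedRead] = []
    read_truth_rows = []
    cell_truth_rows = []
    read_no = 0
    for cb in barcodes:
        true_tf = tf_names[rng.integers(len(tf_names))]
        n_true = 0
        while n_true < 1:
            n_true = int(rng.poisson(params.true_umi_mean))
        molecules = [(true_tf, False)] * n_true
        contaminant = ""
        if len(tf_names) > 1 and rng.random() < params.contamination_prob:
            others = [t for t in tf_names if t != true_tf]
            contaminant = others[rng.integers(len(others))]
            lo, hi = params.contamination_umis
            n_cont = int(rng.integers(lo, hi + 1))
            molecules += [(contaminant, True)] * n_cont
        cell_truth_rows.append(
            {"cell_barcode": cb, "true_tf": true_tf, "n_true_umis": n_true,
             "contaminant_tf": contaminant}
        )
        umis = _unique_seqs(rng, len(molecules), params.umi_len)
        for (tf, is_cont), umi in zip(molecules, umis):
            spec = tag_by_name[tf]
            for _ in range(params.reads_per_umi):
                tag = spec.forward_tag if rng.random() < 0.5 else spec.reverse_tag
                max_off = params.read_length - len(tag)
                if max_off < 0:
                    raise ValueError("read_length shorter than tag")
                off = int(rng.integers(max_off + 1))
                seq = (
                    _random_seq(rng, off)
                    + tag
                    + _random_seq(rng, params.read_length - off - len(tag))
                )
                seq = _mutate(rng, seq, params.substitution_error_rate)
                rid = f"read{read_no:08d}"
                read_no += 1
                reads.append(TaggedRead(rid, cb, umi, seq))
                read_truth_rows.append(
                    {"read_id": rid, "cell_barcode": cb, "umi": umi,
                     "tf_name": tf, "is_contaminant": is_cont, "offset": off}
                )
    truth = {
        "reads": pd.DataFrame(read_truth_rows),
        "cells": pd.DataFrame(cell_truth_rows),
    }
    return reads, truth


def true_umi_count_table(truth: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cell × TF UMI counts tallied directly from the ground truth."""
    mol = truth["reads"].drop_duplicates(["cell_barcode", "umi", "tf_name"])
    table = mol.value_counts(["cell_barcode", "tf_name"]).unstack(fill_value=0)
    table.columns.name = None
    table.index.name = "cell_barcode"
    return table.sort_index()


def simulate_expression_cohort(
    params: ExprSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a counts matrix, a label table, and ground truth.

    Baseline per-gene means are lognormal(0, 1); counts are negative
    binomial with var = m + dispersion * m^2. Each population gene panel
    is drawn from the regular genes (never from the induced-TF genes), and
    one marker gene named after the population is added to the matrix and
    strongly expressed only there, emulating the induction itself — it is
    the gene the scoring pipeline must exclude.

    Returns (counts cells × genes, cells label table, truth dict).
    """
    rng = np.random.default_rng(params.seed)
    gene_names = [f"g{i + 1:04d}" for i in range(params.n_genes)]
    pop_names = [p.name for p in params.populations]
    if len(set(pop_names)) != len(pop_names):
        raise ValueError("population names must be unique")
    all_genes = gene_names + pop_names  # induced-TF marker genes appended
    base_log_mean = rng.normal(0.0, 1.0, size=params.n_genes)
    marker_base_log_mean = np.full(len(pop_names), -3.0)  # near-silent baseline
    log_mean = np.concatenate([base_log_mean, marker_base_log_mean])

    def nb_sample(mean_vec: np.ndarray, n_cells: int) -> np.ndarray:
        m = np.clip(mean_vec, 1e-8, None)
        if params.dispersion <= 0:
            return rng.poisson(np.broadcast_to(m, (n_cells, m.size)))
        r = 1.0 / params.dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, np.broadcast_to(p, (n_cells, m.size)))

    blocks, labels, tf_col = [], [], []
    base_mean = np.exp(log_mean)
    blocks.append(nb_sample(base_mean, params.n_control_cells))
    labels += ["control"] * params.n_control_cells
    tf_col += [""] * params.n_control_cells

    shifted_genes: dict[str, list[str]] = {}
    for k, pop in enumerate(params.populations):
        lm = log_mean.copy()
        lm[params.n_genes + k] = 2.0  # induced marker gene on
        if pop.shifted_gene_count and not pop.is_null:
            chosen = rng.choice(params.n_genes, size=pop.shifted_gene_count,
                                replace=False)
            lm[chosen] += pop.shift_size
            shifted_genes[pop.name] = [gene_names[i] for i in sorted(chosen)]
        else:
            shifted_genes[pop.name] = []
        blocks.append(nb_sample(np.exp(lm), pop.n_cells))
        labels += ["single"] * pop.n_cells
        tf_col += [pop.name] * pop.n_cells

    X = np.vstack(blocks)
    n_cells_total = X.shape[0]
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells_total)]
    counts = pd.DataFrame(X, index=cell_ids, columns=all_genes)
    cells = pd.DataFrame(
        {"cell_barcode": cell_ids, "label": labels, "tf_name": tf_col}
    )
    truth = {
        "itf_genes": pop_names,
        "shifted_genes": shifted_genes,
        "is_potent": {p.name: (not p.is_null and p.shifted_gene_count > 0)
                      for p in params.populations},
        "base_log_mean": pd.Series(base_log_mean, index=gene_names),
        "params": asdict(params),
    }
    return counts, cells, truth


def example_tag_inputs(
    n_tfs: int = 80,
    cds_len: int = 600,
    seed: int = 0,
):
    """Random ORFs and vector context for simulations and round-trip tests.

    Returns (orfs, vector_context) ready for
    :func:`itfscreen.tags.build_tag_table`. CDSs begin with ATG, end with
    a stop codon, and are distinct.
    """
    from .tags import OrfRecord, VectorContext

    rng = np.random.default_rng(seed)
    stops = ["TAA", "TAG", "TGA"]
    orfs = []
    seen: set[str] = set()
    i = 0
    while len(orfs) < n_tfs:
        body = _random_seq(rng, cds_len - 6)
        cds = "ATG" + body + stops[rng.integers(3)]
        if cds[:24] in seen:  # keep forward cores distinct
            continue
        seen.add(cds[:24])
        i += 1
        orfs.append(OrfRecord(name=f"Tf{i:02d}", cds=cds))
    vec = VectorContext(upstream=_random_seq(rng, 30), downstream=_random_seq(rng, 30))
    return orfs, vec
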