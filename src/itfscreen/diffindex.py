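"""Differentiation index: control-referenced PCA centroid distance z-scores.

The differentiation index quantifies how far a cell's transcriptome has
moved from the undifferentiated (control) state. The procedure:

1. normalize counts (default: per-cell scaling to 10,000 followed by
   log1p; any variance-stabilized matrix can be supplied instead);
2. drop the induced-TF genes themselves and fit PCA (default 50 PCs) on
   all cells jointly;
3. compute the centroid of control cells in PC space, the Euclidean
   distance of every cell to that centroid, and z-normalize all distances
   with the mean and sample standard deviation of the *control* distances.

A TF is called potent when its single-TF cells' indexes exceed the control
distribution (one-sided Mann–Whitney U, Benjamini–Hochberg adjusted
p < 0.01 by default). The same index can be restricted to named gene sets
(the whole pipeline re-run on the set's genes) to resolve which programs a
TF activates; per-(TF, gene set) medians feed percentile ranks and the
TF–TF similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .assign import LABEL_CONTROL, LABEL_SINGLE

DEFAULT_N_PCS = 50
DEFAULT_TARGET_SUM = 10_000.0
DEFAULT_MIN_SET_SIZE = 15
DEFAULT_ALPHA = 0.01
MIN_CONTROL_CELLS = 3
MIN_CELLS_PER_TF = 3
#: ribosomal protein gene-name prefixes (mouse convention)
RIBOSOMAL_PREFIXES = ("Rps", "Rpl")


class DegenerateControls(ValueError):
    """Too few control cells, or zero variance in control distances."""


class AllZeroCell(UserWarning):
    """A cell had zero total counts and was left as zeros."""


class RankDeficient(UserWarning):
    """Requested more PCs than the data support; count was reduced."""


class ZeroVarianceRow(UserWarning):
    """A TF's median-index vector was constant and was dropped."""


class SetTooSmall(UserWarning):
    """A gene set fell below the minimum size after exclusions."""


def as_expression_frame(x) -> pd.DataFrame:
    """Coerce an AnnData or DataFrame to a dense cells × genes DataFrame."""
    if isinstance(x, pd.DataFrame):
        return x
    try:  # AnnData without importing it as a hard type
        from scipy import sparse

        X = x.X
        if sparse.issparse(X):
            X = X.toarray()
        return pd.DataFrame(np.asarray(X), index=x.obs_names, columns=x.var_names)
    except AttributeError:
        raise TypeError(f"expected DataFrame or AnnData, got {type(x)!r}")


# ---------------------------------------------------------------------------
# normalization

def normalize_counts(
    counts,
    method: str | Callable[[pd.DataFrame], pd.DataFrame] = "log1p_cp10k",
    target_sum: float = DEFAULT_TARGET_SUM,
) -> pd.DataFrame:
    """Normalize a raw count matrix (cells × genes).

    The default scales each cell to ``target_sum`` total counts and applies
    log1p — a simpler stand-in for variance stabilization, recorded in the
    result's ``attrs["normalization"]``. A callable can be supplied to plug
    in any other normalization with the same contract, and an already-
    normalized matrix can bypass this step entirely.
    """
    df = as_expression_frame(counts)
    if callable(method):
        out = method(df)
        out.attrs["normalization"] = getattr(method, "__name__", "custom")
        return out
    if method != "log1p_cp10k":
        raise ValueError(f"unknown normalization method {method!r}")
    X = df.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) left as zeros",
                      AllZeroCell, stacklevel=2)
    scale = np.where(zero, 1.0, totals)
    out = pd.DataFrame(
        np.log1p(X / scale[:, None] * target_sum), index=df.index, columns=df.columns
    )
    out.attrs["normalization"] = "log1p_cp10k"
    return out


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcSpace:
    """Fitted PCA coordinate system over cells."""

    scores: pd.DataFrame    # cells × PCs
    loadings: pd.DataFrame  # genes × PCs (orthonormal columns)
    mean: pd.Series         # per-gene centering vector
    n_pcs: int
    excluded_genes: list[str] = field(default_factory=list)


def fit_pca(
    norm,
    n_pcs: int = DEFAULT_N_PCS,
    exclude_genes: Iterable[str] = (),
    random_state: int = 0,
) -> PcSpace:
    """Fit PCA on a normalized matrix after dropping the induced-TF genes.

    The ectopically induced genes are removed before fitting so the index
    measures downstream transcriptome change, not the induction itself.
    ``n_pcs`` is capped at the feasible rank with a warning.
    """
    df = as_expression_frame(norm)
    excluded = [g for g in exclude_genes if g in df.columns]
    kept = df.drop(columns=excluded)
    feasible = min(kept.shape[0], kept.shape[1])
    k = min(n_pcs, feasible)
    if k < n_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {k} (rank limit)",
                      RankDeficient, stacklevel=2)
    solver = "randomized" if min(kept.shape) > 4 * k and kept.size > 2_000_000 else "full"
    pca = PCA(n_components=k, svd_solver=solver, random_state=random_state)
    scores = pca.fit_transform(kept.to_numpy(dtype=float))
    pc_names = [f"PC{i + 1}" for i in range(k)]
    return PcSpace(
        scores=pd.DataFrame(scores, index=kept.index, columns=pc_names),
        loadings=pd.DataFrame(pca.components_.T, index=kept.columns, columns=pc_names),
        mean=pd.Series(pca.mean_, index=kept.columns),
        n_pcs=k,
        excluded_genes=excluded,
    )


# ---------------------------------------------------------------------------
# differentiation index

@dataclass(frozen=True)
class ControlReference:
    """z-normalization parameters derived from control cells."""

    centroid: np.ndarray
    mu: float
    sigma: float


def compute_differentiation_index(
    pcs: PcSpace,
    control_cells: Sequence[str],
) -> tuple[pd.Series, ControlReference]:
    """Per-cell differentiation index and its control reference.

    index_i = (||s_i - c|| - mu) / sigma, where c is the control centroid
    in PC space and mu, sigma are the mean and sample (n-1) standard
    deviation of the control cells' own distances to c. Control indexes
    therefore have mean 0 and sd 1 by construction.
    """
    controls = [c for c in control_cells if c in pcs.scores.index]
    if len(controls) < MIN_CONTROL_CELLS:
        raise DegenerateControls(
            f"need >= {MIN_CONTROL_CELLS} control cells, got {len(controls)}"
        )
    S = pcs.scores.to_numpy(dtype=float)
    ctrl = pcs.scores.loc[controls].to_numpy(dtype=float)
    centroid = ctrl.mean(axis=0)
    ctrl_dist = np.linalg.norm(ctrl - centroid, axis=1)
    mu = float(ctrl_dist.mean())
    sigma = float(ctrl_dist.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateControls("control distances have zero variance")
    dist = np.linalg.norm(S - centroid, axis=1)
    index = pd.Series((dist - mu) / sigma, index=pcs.scores.index,
                      name="differentiation_index")
    return index, ControlReference(centroid=centroid, mu=mu, sigma=sigma)


def differentiation_index_pipeline(
    counts,
    control_cells: Sequence[str],
    exclude_genes: Iterable[str] = (),
    n_pcs: int = DEFAULT_N_PCS,
    method: str | Callable = "log1p_cp10k",
    genes: Sequence[str] | None = None,
    random_state: int = 0,
) -> tuple[pd.Series, ControlReference]:
    """normalize -> (restrict genes) -> PCA -> index, in one call."""
    norm = normalize_counts(counts, method=method)
    if genes is not None:
        keep = [g for g in genes if g in norm.columns]
        norm = norm[keep]
    pcs = fit_pca(norm, n_pcs=n_pcs, exclude_genes=exclude_genes,
                  random_state=random_state)
    return compute_differentiation_index(pcs, control_cells)


# ---------------------------------------------------------------------------
# potency testing

def test_potency(
    index: pd.Series,
    cells: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "BH",
    alternative: str = "greater",
    min_cells: int = MIN_CELLS_PER_TF,
) -> pd.DataFrame:
    """Per-TF Mann–Whitney U of single-TF cells' indexes against controls.

    ``cells`` is the label table from :func:`itfscreen.assign.classify_cells`
    (columns cell_barcode, label, tf_name). TFs with fewer than
    ``min_cells`` cells are flagged untested; adjustment (Benjamini–
    Hochberg by default, ``adjust="bonferroni"`` available) runs across the
    tested TFs, and potency means adjusted p strictly below ``alpha``.
    """
    ctrl_cells = cells.loc[cells["label"] == LABEL_CONTROL, "cell_barcode"]
    ctrl_idx = index.reindex(ctrl_cells).dropna().to_numpy()
    if ctrl_idx.size < MIN_CONTROL_CELLS:
        raise DegenerateControls("too few control cells with index values")

    single = cells[cells["label"] == LABEL_SINGLE]
    rows = []
    for tf, grp in sorted(single.groupby("tf_name")):
        vals = index.reindex(grp["cell_barcode"]).dropna().to_numpy()
        row = {"tf_name": tf, "n_cells": int(vals.size),
               "median_index": float(np.median(vals)) if vals.size else np.nan,
               "U": np.nan, "p": np.nan, "tested": vals.size >= min_cells}
        if row["tested"]:
            res = stats.mannwhitneyu(vals, ctrl_idx, alternative=alternative)
            row["U"], row["p"] = float(res.statistic), float(res.pvalue)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    out["potent"] = False
    tested = out["tested"].to_numpy()
    if tested.any():
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        _, p_adj, _, _ = multipletests(out.loc[tested, "p"], method=method)
        out.loc[tested, "p_adj"] = p_adj
        out.loc[tested, "potent"] = p_adj < alpha
    return out


test_potency.__test__ = False  # library function, not a pytest case


# ---------------------------------------------------------------------------
# gene-set restricted indexes

def filter_gene_sets(
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    exclude_genes: Iterable[str] = (),
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Intersect sets with the matrix, apply global exclusions, drop small sets.

    Returns (kept sets, dropped set -> reason). Exclusions (the induced-TF
    genes, optionally ribosomal genes) are removed from every set before
    the size check.
    """
    universe_set = set(universe)
    excl = set(exclude_genes)
    kept: dict[str, list[str]] = {}
    dropped: dict[str, str] = {}
    for name, members in gene_sets.items():
        genes = sorted((set(members) & universe_set) - excl)
        if len(genes) < min_size:
            dropped[name] = f"{len(genes)} genes after exclusions (< {min_size})"
            warnings.warn(f"gene set {name!r} dropped: {dropped[name]}",
                          SetTooSmall, stacklevel=2)
        else:
            kept[name] = genes
    return kept, dropped


@dataclass
class GeneSetIndexResult:
    per_cell: pd.DataFrame            # cells × gene sets
    medians: pd.DataFrame | None      # TFs (+control) × gene sets
    dropped: dict[str, str]


def ribosomal_genes(universe: Sequence[str],
                    prefixes: Sequence[str] = RIBOSOMAL_PREFIXES) -> list[str]:
    """Genes matching the ribosomal-protein name prefixes (default Rps/Rpl)."""
    lowered = tuple(p.lower() for p in prefixes)
    return [g for g in universe if str(g).lower().startswith(lowered)]


def geneset_indexes(
    counts,
    gene_sets: Mapping[str, Sequence[str]],
    control_cells: Sequence[str],
    cells: pd.DataFrame | None = None,
    exclude_genes: Iterable[str] = (),
    n_pcs: int = DEFAULT_N_PCS,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    method: str | Callable = "log1p_cp10k",
    random_state: int = 0,
) -> GeneSetIndexResult:
    """Differentiation index restricted to each gene set.

    Normalization is computed once on the full matrix; for each retained
    set the matrix is restricted to the set's genes and PCA plus the
    control-referenced index are re-fitted (``n_pcs`` capped per set).
    When ``cells`` labels are given, per-(TF, set) medians over single-TF
    cells (plus the control row) are tabulated.
    """
    norm = normalize_counts(counts, method=method)
    kept, dropped = filter_gene_sets(gene_sets, norm.columns,
                                     exclude_genes=exclude_genes, min_size=min_size)
    per_cell = {}
    for name, genes in kept.items():
        pcs = fit_pca(norm[genes], n_pcs=min(n_pcs, len(genes)),
                      random_state=random_state)
        idx, _ = compute_differentiation_index(pcs, control_cells)
        per_cell[name] = idx
    per_cell_df = pd.DataFrame(per_cell)

    medians = None
    if cells is not None and not per_cell_df.empty:
        groups: dict[str, pd.Index] = {
            tf: grp["cell_barcode"]
            for tf, grp in cells[cells["label"] == LABEL_SINGLE].groupby("tf_name")
        }
        groups[LABEL_CONTROL] = cells.loc[cells["label"] == LABEL_CONTROL,
                                          "cell_barcode"]
        medians = pd.DataFrame(
            {
                name: {
                    g: float(per_cell_df[name].reindex(cbs).dropna().median())
                    for g, cbs in groups.items()
                }
                for name in per_cell_df.columns
            }
        )
        medians.index.name = "tf_name"
    return GeneSetIndexResult(per_cell=per_cell_df, medians=medians, dropped=dropped)


# ---------------------------------------------------------------------------
# percentile ranks and similarity

def percentile_ranks(medians: pd.Series) -> pd.Series:
    """Percentile rank of each TF's median among all TFs, on a 0–100 scale.

    rank = 100 * (#strictly smaller + 0.5 * #ties excluding self) / (n - 1),
    so the maximum scores 100, the minimum 0, and an all-tied vector 50.
    """
    v = medians.to_numpy(dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need >= 2 values for percentile ranks")
    smaller = (v[:, None] > v[None, :]).sum(axis=1)
    ties = (v[:, None] == v[None, :]).sum(axis=1) - 1
    return pd.Series(100.0 * (smaller + 0.5 * ties) / (n - 1),
                     index=medians.index, name="percentile_rank")


def tf_similarity(
    median_matrix: pd.DataFrame,
    method: str = "pearson",
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[str]]:
    """TF × TF similarity from per-gene-set median indexes.

    Similarity is the correlation (Pearson by default, ``method=
    "spearman"`` available) between two TFs' median-index vectors across
    gene sets; rows with zero variance are dropped with a warning. Returns
    the symmetric unit-diagonal matrix and the leaf order of average-
    linkage hierarchical clustering on distance 1 - similarity.
    """
    M = median_matrix.astype(float)
    if M.shape[1] < 2:
        raise ValueError("need >= 2 gene sets per TF row")
    variable = M.std(axis=1) > 0
    if (~variable).any():
        warnings.warn(
            f"dropping zero-variance rows: {list(M.index[~variable])}",
            ZeroVarianceRow, stacklevel=2,
        )
        M = M.loc[variable]
    if M.shape[0] < 2:
        raise ValueError("fewer than 2 TFs with variable median vectors")
    if method == "spearman":
        M = M.rank(axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown similarity method {method!r}")
    sim = pd.DataFrame(np.corrcoef(M.to_numpy()), index=M.index, columns=M.index)
    np.fill_diagonal(sim.values, 1.0)
    dist = np.clip(1.0 - sim.to_numpy(), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [sim.index[i] for i in hierarchy.leaves_list(Z)]
    return sim, order
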