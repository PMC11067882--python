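"""Per-cell iTF calls from UMI counts: threshold sweep, labels, cell QC.

Each cell line carries one induced TF, so a cell should show UMIs for a
single construct; extra low-UMI assignments arise from ambient RNA and
library artifacts. Sweeping a minimum-UMI threshold and keeping the value
that maximizes the number of single-TF cells separates true inductions
(many UMIs) from contamination (1–2 UMIs). Control cells are cells with
zero iTF UMIs at any level — evidence below threshold disqualifies a cell
from both the perturbed and the control set ("unassigned").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABEL_SINGLE = "single"
LABEL_MULTI = "multi"
LABEL_CONTROL = "control"
LABEL_UNASSIGNED = "unassigned"

DEFAULT_THRESHOLDS = range(1, 6)
#: mouse mitochondrial gene-name prefix
DEFAULT_MITO_PREFIX = "mt-"


class EmptyTable(ValueError):
    """UMI count table has no cells."""


class UnknownMitoGenes(UserWarning):
    """The mitochondrial gene set matched nothing in the matrix."""


@dataclass(frozen=True)
class QcCriteria:
    """Cell quality-control cutoffs; all inequalities are strict."""

    min_genes: int = 1000
    max_mito_fraction: float = 0.10
    min_molecules: int = 10000

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_molecules) <= 0 or self.max_mito_fraction <= 0:
            raise ValueError("QC criteria must be positive")


def sweep_umi_thresholds(
    table: pd.DataFrame,
    thresholds: Iterable[int] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Count single/multi/zero-TF cells at each minimum-UMI threshold.

    ``table`` is cells × TFs of UMI counts. At threshold t a cell is
    "single" if exactly one TF has count >= t, "multi" if two or more do,
    and "zero" otherwise. Returns a DataFrame with columns
    threshold, n_single, n_multi, n_zero.
    """
    if table.shape[0] == 0:
        raise EmptyTable("UMI count table has no cells")
    counts = table.to_numpy()
    rows = []
    for t in thresholds:
        n_at = (counts >= t).sum(axis=1)
        rows.append(
            {
                "threshold": int(t),
                "n_single": int((n_at == 1).sum()),
                "n_multi": int((n_at >= 2).sum()),
                "n_zero": int((n_at == 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def select_threshold(sweep: pd.DataFrame) -> int:
    """Threshold maximizing the single-TF cell count; ties go to the smallest."""
    s = sweep.sort_values("threshold")
    best = s.loc[s["n_single"].idxmax()]
    return int(best["threshold"])


def classify_cells(
    table: pd.DataFrame,
    threshold: int,
    all_barcodes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Label every cell single/multi/control/unassigned at one threshold.

    Controls must have zero UMIs for every construct; barcodes listed in
    ``all_barcodes`` but absent from the table are controls by definition.
    Returns a DataFrame with columns cell_barcode, label, tf_name.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rows = []
    if table.shape[0]:
        counts = table.to_numpy()
        tf_names = np.asarray(table.columns)
        n_at = (counts >= threshold).sum(axis=1)
        any_umi = (counts > 0).sum(axis=1)
        for i, cb in enumerate(table.index):
            if n_at[i] == 1:
                tf = tf_names[counts[i] >= threshold][0]
                rows.append((cb, LABEL_SINGLE, tf))
            elif n_at[i] >= 2:
                rows.append((cb, LABEL_MULTI, ""))
            elif any_umi[i] == 0:
                rows.append((cb, LABEL_CONTROL, ""))
            else:
                rows.append((cb, LABEL_UNASSIGNED, ""))
    if all_barcodes is not None:
        known = set(table.index)
        rows.extend((cb, LABEL_CONTROL, "") for cb in all_barcodes if cb not in known)
    df = pd.DataFrame(rows, columns=["cell_barcode", "label", "tf_name"])
    return df.sort_values("cell_barcode", ignore_index=True)


def qc_filter_cells(
    counts: pd.DataFrame,
    criteria: QcCriteria = QcCriteria(),
    mito_genes: Sequence[str] | None = None,
) -> tuple[pd.Series, dict]:
    """Pass/fail each cell of a cells × genes raw count matrix.

    A cell passes iff it has strictly more than ``min_genes`` detected
    genes, strictly less than ``max_mito_fraction`` of its counts in
    mitochondrial genes, and strictly more than ``min_molecules`` total
    counts. Mitochondrial genes default to the "mt-" name-prefix
    convention; pass an explicit list to override.
    """
    X = counts.to_numpy()
    if mito_genes is None:
        mito_mask = counts.columns.str.lower().str.startswith(DEFAULT_MITO_PREFIX)
    else:
        mito_mask = counts.columns.isin(set(mito_genes))
    if not mito_mask.any():
        warnings.warn("no mitochondrial genes found in matrix; mito fraction is 0",
                      UnknownMitoGenes, stacklevel=2)

    total = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_mask].sum(axis=1) / np.maximum(total, 1), 0.0)

    qc_pass = (
        (n_genes > criteria.min_genes)
        & (mito_frac < criteria.max_mito_fraction)
        & (total > criteria.min_molecules)
    )
    out = pd.Series(qc_pass, index=counts.index, name="qc_pass")
    summary = {
        "n_cells": int(len(out)),
        "n_pass": int(qc_pass.sum()),
        "pass_fraction": float(qc_pass.mean()) if len(out) else float("nan"),
        "criteria": {
            "min_genes": criteria.min_genes,
            "max_mito_fraction": criteria.max_mito_fraction,
            "min_molecules": criteria.min_molecules,
        },
    }
    return out, summary


def assignment_summary(cells: pd.DataFrame, qc_pass: pd.Series | None = None) -> dict:
    """Single-TF proportions over all cells and, when QC is supplied, over QC-passing cells."""
    n = len(cells)
    single = cells["label"] == LABEL_SINGLE
    summary = {
        "n_cells": int(n),
        "n_single": int(single.sum()),
        "single_fraction_all_cells": float(single.mean()) if n else float("nan"),
        "n_tfs_detected": int(cells.loc[single, "tf_name"].nunique()),
    }
    if qc_pass is not None:
        passing = cells["cell_barcode"].map(qc_pass).fillna(False).astype(bool)
        n_pass = int(passing.sum())
        summary["n_qc_pass"] = n_pass
        summary["single_fraction_qc_pass"] = (
            float((single & passing).sum() / n_pass) if n_pass else float("nan")
        )
    return summary
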