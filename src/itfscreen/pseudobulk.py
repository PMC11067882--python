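"""Pseudobulk profiles, marker panels, and moving-window smoothing.

Pseudobulk expression is the arithmetic mean of log-normalized values over
a group's cells — one column per single-TF group plus the control group.
Groups with fewer than three cells are kept but flagged ``low_n`` (the
cutoff under which downstream differential testing is unreliable).

The moving-window average relates a gene ordering (e.g. genes ranked by
relative expression change) to a noisy per-gene score (e.g. promoter/
enhancer binding peak scores) by smoothing the score series along the
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import LABEL_CONTROL, LABEL_SINGLE

DEFAULT_WINDOW = 100
DEFAULT_STEP = 1
LOW_N_CUTOFF = 3


class SeriesTooShort(ValueError):
    """Series shorter than the smoothing window."""


class MissingGene(UserWarning):
    """Marker panel genes absent from the matrix."""


@dataclass
class PseudobulkResult:
    means: pd.DataFrame   # genes × groups
    n_cells: pd.Series    # per group
    low_n: pd.Series      # per group, True when n_cells < 3


def pseudobulk_means(norm: pd.DataFrame, cells: pd.DataFrame) -> PseudobulkResult:
    """Per-group mean expression from a cells × genes normalized matrix.

    ``cells`` is the label table (cell_barcode, label, tf_name); one group
    per single-TF label plus the control group.
    """
    groups: dict[str, pd.Index] = {}
    single = cells[cells["label"] == LABEL_SINGLE]
    for tf, grp in single.groupby("tf_name"):
        groups[tf] = grp["cell_barcode"]
    ctrl = cells.loc[cells["label"] == LABEL_CONTROL, "cell_barcode"]
    if len(ctrl):
        groups[LABEL_CONTROL] = ctrl

    means, counts = {}, {}
    for name, cbs in groups.items():
        member = norm.reindex(cbs.astype(str)).dropna(how="all")
        if member.empty:
            continue
        means[name] = member.mean(axis=0)
        counts[name] = len(member)
    if not means:
        raise ValueError("no group has any cells in the matrix")
    means_df = pd.DataFrame(means)
    n_cells = pd.Series(counts, name="n_cells")
    return PseudobulkResult(means=means_df, n_cells=n_cells,
                            low_n=(n_cells < LOW_N_CUTOFF).rename("low_n"))


def marker_report(
    pb: PseudobulkResult,
    panel: list[str],
    reference_group: str = LABEL_CONTROL,
    mode: str = "ratio",
) -> tuple[pd.DataFrame, list[str]]:
    """Relative expression of a marker panel in each group vs the reference.

    ``mode="ratio"`` de-logs the pseudobulk means (expm1) and divides by
    the reference group, so the reference column is exactly 1; ``mode=
    "log_diff"`` subtracts in log space (reference column 0). Panel genes
    missing from the matrix are returned separately and warned about.
    """
    import warnings

    present = [g for g in panel if g in pb.means.index]
    missing = [g for g in panel if g not in pb.means.index]
    if missing:
        warnings.warn(f"marker genes missing from matrix: {missing}",
                      MissingGene, stacklevel=2)
    if reference_group not in pb.means.columns:
        raise KeyError(f"reference group {reference_group!r} not in pseudobulk")
    sub = pb.means.loc[present]
    if mode == "ratio":
        lin = np.expm1(sub)
        ref = lin[reference_group]
        rel = lin.div(ref.where(ref != 0, np.nan), axis=0)
    elif mode == "log_diff":
        rel = sub.sub(sub[reference_group], axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rel.attrs["mode"] = mode
    return rel, missing


def moving_window_average(
    values,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> np.ndarray:
    """Mean of each full length-``window`` slice of the series, at stride ``step``.

    output[i] = mean(values[i*step : i*step + window]); output length is
    floor((n - window) / step) + 1. window=1, step=1 is the identity.
    """
    v = np.asarray(values, dtype=float)
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if v.size < window:
        raise SeriesTooShort(f"series of length {v.size} < window {window}")
    sliding = np.lib.stride_tricks.sliding_window_view(v, window)
    return sliding.mean(axis=1)[::step]


def smoothed_score_profile(
    scores,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    randomize: bool = False,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Moving-window average of a per-gene score series along a gene ordering.

    With ``randomize=True`` the scores are permuted across genes first
    (seeded via ``rng``), giving the null profile against which the
    observed ordering/score association is compared.
    """
    v = np.asarray(scores, dtype=float)
    if randomize:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        v = gen.permutation(v)
    return moving_window_average(v, window=window, step=step)
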