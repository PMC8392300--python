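"""Small assay computations: relative qPCR quantification, survival fractions,
and intensity thresholding for marker co-expression counts.

These operate on already-extracted tabular values (Ct tables, cell counts,
per-cell intensities); image segmentation is upstream and out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_COLUMNS = ("sample", "condition", "gene", "ct")


@dataclass
class DdctResult:
    """Relative expression by the 2^-ddCt method.

    ``fold`` uses the mean dCt per condition (the common convention);
    ``per_sample_folds`` are the treated samples' folds against the control
    mean dCt, so either dispersion convention can be reported.
    """

    fold: float
    ddct: float
    per_sample_folds: np.ndarray
    dct_treated: np.ndarray
    dct_control: np.ndarray


def _mean_dct(df: pd.DataFrame, target: str, reference: str, condition: str) -> np.ndarray:
    sub = df[df["condition"] == condition]
    if sub.empty:
        raise KeyError(f"condition {condition!r} not present in the Ct table")
    dcts = []
    for sample, grp in sub.groupby("sample"):
        genes = grp.set_index("gene")["ct"]
        for gene in (target, reference):
            if gene not in genes.index:
                raise KeyError(f"gene {gene!r} missing for sample {sample!r}")
        dcts.append(float(genes[target] - genes[reference]))
    return np.asarray(dcts)


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    treated: str,
    control: str,
) -> DdctResult:
    """Fold change of ``target`` (vs ``reference`` gene) in ``treated`` vs
    ``control`` condition: ``2**-(mean dCt_treated - mean dCt_control)``.

    The table is long-format with columns ``sample, condition, gene, ct``.
    """
    if target == reference:
        raise ValueError("target and reference genes must differ")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    dct_t = _mean_dct(table, target, reference, treated)
    dct_c = _mean_dct(table, target, reference, control)
    ddct = float(dct_t.mean() - dct_c.mean())
    return DdctResult(
        fold=float(2.0 ** (-ddct)),
        ddct=ddct,
        per_sample_folds=2.0 ** (-(dct_t - dct_c.mean())),
        dct_treated=dct_t,
        dct_control=dct_c,
    )


def survival_fraction(n_egfp: int, n_alive: int) -> float:
    """Percent of induced (EGFP+) cells surviving: ``100 * n_alive / n_egfp``."""
    if n_egfp <= 0:
        raise ValueError("n_egfp must be positive")
    if n_alive < 0:
        raise ValueError("n_alive must be non-negative")
    return 100.0 * n_alive / n_egfp


def background_threshold(
    signal: np.ndarray, bg_samples
) -> tuple[np.ndarray, np.ndarray, float]:
    """Background-subtract an intensity array at mean(bg) + 2 SD(bg).

    ``bg_samples`` are background intensity sets (typically three independent
    image locations), pooled for the cutoff.  Returns the clipped
    (non-negative) signal, the positivity mask ``signal > cutoff``, and the
    cutoff itself.
    """
    signal = np.asarray(signal, dtype=float)
    bg = np.concatenate([np.atleast_1d(np.asarray(b, dtype=float)).ravel() for b in bg_samples])
    if bg.size < 2:
        raise ValueError("need at least two background values")
    cutoff = float(bg.mean() + 2.0 * bg.std())
    out = np.maximum(signal - cutoff, 0.0)
    return out, signal > cutoff, cutoff


def coexpression_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Percent of a-positive cells that are also b-positive."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have the same length")
    n_a = int(mask_a.sum())
    if n_a == 0:
        raise ValueError("no a-positive cells; fraction undefined")
    return 100.0 * int((mask_a & mask_b).sum()) / n_a
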