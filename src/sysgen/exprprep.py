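"""Two-colour array preprocessing into the e-trait expression matrix.

Workflow: per-array lowess normalization of M = log2(R/G) on A,
between-array quantile normalization, probe filtering against a background
intensity floor, flooring + log2, replicate averaging, and parental
differential expression (pooled-variance t with Benjamini-Hochberg control
and a fold-change gate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoColourArray",
    "ExpressionMatrix",
    "lowess_ma_normalize",
    "quantile_normalize",
    "filter_and_floor",
    "average_replicates",
    "differential_expression",
]


@dataclass
class TwoColourArray:
    """One two-colour hybridization: red/green intensities per probe."""

    probes: list
    red: np.ndarray
    green: np.ndarray
    array_id: str = ""
    dye_swap: bool = False

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        for channel, name in ((self.red, "R"), (self.green, "G")):
            bad = np.where(~(np.isfinite(channel) & (channel > 0)))[0]
            if bad.size:
                raise ValueError(
                    f"non-positive {name} intensity at probe {self.probes[bad[0]]!r}")


@dataclass
class ExpressionMatrix:
    """Transcripts x lines of log2 expression, plus optional gene positions.

    ``positions`` maps transcript -> (chrom, bp midpoint); transcripts with
    no known position stay absent and are treated as unplaced downstream.
    """

    values: pd.DataFrame                       # index transcripts, columns lines
    positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "bp"]))

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        if len(self.values) and self.values.isna().all(axis=1).any():
            raise ValueError("all-missing transcript row")

    @property
    def transcripts(self) -> list:
        return list(self.values.index)

    @property
    def lines(self) -> list:
        return list(self.values.columns)

    def position_of(self, transcript) -> tuple | None:
        if transcript in self.positions.index:
            row = self.positions.loc[transcript]
            return row["chrom"], int(row["bp"])
        return None


def lowess_ma_normalize(array: TwoColourArray, span: float = 0.3) -> pd.Series:
    """Within-array lowess normalization on the MA plane.

    M = log2(R/G), A = (log2 R + log2 G)/2; the lowess trend M-hat(A) is
    subtracted so intensity-dependent dye bias is removed. Dye-swap arrays
    are sign-flipped so M always means (sample / reference).
    """
    if len(array.probes) < 50:
        raise ValueError("need >= 50 probes for lowess normalization")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    m = np.log2(array.red / array.green)
    a = 0.5 * (np.log2(array.red) + np.log2(array.green))
    fit = sm_lowess(m, a, frac=span, return_sorted=False)
    m_norm = m - fit
    if array.dye_swap:
        m_norm = -m_norm
    return pd.Series(m_norm, index=array.probes, name=array.array_id or "M")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical distributions across columns (arrays/lines).

    Every column's sorted values are replaced by the across-column mean of
    the order statistics; ties within a column receive the mean of their
    target values, preserving within-column ranks.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns to quantile-normalize")
    if np.any(X < 0):
        raise ValueError("negative intensities not allowed")
    order = np.argsort(X, axis=0, kind="stable")
    ranksorted = np.take_along_axis(X, order, axis=0)
    target = ranksorted.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ord_j = order[:, j]
        xs = X[ord_j, j]
        # tied input values share the mean target over their rank run
        _, inverse, counts = np.unique(xs, return_inverse=True, return_counts=True)
        group_mean = np.bincount(inverse, weights=target) / counts
        out[ord_j, j] = group_mean[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_and_floor(matrix: pd.DataFrame, intensity_floor: float = 20.0,
                     min_frequency: float = 0.30) -> tuple[ExpressionMatrix, int]:
    """Probe filter + background floor + log2, on linear-scale intensities.

    A probe is kept iff the fraction of samples with intensity above the
    floor is at least ``min_frequency`` (probes rarely above background carry
    no usable signal). Surviving values below the floor are clamped up to it,
    then everything is log2-transformed. Returns (matrix, n_removed).
    """
    X = matrix.to_numpy(dtype=float)
    above = (X > intensity_floor)
    frac = np.nanmean(np.where(np.isnan(X), np.nan, above), axis=1)
    keep = frac >= min_frequency
    n_removed = int((~keep).sum())
    kept = matrix.loc[keep]
    floored = kept.clip(lower=intensity_floor)
    return ExpressionMatrix(np.log2(floored)), n_removed


def average_replicates(matrix: pd.DataFrame, replicate_map: dict) -> pd.DataFrame:
    """Average replicate columns per line on the log2 scale.

    ``replicate_map``: line id -> list of column names. Missing replicate
    values are ignored in the mean; a line with no columns is an error.
    """
    out = {}
    for line, cols in replicate_map.items():
        if not cols:
            raise ValueError(f"line {line!r} has zero replicate columns")
        out[line] = matrix[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(group_a: pd.DataFrame, group_b: pd.DataFrame,
                            fdr: float = 0.05, fc_cut: float = 2.0) -> pd.DataFrame:
    """Parental differential expression on log2 values.

    Pooled-variance (Student) two-sample t per transcript, Benjamini-Hochberg
    adjusted p, geometric fold change 2^|meanA - meanB| signed toward the
    higher group. Significant iff adjusted p < ``fdr`` and FC >= ``fc_cut``.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    if not group_a.index.equals(group_b.index):
        group_b = group_b.reindex(group_a.index)
    A = group_a.to_numpy(dtype=float)
    B = group_b.to_numpy(dtype=float)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    # both groups constant with equal means -> 0/0; convention p = 1
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p_adj = _bh_adjust(p)
    diff = A.mean(axis=1) - B.mean(axis=1)
    fc = np.sign(diff) * 2.0 ** np.abs(diff)
    fc[diff == 0] = 1.0
    flag = (p_adj < fdr) & (np.abs(fc) >= fc_cut)
    return pd.DataFrame({
        "t": t, "p": p, "p_adj": p_adj, "fc": fc, "flag": flag,
    }, index=group_a.index)
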