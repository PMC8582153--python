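"""Clinical-specimen support: correlation screen and subtype dichotomization.

Two readouts on a log-scale clinical expression matrix with subtype labels:

* a Pearson correlation screen of every gene against the factor's own
  expression row (two-sided t test on ``r``, keep p < alpha, signed), and
* the median-dichotomization contingency analysis: samples are split into
  high/low factor expressors at the median and tested for association with
  the GCB/ABC subtype by Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Log-scale expression (genes x samples) with per-sample subtype labels.

    Rows containing missing values are dropped at load with a warning
    (imputation is out of scope).  ``subtypes`` values are GCB, ABC or other.
    """

    values: pd.DataFrame
    subtypes: pd.Series

    def __post_init__(self) -> None:
        self.subtypes = self.subtypes.loc[self.values.columns]
        na_rows = self.values.isna().any(axis=1)
        if na_rows.any():
            warnings.warn(f"dropping {int(na_rows.sum())} gene rows with missing values")
            self.values = self.values.loc[~na_rows]

    @classmethod
    def from_tsv(cls, expr_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples["subtype"])

    def subset(self, subtype: str) -> "ExpressionMatrix":
        keep = self.subtypes[self.subtypes == subtype].index
        return ExpressionMatrix(self.values[keep], self.subtypes.loc[keep])


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    r: float
    p: float

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray  # rows: high/low TF, cols: GCB/ABC
    odds_ratio: float
    p: float


def correlation_screen(
    matrix: ExpressionMatrix,
    tf_gene: str,
    alpha: float = 0.01,
    *,
    subtype: str | None = None,
) -> list[CorrelationResult]:
    """Genes significantly correlated with the factor's expression.

    Pearson ``r`` of each gene row against the factor row; two-sided p from
    ``t = r * sqrt((n-2)/(1-r**2))`` on ``n-2`` df.  The factor row itself is
    excluded, zero-variance genes are skipped with a warning, and only genes
    with ``p < alpha`` are returned.  ``subtype`` restricts the screen to
    samples of one subtype (the screen is typically run within GCB cases).
    """
    if subtype is not None:
        matrix = matrix.subset(subtype)
    if tf_gene not in matrix.values.index:
        raise KeyError(f"factor gene {tf_gene!r} absent from expression matrix")
    X = matrix.values
    n = X.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples, have {n}")
    tf = X.loc[tf_gene].to_numpy(dtype=float)
    others = X.drop(index=tf_gene)
    Y = others.to_numpy(dtype=float)
    tf_c = tf - tf.mean()
    Y_c = Y - Y.mean(axis=1, keepdims=True)
    tf_ss = float(tf_c @ tf_c)
    if tf_ss == 0:
        raise ValueError(f"factor gene {tf_gene!r} has zero variance")
    y_ss = (Y_c**2).sum(axis=1)
    zero_var = y_ss == 0
    if zero_var.any():
        warnings.warn(f"skipping {int(zero_var.sum())} zero-variance gene(s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y_c @ tf_c) / np.sqrt(y_ss * tf_ss)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = [
        CorrelationResult(gene_id=g, r=float(ri), p=float(pi))
        for g, ri, pi, zv in zip(others.index, r, p, zero_var)
        if not zv and pi < alpha
    ]
    return out


def dichotomize_and_test(
    matrix: ExpressionMatrix,
    tf_gene: str,
    subtypes: Sequence[str] = ("GCB", "ABC"),
) -> ContingencyResult:
    """Median split of factor expression vs subtype, Fisher exact test.

    High = expression strictly above the median over all included samples;
    ties at the median go to low.  The 2x2 table is high/low x subtype and
    is tested two-sided by Fisher's exact test; the odds ratio uses a
    Haldane 0.5 correction when any cell is zero.
    """
    keep = matrix.subtypes.isin(subtypes)
    if not keep.any():
        raise ValueError("no samples with the requested subtypes")
    vals = matrix.values.loc[tf_gene, keep.index[keep]]
    labels = matrix.subtypes[keep]
    for s in subtypes:
        if (labels == s).sum() == 0:
            raise ValueError(f"subtype group {s!r} is empty")
    if vals.nunique() == 1:
        raise ValueError("all samples have identical expression; median split undefined")
    median = float(vals.median())
    high = vals > median
    table = np.array(
        [
            [(high & (labels == s)).sum() for s in subtypes],
            [(~high & (labels == s)).sum() for s in subtypes],
        ],
        dtype=int,
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return ContingencyResult(table=table, odds_ratio=odds, p=float(p))


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in results],
            "r": [c.r for c in results],
            "p": [c.p for c in results],
            "sign": [c.sign for c in results],
        }
    ).set_index("gene_id")
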