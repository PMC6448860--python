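"""Expression-based validation: differential expression and catalog overlap.

Mirrors the classical two-group microarray check: a per-gene Welch t-test
between case and control samples combined with a fold-change filter
(P < 0.05 and FC >= 2 or <= 1/2 by default), followed by an upper-tail
hypergeometric test of whether the differentially expressed genes overlap
the disease risk-gene catalog more than chance.

Intensities are treated as log2 by default (the beadchip convention);
``scale`` is always explicit, never guessed.  For log2 data the linear
fold change is 2^(mean difference); for linear data the ratio of group
means.  No multiple-testing correction is applied to the per-gene
p-values — the contract thresholds raw P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import HypergeomInputs, hypergeometric_enrichment_p
from .errors import EmptyInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "differential_expression",
    "overlap_significance",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples measurement matrix with an explicit scale."""

    values: pd.DataFrame  # index: genes, columns: samples
    scale: str = "log2"   # "log2" or "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise InputError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise InputError("expression matrix contains missing values")

    @classmethod
    def read_tsv(cls, path, scale: str = "log2") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, scale=scale)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class DERecord:
    """One gene's two-group test: Welch t, raw p, linear fold change."""

    gene: str
    t_stat: float
    p: float
    fc: float
    significant: bool
    p_defined: bool = True


def differential_expression(
    expr: ExpressionMatrix,
    groups: dict[str, str],
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    equal_var: bool = False,
) -> list[DERecord]:
    """Per-gene Welch t-test plus two-sided fold-change filter.

    ``groups`` maps every sample column to ``"case"`` or ``"control"``;
    both groups need >= 2 samples.  A gene is significant iff
    p < ``p_threshold`` and fc >= ``fc_threshold`` or <= 1/``fc_threshold``.
    Genes with zero variance in both groups get an undefined p and are
    flagged non-significant.  ``equal_var=True`` switches to the pooled
    (Student) t-test.
    """
    missing = set(expr.values.columns) - set(groups)
    if missing:
        raise InputError(f"samples without a group label: {sorted(missing)[:5]}")
    case_cols = [s for s in expr.values.columns if groups[s] == "case"]
    ctrl_cols = [s for s in expr.values.columns if groups[s] == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InputError("each group needs at least 2 samples")

    case = expr.values[case_cols].to_numpy(dtype=float)
    ctrl = expr.values[ctrl_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    if expr.scale == "log2":
        fc = 2.0 ** (case.mean(axis=1) - ctrl.mean(axis=1))
    else:
        if np.any(case.mean(axis=1) <= 0) or np.any(ctrl.mean(axis=1) <= 0):
            raise InputError("linear-scale fold change requires positive group means")
        fc = case.mean(axis=1) / ctrl.mean(axis=1)

    records = []
    for gene, t, p, f in zip(expr.values.index, t_stat, pvals, fc):
        defined = bool(np.isfinite(p))
        passes_fc = f >= fc_threshold or f <= 1.0 / fc_threshold
        sig = defined and p < p_threshold and passes_fc
        records.append(
            DERecord(
                gene=str(gene),
                t_stat=float(t) if np.isfinite(t) else float("nan"),
                p=float(p) if defined else float("nan"),
                fc=float(f),
                significant=sig,
                p_defined=defined,
            )
        )
    n_undef = sum(1 for r in records if not r.p_defined)
    if n_undef:
        logger.warning("%d genes had undefined t-test p (zero variance)", n_undef)
    return records


def overlap_significance(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test of two gene sets."""
    if not universe:
        raise EmptyInputError("empty universe")
    a = set_a & universe
    b = set_b & universe
    x = len(a & b)
    p = hypergeometric_enrichment_p(
        HypergeomInputs(x=x, M=len(universe), K=len(a), N=len(b))
    )
    return x, p
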