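"""Per-miRNA paired t-tests with FDR adjustment (criteria 1 and 2).

For each miRNA the per-patient log2 differences d_i = scar_i - normal_i
give t = mean(d) / (sd(d) / sqrt(n)) with the (n-1)-denominator sample
SD, two-sided p from Student's t on n-1 degrees of freedom, and a
q-value from the Benjamini-Hochberg step-up procedure (or Storey's
pi0-estimated variant). Fold change is reported on the anti-logged
scale 2^mean(d).

Degenerate rows (zero variance of differences) are retained, not
dropped, so the multiple-testing denominator stays well defined:
sd = 0 and mean = 0 gives (t=0, p=1); sd = 0 and mean != 0 gives
(t = +/-inf, p=0) and a logged flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import paired_arrays

logger = logging.getLogger(__name__)


def paired_t_test(scar, normal):
    """Paired two-sided t-test on aligned vectors.

    Returns ``(t_stat, df, p_value)``. Vectors must share length n >= 2
    and be aligned by patient.
    """
    scar = np.asarray(scar, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if scar.shape != normal.shape:
        raise InputError("scar and normal vectors differ in length")
    n = scar.size
    if n < 2:
        raise InputError("paired t-test needs at least 2 pairs")
    t, p = _t_from_diffs((scar - normal)[None, :])
    return float(t[0]), n - 1, float(p[0])


def _t_from_diffs(diffs: np.ndarray):
    """Vectorized paired t over rows of a (features x pairs) matrix."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    t = np.empty_like(mean)
    nonzero_sd = sd > 0
    t[nonzero_sd] = mean[nonzero_sd] / (sd[nonzero_sd] / np.sqrt(n))
    degenerate = ~nonzero_sd
    t[degenerate & (mean == 0)] = 0.0
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    n_flagged = int((degenerate & (mean != 0)).sum())
    if n_flagged:
        logger.warning("%d rows with zero variance and nonzero mean "
                       "difference: p set to 0", n_flagged)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    return t, np.minimum(p, 1.0)


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator."""
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m))
    if pi0 <= 0:
        pi0 = 1.0 / m  # all p below lambda; keep the estimate positive
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust(p_values, method: str = "bh"):
    """FDR-adjusted q-values for a vector of p-values in [0, 1].

    ``method="bh"`` gives Benjamini-Hochberg step-up adjusted p-values
    (q_(i) = min_{j>=i} m p_(j) / j, capped at 1); ``method="storey"``
    multiplies them by the pi0 estimate from the lambda = 0.5 rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be a 1-D vector")
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise InputError(f"unknown FDR method: {method!r}")


class PairedDifferential:
    """Paired differential-expression model for a normalized matrix.

    Parameters
    ----------
    matrix : DataFrame
        log2-scale expression, miRNAs x arrays.
    samples : DataFrame
        Sample sheet (``array_id, patient_id, condition``) defining a
        complete paired design covering all matrix columns.

    ``fit()`` returns a :class:`PairedDifferentialResults`.
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame):
        self.matrix = matrix
        self.samples = samples
        self.pairs = paired_arrays(samples, columns=matrix.columns)
        if len(self.pairs) < 2:
            raise InputError("paired analysis needs at least 2 patients")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def fit(self, fdr_method: str = "bh") -> "PairedDifferentialResults":
        scar = self.matrix[self.pairs["scar"]].to_numpy(dtype=float)
        normal = self.matrix[self.pairs["normal"]].to_numpy(dtype=float)
        diffs = scar - normal
        t, p = _t_from_diffs(diffs)
        q = fdr_adjust(p, method=fdr_method)
        mean_diff = diffs.mean(axis=1)
        direction = np.where(mean_diff > 0, "elevated",
                             np.where(mean_diff < 0, "lowered", "unchanged"))
        table = pd.DataFrame({
            "mirna_id": self.matrix.index,
            "mean_log2_diff": mean_diff,
            "fold_change": np.exp2(mean_diff),
            "direction": direction,
            "t": t,
            "df": self.n_pairs - 1,
            "p": p,
            "q": q,
        }).sort_values(["p", "mirna_id"], kind="stable").reset_index(drop=True)
        return PairedDifferentialResults(table, n_pairs=self.n_pairs,
                                         fdr_method=fdr_method)


class PairedDifferentialResults:
    """Per-miRNA estimates, p/q-values and directions, sorted by p."""

    def __init__(self, table: pd.DataFrame, n_pairs: int, fdr_method: str):
        self.table = table
        self.n_pairs = n_pairs
        self.fdr_method = fdr_method

    def significant(self, alpha: float = 0.05) -> set:
        """Criterion-1 set: miRNAs with p <= alpha."""
        return set(self.table.loc[self.table["p"] <= alpha, "mirna_id"])

    def fdr_significant(self, alpha: float = 0.05) -> set:
        """Criterion-2 set: miRNAs with q <= alpha."""
        return set(self.table.loc[self.table["q"] <= alpha, "mirna_id"])

    def summary(self, alpha: float = 0.05) -> str:
        m = len(self.table)
        n_p = len(self.significant(alpha))
        n_q = len(self.fdr_significant(alpha))
        lines = [
            "Paired differential expression",
            "==============================",
            f"miRNAs tested:        {m}",
            f"patient pairs:        {self.n_pairs}",
            f"FDR method:           {self.fdr_method}",
            f"p <= {alpha:g} (criterion 1): {n_p}",
            f"q <= {alpha:g} (criterion 2): {n_q}",
            "",
            "Top rows by p-value:",
            self.table.head(10).to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PairedDifferentialResults":
        table = pd.read_csv(path, sep="\t")
        n_pairs = int(table["df"].iloc[0]) + 1 if len(table) else 0
        return cls(table, n_pairs=n_pairs, fdr_method="bh")


def differential_table(matrix: pd.DataFrame, samples: pd.DataFrame,
                       fdr_method: str = "bh") -> pd.DataFrame:
    """One-call version: fit the paired model, return the result table."""
    return PairedDifferential(matrix, samples).fit(fdr_method).table
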