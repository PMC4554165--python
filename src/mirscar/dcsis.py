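"""Distance-correlation sure independence screening (DC-SIS, criterion 3).

Each miRNA is ranked by the squared distance correlation between its
expression vector across arrays and the binary scar/normal indicator;
the top d = multiplier * floor(n / log n) miRNAs are retained. Distance
correlation is model-free: it is zero iff the two variables are
independent, so the screen makes no linearity assumption about how
expression relates to condition.

The estimator is the V-statistic (biased) form from double-centred
pairwise distance matrices: with a_kl = |x_k - x_l| and

    A_kl = a_kl - abar_k. - abar_.l + abar_..

(and B likewise from y), dCov^2(x, y) = (1/m^2) sum_kl A_kl B_kl and
dCor^2 = dCov^2(x,y) / sqrt(dCov^2(x,x) dCov^2(y,y)), defined as 0 when
either factor vanishes (constant input). Tiny negative rounding
residues are clamped at 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import InputError
from .io import paired_arrays

logger = logging.getLogger(__name__)


def _double_centered(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_covariance_sq(x, y) -> float:
    """Squared distance covariance (V-statistic) of two 1-D samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    m = x.size
    if m < 2:
        raise InputError("distance covariance needs at least 2 observations")
    value = float((_double_centered(x) * _double_centered(y)).sum()) / (m * m)
    return max(value, 0.0)


def distance_correlation_sq(x, y) -> float:
    """Squared distance correlation in [0, 1]; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    m = x.size
    if m < 2:
        raise InputError("distance correlation needs at least 2 observations")
    a = _double_centered(x)
    b = _double_centered(y)
    vx = float((a * a).sum())
    vy = float((b * b).sum())
    if vx <= 0.0 or vy <= 0.0:
        return 0.0
    value = float((a * b).sum()) / math.sqrt(vx * vy)
    return min(max(value, 0.0), 1.0)


def model_size(n: int, multiplier: int = 6,
               log_base: float | None = None) -> int:
    """Screening model size d = multiplier * floor(n / log n), minimum 1.

    The logarithm is natural by default (the convention of the sure
    independence screening literature); pass ``log_base`` to override.
    """
    if n < 2:
        raise InputError("model size rule needs n >= 2")
    if multiplier < 1:
        raise InputError("multiplier must be a positive integer")
    log_n = math.log(n) if log_base is None else math.log(n, log_base)
    if log_n <= 0:
        raise InputError("log n must be positive for the chosen base")
    return max(1, multiplier * math.floor(n / log_n))


class DCSIS:
    """DC-SIS screen of a normalized matrix against the scar indicator.

    The response is the 0/1 condition indicator over all arrays; the
    paired structure is deliberately ignored (the screen is defined for
    i.i.d. samples), so n entering the model-size rule is the number of
    arrays by default, or the number of patients with ``n_rule="pairs"``.
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame):
        self.matrix = matrix
        self.samples = samples
        paired_arrays(samples, columns=matrix.columns)  # validates coverage
        cond = samples.set_index("array_id")["condition"]
        self.response = (cond.reindex(matrix.columns.astype(str)) ==
                         "scar").to_numpy(dtype=float)
        self.n_arrays = matrix.shape[1]

    def fit(self, multiplier: int = 6, log_base: float | None = None,
            n_rule: str = "arrays") -> "DCSISResults":
        if n_rule == "arrays":
            n_used = self.n_arrays
        elif n_rule == "pairs":
            n_used = self.n_arrays // 2
        else:
            raise InputError(f"unknown n_rule: {n_rule!r}")
        d = model_size(n_used, multiplier=multiplier, log_base=log_base)

        y = self.response
        b = _double_centered(y)
        vy = float((b * b).sum())
        x = self.matrix.to_numpy(dtype=float)
        m = x.shape[1]
        omega = np.empty(x.shape[0])
        for g in range(x.shape[0]):
            a = _double_centered(x[g])
            vx = float((a * a).sum())
            if vx <= 0.0 or vy <= 0.0:
                omega[g] = 0.0
            else:
                omega[g] = min(max(float((a * b).sum())
                                   / math.sqrt(vx * vy), 0.0), 1.0)
        if np.all(omega == 0.0):
            logger.warning("all screening scores are zero (constant rows "
                           "or constant response); selection falls back to "
                           "lexicographic order")

        table = pd.DataFrame({"mirna_id": self.matrix.index.astype(str),
                              "omega": omega})
        table = table.sort_values(["omega", "mirna_id"],
                                  ascending=[False, True],
                                  kind="stable").reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        table["selected"] = table["rank"] <= min(d, len(table))
        return DCSISResults(table, n_used=n_used, d=d, multiplier=multiplier,
                            log_base=log_base)


class DCSISResults:
    """Screening scores, ranks and the selected top-d set."""

    def __init__(self, table: pd.DataFrame, n_used: int, d: int,
                 multiplier: int, log_base: float | None):
        self.table = table
        self.n_used = n_used
        self.d = d
        self.multiplier = multiplier
        self.log_base = log_base

    @property
    def selected_ids(self) -> set:
        return set(self.table.loc[self.table["selected"], "mirna_id"])

    def summary(self) -> str:
        lines = [
            "DC-SIS feature screening",
            "========================",
            f"miRNAs screened:  {len(self.table)}",
            f"sample size n:    {self.n_used}",
            f"model size d:     {self.d} "
            f"(= {self.multiplier} * floor(n / log n))",
            f"selected:         {int(self.table['selected'].sum())}",
            "",
            "Top rows by omega:",
            self.table.head(10).to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        base = "e" if self.log_base is None else f"{self.log_base:g}"
        with open(path, "w") as fh:
            fh.write(f"# n_used={self.n_used}\n# d={self.d}\n"
                     f"# multiplier={self.multiplier}\n# log_base={base}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DCSISResults":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = fh.tell()
            table = pd.read_csv(fh, sep="\t")
        log_base = meta.get("log_base", "e")
        return cls(table, n_used=int(meta["n_used"]), d=int(meta["d"]),
                   multiplier=int(meta["multiplier"]),
                   log_base=None if log_base == "e" else float(log_base))


def dcsis_screen(matrix: pd.DataFrame, samples: pd.DataFrame,
                 multiplier: int = 6,
                 log_base: float | None = None) -> DCSISResults:
    """One-call version: fit the screen, return its results object."""
    return DCSIS(matrix, samples).fit(multiplier=multiplier,
                                      log_base=log_base)
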