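"""NODF significance against fixed-marginal (Patefield r2dtable-style) nulls.

The null ensemble holds the integer row and column totals of the observed
interaction matrix fixed and draws contingency tables from the hypergeometric
distribution conditional on those marginals — the same ensemble Patefield's
r2dtable algorithm samples. Drawing is done by cross-tabulating a random
pairing of row and column labels, which realises that distribution exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import integer_scaled, nodf


def patefield_sample(row_sums, col_sums, seed=None) -> np.ndarray:
    """One random contingency table with exactly the given marginals.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    row_sums = np.asarray(row_sums, dtype=int)
    col_sums = np.asarray(col_sums, dtype=int)
    if (row_sums < 0).any() or (col_sums < 0).any():
        raise ValueError("marginals must be non-negative")
    total = row_sums.sum()
    if total != col_sums.sum() or total == 0:
        raise ValueError(
            f"marginal totals differ or are zero: {total} vs {col_sums.sum()}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = np.repeat(np.arange(row_sums.size), row_sums)
    cols = np.repeat(np.arange(col_sums.size), col_sums)
    rng.shuffle(cols)
    table = np.zeros((row_sums.size, col_sums.size), dtype=int)
    np.add.at(table, (rows, cols), 1)
    return table


@dataclass
class NullModelResult:
    """Observed NODF against a fixed-marginal null distribution."""

    observed: float
    null_values: np.ndarray
    p_higher: float
    p_lower: float

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1))
            if len(self.null_values) > 1
            else 0.0,
            "null_q025": float(np.quantile(self.null_values, 0.025)),
            "null_q975": float(np.quantile(self.null_values, 0.975)),
            "n_rand": int(len(self.null_values)),
            "p_higher": self.p_higher,
            "p_lower": self.p_lower,
        }


def nodf_significance(net, n_rand: int = 100, seed=None) -> NullModelResult:
    """Monte Carlo NODF significance with Patefield fixed-marginal nulls.

    The observed weight matrix is scaled to integer counts, null tables are
    drawn with the observed marginals, binarized at > 0, and NODF recomputed.
    ``p_higher`` is the plain proportion of null matrices with NODF >= the
    observed value, ``p_lower`` the proportion with NODF <= it.
    """
    if n_rand < 20:
        raise ValueError("n_rand must be >= 20")
    mat = integer_scaled(net)
    row_sums = mat.sum(axis=1)
    col_sums = mat.sum(axis=0)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if (row_sums > 0).sum() < 2 or (col_sums > 0).sum() < 2:
        raise ValueError(
            "degenerate marginals: fewer than 2 occupied rows or columns, "
            "every null table is forced to equal the observed"
        )
    observed = nodf(mat > 0)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_rand)
    for k in range(n_rand):
        table = patefield_sample(row_sums, col_sums, rng)
        try:
            nulls[k] = nodf(table > 0)
        except ValueError:  # a null table may lose all fill in a guild pair
            nulls[k] = 0.0
    p_higher = float((nulls >= observed).mean())
    p_lower = float((nulls <= observed).mean())
    return NullModelResult(observed, nulls, p_higher, p_lower)
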