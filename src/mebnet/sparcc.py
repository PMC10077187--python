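"""SparCC-style compositional correlation inference.

Read counts from amplicon sequencing are compositional: only relative
abundances are observed, so naive Pearson correlations between fractions are
confounded by the closure constraint. The estimator implemented here works
from log-ratio variances

    t_ij = Var_samples[ log(x_i / x_j) ]

which are invariant to the per-sample closure, and approximates the latent
(basis) log-abundance variances ``omega_i**2`` under a sparsity assumption:
summing t_ij over partners j gives the linear system

    t_i ~= (p - 2) * omega_i**2 + sum_j omega_j**2

whose solution yields correlations

    rho_ij = (omega_i**2 + omega_j**2 - t_ij) / (2 * omega_i * omega_j).

Strongly correlated pairs violate the sparsity assumption, so the strongest
pair above an exclusion threshold is iteratively removed from the system and
the basis variances re-solved. Uncertainty in the fractions themselves is
integrated out by averaging over Dirichlet posterior draws of the per-sample
composition, and significance is assessed by a permutation bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import OtuTable

#: floor applied to basis variances so omega stays positive
OMEGA2_FLOOR = 1e-10


@dataclass
class CorrelationEstimate:
    """Basis correlations for a set of OTUs.

    Attributes
    ----------
    otu_ids : list of str
    rho : ndarray, shape (p, p)
        Symmetric correlation matrix with unit diagonal, clipped to [-1, 1].
    omega : ndarray, shape (p,)
        Basis (latent log-abundance) standard deviations.
    excluded_pairs : list of (int, int)
        Index pairs removed from the basis system by the iterative exclusion.
    """

    otu_ids: list[str]
    rho: np.ndarray
    omega: np.ndarray
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.otu_ids)


@dataclass
class SignificanceResult:
    """Bootstrap p-values for a correlation matrix (diagonal NaN)."""

    otu_ids: list[str]
    p: np.ndarray
    n_bootstrap: int
    two_sided: bool = True


def to_fractions(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Convert a counts matrix (OTUs x samples) to strictly positive fractions."""
    x = np.asarray(counts, dtype=float) + pseudocount
    return x / x.sum(axis=0, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Variance matrix of pairwise log-ratios, ``t_ij = Var[log(x_i/x_j)]``.

    Computed via the identity Var(l_i - l_j) = Var(l_i) + Var(l_j) - 2 Cov(l_i, l_j)
    on the log fractions, which is exactly the per-pair sample variance.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 2 or fractions.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate log-ratio variances")
    if (fractions <= 0).any():
        raise ValueError("fractions must be strictly positive (apply a pseudocount)")
    logs = np.log(fractions)
    cov = np.cov(logs, ddof=1)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def estimate_basis_variances(
    t: np.ndarray, active_pairs: np.ndarray | None = None
) -> np.ndarray:
    """Solve the basis-variance linear system restricted to the active pairs.

    Parameters
    ----------
    t : symmetric log-ratio variance matrix
    active_pairs : boolean symmetric matrix marking pairs still in the system
        (diagonal ignored); all pairs active when ``None``.

    Returns
    -------
    omega2 : per-OTU basis variances, floored at a small positive epsilon.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if p < 3:
        raise ValueError("need at least 3 OTUs to solve the basis system")
    if active_pairs is None:
        active = np.ones((p, p), dtype=bool)
    else:
        active = np.asarray(active_pairs, dtype=bool).copy()
    np.fill_diagonal(active, False)

    # t_i = sum_{j active} t_ij = n_i * w_i + sum_{j active} w_j,
    # with w = omega**2 and n_i = number of active partners of i.
    n_active = active.sum(axis=1)
    rhs = (t * active).sum(axis=1)
    m = active.astype(float)
    m[np.diag_indices(p)] = n_active
    omega2, *_ = np.linalg.lstsq(m, rhs, rcond=None)
    return np.maximum(omega2, OMEGA2_FLOOR)


def _rho_from(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    omega = np.sqrt(omega2)
    num = omega2[:, None] + omega2[None, :] - t
    rho = num / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def estimate_correlations(
    fractions: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    otu_ids: list[str] | None = None,
) -> CorrelationEstimate:
    """Estimate basis correlations with iterative strong-pair exclusion.

    Each round removes the single strongest ``|rho|`` pair exceeding
    ``exclusion_threshold`` from the basis system and re-solves, for at most
    ``max_exclusion_rounds`` rounds.
    """
    fractions = np.asarray(fractions, dtype=float)
    p = fractions.shape[0]
    if otu_ids is None:
        otu_ids = [str(i) for i in range(p)]
    t = log_ratio_variances(fractions)
    active = np.ones((p, p), dtype=bool)
    np.fill_diagonal(active, False)
    excluded: list[tuple[int, int]] = []

    omega2 = estimate_basis_variances(t, active)
    rho = _rho_from(t, omega2)
    for _ in range(max_exclusion_rounds):
        absr = np.abs(rho) * active
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= exclusion_threshold:
            break
        active[i, j] = active[j, i] = False
        excluded.append((min(i, j), max(i, j)))
        # an OTU left with too few partners keeps its last solved variance
        omega2 = estimate_basis_variances(t, active)
        rho = _rho_from(t, omega2)

    return CorrelationEstimate(list(otu_ids), rho, np.sqrt(omega2), excluded)


def _counts_and_ids(counts) -> tuple[np.ndarray, list[str]]:
    if isinstance(counts, OtuTable):
        return counts.counts, list(counts.otu_ids)
    arr = np.asarray(counts)
    return arr, [str(i) for i in range(arr.shape[0])]


def dirichlet_average(
    counts,
    n_draws: int = 20,
    seed: int | None = None,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
) -> CorrelationEstimate:
    """SparCC estimate averaged over Dirichlet posterior draws of the fractions.

    For each draw, every sample's composition is drawn from
    Dirichlet(counts + pseudocount) and correlations re-estimated; the
    element-wise median over draws is returned. ``n_draws=1`` reduces to a
    single-draw estimate.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    arr, ids = _counts_and_ids(counts)
    rng = np.random.default_rng(seed)
    rhos = []
    omegas = []
    excluded: set[tuple[int, int]] = set()
    alpha = arr.astype(float) + pseudocount
    for _ in range(n_draws):
        # per-sample Dirichlet draw; gamma trick vectorises over samples
        g = rng.standard_gamma(alpha)
        frac = g / g.sum(axis=0, keepdims=True)
        est = estimate_correlations(
            frac, exclusion_threshold, max_exclusion_rounds, otu_ids=ids
        )
        rhos.append(est.rho)
        omegas.append(est.omega)
        excluded.update(est.excluded_pairs)
    rho = np.median(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    omega = np.median(omegas, axis=0)
    return CorrelationEstimate(ids, rho, omega, sorted(excluded))


def bootstrap_pvalues(
    counts,
    observed: CorrelationEstimate,
    n_boot: int = 100,
    seed: int | None = None,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
) -> SignificanceResult:
    """Two-sided permutation-bootstrap p-values for SparCC correlations.

    Each replicate permutes every OTU's counts independently across samples
    (destroying all between-OTU association while preserving each OTU's
    abundance distribution), re-estimates correlations, and p_ij is the plain
    proportion of null ``|rho|`` values at least as large as the observed.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    arr, ids = _counts_and_ids(counts)
    p_otus, n_samples = arr.shape
    rng = np.random.default_rng(seed)
    obs = np.abs(observed.rho)
    exceed = np.zeros_like(obs)
    for _ in range(n_boot):
        perm = np.empty_like(arr)
        for i in range(p_otus):
            perm[i] = arr[i, rng.permutation(n_samples)]
        frac = to_fractions(perm, pseudocount)
        null = estimate_correlations(
            frac, exclusion_threshold, max_exclusion_rounds
        ).rho
        exceed += np.abs(null) >= obs
    pvals = exceed / n_boot
    np.fill_diagonal(pvals, np.nan)
    return SignificanceResult(ids, pvals, n_boot, two_sided=True)


def significant_edges(
    rho: np.ndarray,
    p: np.ndarray,
    otu_ids: list[str] | None = None,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Edges with ``|rho| > r_threshold`` and ``p < p_threshold`` (both strict).

    Returns a DataFrame with columns source, target, rho, p, sign.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    if rho.shape != p.shape:
        raise ValueError("rho and p shapes differ")
    n = rho.shape[0]
    if otu_ids is None:
        otu_ids = [str(i) for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    keep = (np.abs(rho[iu, ju]) > r_threshold) & (p[iu, ju] < p_threshold)
    iu, ju = iu[keep], ju[keep]
    return pd.DataFrame(
        {
            "source": [otu_ids[i] for i in iu],
            "target": [otu_ids[j] for j in ju],
            "rho": rho[iu, ju],
            "p": p[iu, ju],
            "sign": np.where(rho[iu, ju] > 0, "positive", "negative"),
        }
    )
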