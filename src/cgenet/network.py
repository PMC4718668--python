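"""Correlation-network construction and significance thresholding.

A group's network is the symmetric matrix of intersubject Pearson
correlations of expression between every pair of regions — coordinated gene
expression (CGE), the gene-expression analogue of functional connectivity.
Edges are tested with the conventional two-tailed t-test behind correlation
thresholds (t = r * sqrt((n-2)/(1-r^2)), df = n-2); non-significant entries
are zeroed to produce the visualization and community-detection substrate.
No multiple-testing correction is applied at this stage — correction enters
only at network comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientSubjects
from .expression import ExpressionTable, GroupKey
from .registry import RegionRegistry

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def correlation_pvalue(
    r: float | np.ndarray, n: int, tail: str = "two-sided"
) -> float | np.ndarray:
    """P-value for a Pearson correlation from n paired observations.

    Two-sided by default: p = 2 * (1 - T_{n-2}(|t|)) with
    t = r * sqrt((n-2) / (1-r^2)). |r| = 1 maps to p = 0 without overflow.
    """
    if n < 4:
        raise DomainError(f"n = {n} < 4: correlation test not run")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise DomainError("|r| > 1")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt(df / (1.0 - r_arr**2))
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise DomainError(f"unknown tail {tail!r}")
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, np.minimum(p, 1.0))
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def critical_r(n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Smallest |r| significant at the given two-sided alpha for n subjects."""
    if n < 4:
        raise DomainError(f"n = {n} < 4")
    df = n - 2
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def permutation_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Two-sided permutation p for a Pearson correlation (cross-check only).

    Permutes one variable's subject labels; exact enumeration is replaced by
    ``n_perm`` uniform draws (add-one correction keeps p > 0).
    """
    rng = np.random.default_rng(seed)
    r_obs = abs(float(np.corrcoef(x, y)[0, 1]))
    hits = 0
    for _ in range(n_perm):
        r = float(np.corrcoef(x, rng.permutation(y))[0, 1])
        if abs(r) >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass(frozen=True)
class CorrelationNetwork:
    """Per-group Pearson correlation matrix with edge-wise p-values.

    ``r`` and ``p`` are symmetric region-indexed DataFrames; the diagonal is
    fixed at r = 0, p = 1 and never treated as an edge. ``n`` is the single
    subject count behind every edge (listwise-complete subjects).
    """

    group: GroupKey
    regions: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        r, p = self.r.to_numpy(), self.p.to_numpy()
        if not np.allclose(r, r.T) or not np.allclose(p, p.T):
            raise ValueError("r and p must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("|r| > 1")


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Correlation network with non-significant edges zeroed.

    ``w`` equals r where p < alpha and 0 elsewhere; signs are preserved
    (positive and negative CGE are both retained).
    """

    group: GroupKey
    regions: tuple[str, ...]
    w: pd.DataFrame
    alpha: float
    n: int

    @property
    def edge_count(self) -> int:
        """Number of surviving (unordered, off-diagonal) edges."""
        m = self.w.to_numpy()
        return int(np.count_nonzero(np.triu(m, k=1)))


def pearson_network(
    table: ExpressionTable,
    group: GroupKey,
    registry: RegionRegistry | None = None,
    allow_missing: bool = False,
    tail: str = "two-sided",
) -> CorrelationNetwork:
    """Build a group's intersubject correlation network.

    Requires at least 4 complete subjects. Zero-variance regions are logged
    and their edges set to r = 0, p = 1.
    """
    registry = registry or table.registry
    wide = table.group_matrix(group, allow_missing=allow_missing)
    n = len(wide)
    if n < 4:
        raise InsufficientSubjects(
            f"group {group}: {n} complete subject(s) < 4"
        )
    values = wide.to_numpy()
    sd = values.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning(
            "group %s: zero-variance regions %s — edges set to r=0, p=1",
            group, [wide.columns[i] for i in flat],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    p = np.asarray(correlation_pvalue(r, n, tail=tail))
    p[flat, :] = 1.0
    p[:, flat] = 1.0
    np.fill_diagonal(p, 1.0)
    r = (r + r.T) / 2
    p = (p + p.T) / 2
    regions = tuple(wide.columns)
    return CorrelationNetwork(
        group=group,
        regions=regions,
        r=pd.DataFrame(r, index=regions, columns=regions),
        p=pd.DataFrame(p, index=regions, columns=regions),
        n=n,
    )


def threshold_network(
    net: CorrelationNetwork, alpha: float = DEFAULT_ALPHA
) -> ThresholdedNetwork:
    """Zero all edges with p >= alpha, preserving sign and magnitude."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside (0, 1)")
    w = net.r.where(net.p < alpha, other=0.0)
    w = w.copy()
    np.fill_diagonal(w.values, 0.0)
    thr = ThresholdedNetwork(
        group=net.group, regions=net.regions, w=w, alpha=alpha, n=net.n
    )
    logger.info(
        "group %s: %d/%d edges retained at alpha=%g",
        net.group, thr.edge_count, len(net.regions) * (len(net.regions) - 1) // 2,
        alpha,
    )
    return thr


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Square region-indexed matrix to CSV at full precision."""
    path = Path(path)
    matrix.to_csv(path, float_format="%.17g", lineterminator="\n")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return df.astype(float)
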