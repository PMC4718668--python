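"""Edge-wise statistical comparison of two correlation networks.

Drug-vs-baseline contrasts are made on the UNthresholded r matrices: each
edge's correlations are Fisher r-to-z transformed and the difference score

    Z = (z_a - z_b) / sqrt(1/(n_a - 3) + 1/(n_b - 3))

is referred to a standard normal (two-tailed). The 351 edge p-values of one
contrast form a single family corrected by the Benjamini-Hochberg step-up
false discovery rate (Benjamini-Yekutieli available), at a deliberately
liberal default of q = 0.35 to prioritize sensitivity in small-n networks.

Significant edges are classified by their per-group thresholded states
(baseline -> drug): null->pos = gain_positive, pos->null = loss_positive,
null->neg = gain_negative, neg->null = loss_negative, pos<->neg =
sign_reversal. A significant edge whose thresholded sign did not change is
not one of those transitions; it is reported in the supplementary
``strength_change`` column instead of receiving a class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DomainError,
    EmptyInput,
    InsufficientSubjects,
    RegionMismatch,
)
from .expression import GroupKey
from .network import CorrelationNetwork, ThresholdedNetwork

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.35
#: clamp for |r| -> 1 before atanh
R_CLAMP = 1e-7

EDGE_CLASSES = (
    "gain_positive",
    "loss_positive",
    "gain_negative",
    "loss_negative",
    "sign_reversal",
    "none",
)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher r-to-z (variance-stabilizing) transform, z = atanh(r).

    |r| within R_CLAMP of 1 is clamped (with a logged warning) so degenerate
    correlations produce large finite z instead of infinity.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise DomainError("|r| > 1")
    clamped = np.abs(r_arr) > 1 - R_CLAMP
    if np.any(clamped):
        logger.warning(
            "%d correlation(s) with |r| >= %g clamped before atanh",
            int(np.sum(clamped)), 1 - R_CLAMP,
        )
    z = np.arctanh(np.clip(r_arr, -(1 - R_CLAMP), 1 - R_CLAMP))
    return float(z) if np.ndim(r) == 0 else z


def z_difference(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> pd.DataFrame:
    """Per-edge Fisher-z difference scores and two-tailed normal p-values.

    Convention: a = drug, b = baseline; positive Z means the correlation
    strengthened under drug. One row per unordered off-diagonal edge.
    """
    if net_a.regions != net_b.regions:
        raise RegionMismatch(
            f"region sets differ: {net_a.regions} vs {net_b.regions}"
        )
    if net_a.n < 4 or net_b.n < 4:
        raise InsufficientSubjects(
            f"n_a={net_a.n}, n_b={net_b.n}: both must be >= 4"
        )
    regions = net_a.regions
    iu = np.triu_indices(len(regions), k=1)
    r_a = net_a.r.to_numpy()[iu]
    r_b = net_b.r.to_numpy()[iu]
    z_a = np.asarray(fisher_z(r_a))
    z_b = np.asarray(fisher_z(r_b))
    se = np.sqrt(1.0 / (net_a.n - 3) + 1.0 / (net_b.n - 3))
    z_score = (z_a - z_b) / se
    p = 2.0 * stats.norm.sf(np.abs(z_score))
    return pd.DataFrame(
        {
            "region_a": np.asarray(regions)[iu[0]],
            "region_b": np.asarray(regions)[iu[1]],
            "r_drug": r_a,
            "r_base": r_b,
            "z_drug": z_a,
            "z_base": z_b,
            "Z": z_score,
            "p": np.minimum(p, 1.0),
        }
    )


def fdr_adjust(
    pvals: np.ndarray, q_level: float = DEFAULT_Q, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """FDR-adjusted p-values and significance mask at ``q_level``.

    ``method`` selects Benjamini-Hochberg ("bh", step-up, independence/PRDS)
    or Benjamini-Yekutieli ("by", arbitrary dependence).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise EmptyInput("no p-values to adjust")
    if np.any((pvals < 0) | (pvals > 1)):
        raise DomainError("p-values outside [0, 1]")
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if mt_method is None:
        raise DomainError(f"unknown FDR method {method!r}")
    reject, adjusted, _, _ = multipletests(
        pvals, alpha=q_level, method=mt_method
    )
    return adjusted, reject


@dataclass(frozen=True)
class DifferenceMap:
    """Classified drug-vs-baseline edge differences for one contrast."""

    group_a: GroupKey
    group_b: GroupKey
    edges: pd.DataFrame  # columns from z_difference + q_adj, significant,
    #                      class, strength_change
    q_level: float
    method: str

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def class_counts(self) -> dict[str, int]:
        counts = self.edges["class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in EDGE_CLASSES}


def _edge_state(w: float) -> str:
    return "pos" if w > 0 else ("neg" if w < 0 else "null")


_TRANSITIONS = {
    ("null", "pos"): "gain_positive",
    ("pos", "null"): "loss_positive",
    ("null", "neg"): "gain_negative",
    ("neg", "null"): "loss_negative",
    ("pos", "neg"): "sign_reversal",
    ("neg", "pos"): "sign_reversal",
}


def classify_edges(
    diff: pd.DataFrame,
    thr_a: ThresholdedNetwork,
    thr_b: ThresholdedNetwork,
    q_level: float = DEFAULT_Q,
    method: str = "bh",
) -> DifferenceMap:
    """FDR-correct a z_difference table and label significant transitions.

    States are read baseline -> drug from the two thresholded networks.
    """
    if thr_a.regions != thr_b.regions:
        raise RegionMismatch("thresholded networks have different regions")
    edges = diff.copy()
    adjusted, reject = fdr_adjust(edges["p"].to_numpy(), q_level, method)
    edges["q_adj"] = adjusted
    edges["significant"] = reject

    wa, wb = thr_a.w, thr_b.w
    classes, strength = [], []
    for row in edges.itertuples():
        if not row.significant:
            classes.append("none")
            strength.append("")
            continue
        state_b = _edge_state(wb.at[row.region_a, row.region_b])
        state_a = _edge_state(wa.at[row.region_a, row.region_b])
        cls = _TRANSITIONS.get((state_b, state_a))
        if cls is None:
            # same thresholded sign on both sides: a pure strength change
            classes.append("none")
            strength.append(f"{state_b}->{state_a}")
        else:
            classes.append(cls)
            strength.append("")
    edges["class"] = classes
    edges["strength_change"] = strength
    return DifferenceMap(
        group_a=thr_a.group,
        group_b=thr_b.group,
        edges=edges,
        q_level=q_level,
        method=method,
    )


def compare_networks(
    net_a: CorrelationNetwork,
    net_b: CorrelationNetwork,
    thr_a: ThresholdedNetwork,
    thr_b: ThresholdedNetwork,
    q_level: float = DEFAULT_Q,
    method: str = "bh",
) -> DifferenceMap:
    """Full contrast: z differences on raw r, FDR, classification."""
    return classify_edges(
        z_difference(net_a, net_b), thr_a, thr_b, q_level, method
    )


def write_difference_map(diff: DifferenceMap, path: str | Path) -> Path:
    path = Path(path)
    cols = [
        "region_a", "region_b", "r_drug", "r_base", "Z", "p", "q_adj",
        "significant", "class", "strength_change",
    ]
    out = diff.edges[cols].copy()
    for c in ("r_drug", "r_base", "Z", "p", "q_adj"):
        out[c] = out[c].map(lambda v: format(v, ".17g"))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
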