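"""Single-factor differential-expression calls.

For each organ, three pairwise comparisons are screened: limiting vs
optimal nitrogen at optimal water, and mild / severe water stress vs
optimal water at optimal nitrogen. Following common microarray practice
the fold-change filter is applied first (|mean log2 difference| >=
log2 FC threshold), and the Benjamini-Hochberg correction is then applied
to the unpaired equal-variance t-test p-values of the filtered family
only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, SampleMetadata, check_matrix_metadata

log = logging.getLogger(__name__)

#: Named comparisons: (groupA, groupB) as (nitrogen, water) within an organ.
COMPARISONS = {
    "nitrogen": (("limiting", 1), ("optimal", 1)),
    "mild": (("optimal", 2), ("optimal", 1)),
    "severe": (("optimal", 3), ("optimal", 1)),
}


def _group_values(matrix, metadata, organ, nitrogen, water) -> np.ndarray:
    samples = [
        s
        for s in metadata.samples_for(organ=organ, nitrogen=nitrogen, water=water)
        if s in matrix.values.columns
    ]
    if len(samples) < 2:
        raise ValueError(
            f"condition (organ={organ}, nitrogen={nitrogen}, water={water}) "
            f"has {len(samples)} replicate(s); need >= 2"
        )
    return matrix.values[samples].to_numpy(dtype=float)


def fold_change(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    organ: str,
    groupA: tuple[str, int],
    groupB: tuple[str, int],
) -> pd.Series:
    """Per-entity log2 fold change: mean(log2 A) - mean(log2 B)."""
    if matrix.scale not in ("log2", "log2-baselined"):
        raise ValueError("fold change requires a log2-scale matrix")
    a = _group_values(matrix, metadata, organ, *groupA).mean(axis=1)
    b = _group_values(matrix, metadata, organ, *groupB).mean(axis=1)
    return pd.Series(a - b, index=matrix.entity_ids, name="log2_fc")


def ttest_equal_var(a, b) -> tuple[float, float]:
    """Unpaired two-sided t-test with pooled (equal) variance.

    When the pooled variance is exactly zero: p = 1 if the group means
    are equal (no evidence either way), otherwise an error — degenerate
    input that only arises with noise-free synthetic data.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def ttest_equal_var_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t-test for entity x replicate blocks.

    Vectorized version of :func:`ttest_equal_var`; rows with zero pooled
    variance get t = 0, p = 1 when the means agree and p = 0 otherwise.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    d = A.mean(axis=1) - B.mean(axis=1)
    sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = sp2 == 0.0
    t = np.where(zero, 0.0, t)
    p = np.where(zero & (d == 0.0), 1.0, np.where(zero, 0.0, p))
    return t, p


def benjamini_hochberg(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up FDR correction; returns (adjusted p, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def de_call(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    organ: str,
    comparison: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression calls for one organ and one comparison.

    Returns one row per entity with log2_fc, linear fold change with
    direction, raw and BH-adjusted p (the BH family being the entities
    that pass the fold-change filter), and the final significance flag.
    Entities outside the FC family carry p_adj = NaN and are never
    significant.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; options {list(COMPARISONS)}")
    check_matrix_metadata(matrix, metadata)
    groupA, groupB = COMPARISONS[comparison]
    A = _group_values(matrix, metadata, organ, *groupA)
    B = _group_values(matrix, metadata, organ, *groupB)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    _t, p_raw = ttest_equal_var_matrix(A, B)

    in_family = np.abs(lfc) >= np.log2(fc_threshold)
    p_adj = np.full(len(lfc), np.nan)
    significant = np.zeros(len(lfc), dtype=bool)
    if in_family.any():
        adj, rej = benjamini_hochberg(p_raw[in_family], alpha=alpha)
        p_adj[in_family] = adj
        significant[in_family] = rej
    else:
        log.warning(
            "de_call(%s, %s): no entity passed the %g-fold filter", organ, comparison,
            fc_threshold,
        )
    return pd.DataFrame(
        {
            "entity_id": matrix.entity_ids,
            "comparison": comparison,
            "organ": organ,
            "log2_fc": lfc,
            "fc_linear": np.exp2(np.abs(lfc)),
            "direction": np.where(lfc >= 0, "up", "down"),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "in_family": in_family,
            "significant": significant,
        }
    ).set_index("entity_id")


def significant_set(de_result: pd.DataFrame) -> set[str]:
    """Entity ids flagged significant in a de_call result."""
    return set(de_result.index[de_result["significant"]])


def venn_partition(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive region counts of a k-set Venn diagram.

    Keys are the frozensets of set names whose intersection (minus all
    other sets) the count belongs to; counts over all 2^k - 1 regions sum
    to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    counts: dict[frozenset, int] = {}
    universe = set().union(*named_sets.values())
    for item in universe:
        member = frozenset(n for n in names if item in named_sets[n])
        counts[member] = counts.get(member, 0) + 1
    return counts
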