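"""Nitrogen x water interaction screening on the 2x2 subdesign.

Only the four cells {optimal, limiting nitrogen} x {optimal water, severe
drought} enter this stage. Entities are prescreened on the maximum of the
four pairwise cell fold changes (the two nitrogen contrasts at fixed
water and the two water contrasts at fixed nitrogen), then a per-entity
two-way ANOVA with type-III (partial) sums of squares — sum-to-zero
effect coding — tests nitrogen, water, and their interaction. The ANOVA
is compared against single-factor t-tests within the same subdesign
(all optimal-N vs all limiting-N samples; all optimal-water vs all
severe-water samples): an entity is "exclusively
interaction-responsive" when its interaction term is significant while
neither single-factor t-test is.

The ANOVA is vectorized across entities with shared projection matrices:
in a 2x2 layout every term has one degree of freedom, so each type-III SS
is the increase in residual sum of squares when that term's column is
dropped from the full effect-coded design. Unbalanced replicate counts
(dropped arrays) are supported; empty cells are not.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, SampleMetadata, check_matrix_metadata
from .diffexpr import benjamini_hochberg, ttest_equal_var_matrix

log = logging.getLogger(__name__)

#: The four pairwise comparisons of the 2x2 subdesign, as
#: name -> ((nitrogenA, waterA), (nitrogenB, waterB)); water 1 = optimal,
#: 3 = severe drought.
SUBDESIGN_COMPARISONS = {
    "FC_W_optN": (("optimal", 1), ("optimal", 3)),
    "FC_N_optW": (("optimal", 1), ("limiting", 1)),
    "FC_N_sevW": (("optimal", 3), ("limiting", 3)),
    "FC_W_limN": (("limiting", 1), ("limiting", 3)),
}


def _cell_samples(metadata: SampleMetadata, organ: str) -> dict[tuple[str, int], list[str]]:
    cells = {}
    for nitrogen in ("optimal", "limiting"):
        for water in (1, 3):
            s = metadata.samples_for(organ=organ, nitrogen=nitrogen, water=water)
            if len(s) < 1:
                raise ValueError(
                    f"empty cell (organ={organ}, nitrogen={nitrogen}, water={water})"
                )
            cells[(nitrogen, water)] = s
    return cells


def pairwise_fold_changes(
    matrix: ExpressionMatrix, metadata: SampleMetadata, organ: str
) -> pd.DataFrame:
    """Signed log2 fold changes of the four 2x2 pairwise comparisons."""
    if matrix.scale not in ("log2", "log2-baselined"):
        raise ValueError("fold changes require a log2-scale matrix")
    cells = _cell_samples(metadata, organ)
    means = {
        cell: matrix.values[[s for s in samp if s in matrix.values.columns]]
        .to_numpy()
        .mean(axis=1)
        for cell, samp in cells.items()
    }
    out = {}
    for name, (a, b) in SUBDESIGN_COMPARISONS.items():
        out[name] = means[a] - means[b]
    return pd.DataFrame(out, index=matrix.entity_ids)


def prescreen_pairwise_fc(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    organ: str,
    fc_threshold: float = 2.0,
) -> tuple[list[str], pd.DataFrame]:
    """Entities whose largest pairwise cell fold change reaches the
    threshold; also returns the signed log2 FCs of all four comparisons."""
    lfc = pairwise_fold_changes(matrix, metadata, organ)
    retained_mask = (np.abs(lfc.to_numpy()) >= np.log2(fc_threshold)).any(axis=1)
    retained = list(lfc.index[retained_mask])
    log.info(
        "interaction prescreen (%s): %d of %d entities with max pairwise FC >= %g",
        organ,
        len(retained),
        len(lfc),
        fc_threshold,
    )
    return retained, lfc


def _effect_design(n_labels: np.ndarray, w_labels: np.ndarray) -> np.ndarray:
    """Sum-to-zero effect-coded design [1, N, W, NxW] for a 2x2 layout."""
    xn = np.where(np.asarray(n_labels) == "optimal", 1.0, -1.0)
    xw = np.where(np.asarray(w_labels).astype(int) == 1, 1.0, -1.0)
    return np.column_stack([np.ones(len(xn)), xn, xw, xn * xw])


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (samples x entities) on design X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return np.einsum("ij,ij->j", R, R)


def anova2_type3_matrix(
    Y: np.ndarray, n_labels, w_labels
) -> pd.DataFrame:
    """Per-entity 2x2 two-way ANOVA with type-III sums of squares.

    ``Y`` is samples x entities; ``n_labels`` / ``w_labels`` give each
    sample's nitrogen ("optimal"/"limiting") and water (1/3) level.
    Returns F and p columns for the N, W and NxW terms.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = _effect_design(n_labels, w_labels)
    n_obs = X.shape[0]
    df_err = n_obs - 4
    if df_err < 1:
        raise ValueError("error degrees of freedom < 1")
    for nl in ("optimal", "limiting"):
        for wl in (1, 3):
            if not ((np.asarray(n_labels) == nl) & (np.asarray(w_labels).astype(int) == wl)).any():
                raise ValueError(f"empty cell (nitrogen={nl}, water={wl})")
    rss_full = _rss(X, Y)
    mse = rss_full / df_err
    out = {}
    for k, term in ((1, "N"), (2, "W"), (3, "NxW")):
        X_red = np.delete(X, k, axis=1)
        ss = np.maximum(_rss(X_red, Y) - rss_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss / mse
        # zero error variance: infinite evidence for a nonzero term, none
        # for a term whose SS is itself zero
        F = np.where(mse == 0.0, np.where(ss > 0.0, np.inf, 0.0), F)
        p = stats.f.sf(F, 1, df_err)
        out[f"F_{term}"] = F
        out[f"p_{term}"] = p
    return pd.DataFrame(out)


def anova2_type3(values, n_labels, w_labels) -> dict[str, float]:
    """Single-entity convenience wrapper around :func:`anova2_type3_matrix`."""
    df = anova2_type3_matrix(np.asarray(values, dtype=float)[:, None], n_labels, w_labels)
    return {c: float(df[c].iloc[0]) for c in df.columns}


def classify(
    anova: pd.DataFrame, ttests: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Category flags from BH-adjusted ANOVA and pairwise-t-test p-values.

    ``anova`` must carry columns p_N_adj, p_W_adj, p_NxW_adj; ``ttests``
    columns p_N_ttest_adj, p_W_ttest_adj (single-factor t-tests within
    the 2x2 subdesign). An entity is exclusively interaction-responsive
    when its NxW term is significant while both t-test p-values exceed
    alpha.
    """
    idx = anova.index
    if not idx.equals(ttests.index):
        raise ValueError("anova and t-test results cover different entities")
    for col in ("p_N_adj", "p_W_adj", "p_NxW_adj"):
        if anova[col].isna().any():
            raise ValueError(f"missing p-values in column {col}")
    res = pd.DataFrame(index=idx)
    res["nitrogen_responsive"] = anova["p_N_adj"] <= alpha
    res["water_responsive"] = anova["p_W_adj"] <= alpha
    res["interaction_responsive"] = anova["p_NxW_adj"] <= alpha
    res["exclusive_interaction"] = (
        res["interaction_responsive"]
        & (ttests["p_N_ttest_adj"] > alpha)
        & (ttests["p_W_ttest_adj"] > alpha)
    )
    return res


def interaction_analysis(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    organ: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full interaction stage for one organ: prescreen, type-III ANOVA
    with per-term BH correction, pairwise t-tests, and classification.

    Returns one row per prescreened entity with adjusted p-values and the
    four category flags.
    """
    check_matrix_metadata(matrix, metadata)
    retained, _lfc = prescreen_pairwise_fc(matrix, metadata, organ, fc_threshold)
    if not retained:
        return pd.DataFrame(
            columns=[
                "p_N_adj", "p_W_adj", "p_NxW_adj",
                "p_N_ttest_adj", "p_W_ttest_adj",
                "nitrogen_responsive", "water_responsive",
                "interaction_responsive", "exclusive_interaction",
            ]
        )
    sub = matrix.subset(retained)
    cells = _cell_samples(metadata, organ)
    samples, n_labels, w_labels = [], [], []
    for (nitrogen, water), samp in cells.items():
        present = [s for s in samp if s in sub.values.columns]
        samples += present
        n_labels += [nitrogen] * len(present)
        w_labels += [water] * len(present)
    Y = sub.values[samples].to_numpy().T  # samples x entities
    anova = anova2_type3_matrix(Y, n_labels, w_labels)
    anova.index = pd.Index(retained, name="entity_id")
    # BH within each term family, mirroring the per-test correction
    for term in ("N", "W", "NxW"):
        adj, _ = benjamini_hochberg(anova[f"p_{term}"].to_numpy(), alpha=alpha)
        anova[f"p_{term}_adj"] = adj

    cell_arrays = {
        cell: sub.values[[s for s in samp if s in sub.values.columns]].to_numpy()
        for cell, samp in cells.items()
    }
    # single-factor t-tests within the 2x2: all optimal-N vs all
    # limiting-N samples, and all optimal-water vs all severe-water
    opt_n = np.hstack([cell_arrays[("optimal", 1)], cell_arrays[("optimal", 3)]])
    lim_n = np.hstack([cell_arrays[("limiting", 1)], cell_arrays[("limiting", 3)]])
    opt_w = np.hstack([cell_arrays[("optimal", 1)], cell_arrays[("limiting", 1)]])
    sev_w = np.hstack([cell_arrays[("optimal", 3)], cell_arrays[("limiting", 3)]])
    _t, p_n = ttest_equal_var_matrix(opt_n, lim_n)
    _t, p_w = ttest_equal_var_matrix(opt_w, sev_w)
    ttests = pd.DataFrame(
        {
            "p_N_ttest_adj": benjamini_hochberg(p_n, alpha=alpha)[0],
            "p_W_ttest_adj": benjamini_hochberg(p_w, alpha=alpha)[0],
        },
        index=anova.index,
    )
    flags = classify(anova, ttests, alpha=alpha)
    return pd.concat(
        [anova[["p_N_adj", "p_W_adj", "p_NxW_adj"]], ttests, flags], axis=1
    )
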