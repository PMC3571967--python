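"""Nitrogen-dependent trend comparison.

A gene that responds to the water series differently depending on
nitrogen supply shows up here: its optimal-N and limiting-N 5-point
trajectories are treated as two observations of the same entity, and a
two-component Gaussian mixture is fitted to the stacked observations.
If the two trajectories receive different MAP components the entity is
flagged as following a different trend under the two nitrogen regimes.
Only entities passing the clustering fold-change prescreen under BOTH
nitrogen regimes qualify (a more relaxed cutoff is used under limiting
nitrogen by default). The fit runs within each optimal-N cluster group;
a global mode fits one model over all qualifying entities instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .longclust import fit_em, prescreen_profiles

log = logging.getLogger(__name__)

DEFAULT_FC_OPTIMAL = 3.0
DEFAULT_FC_LIMITING = 2.0


def paired_profile_set(
    profiles_opt: pd.DataFrame,
    profiles_lim: pd.DataFrame,
    fc_opt: float = DEFAULT_FC_OPTIMAL,
    fc_lim: float = DEFAULT_FC_LIMITING,
) -> tuple[list, pd.DataFrame]:
    """Entities passing both prescreens, with their stacked observations.

    Returns (qualifying ids, stacked DataFrame) where the stacked frame
    has two rows per qualifying entity — one per nitrogen level — with
    columns entity_id, nitrogen, W1..W5.
    """
    keep_opt = set(prescreen_profiles(profiles_opt, fc_opt))
    keep_lim = set(prescreen_profiles(profiles_lim, fc_lim))
    have_both = set(profiles_opt.index) & set(profiles_lim.index)
    n_one_sided = len((keep_opt | keep_lim) - have_both)
    if n_one_sided:
        log.info("paired_profile_set: %d entities missing one profile", n_one_sided)
    qualifying = [e for e in profiles_opt.index if e in keep_opt and e in keep_lim]
    rows = []
    for nitrogen, prof in (("optimal", profiles_opt), ("limiting", profiles_lim)):
        block = prof.loc[qualifying].copy()
        block.insert(0, "nitrogen", nitrogen)
        block.insert(0, "entity_id", block.index)
        rows.append(block.reset_index(drop=True))
    stacked = pd.concat(rows, ignore_index=True)
    return qualifying, stacked


def detect_trend_change(
    profiles_opt: pd.DataFrame,
    profiles_lim: pd.DataFrame,
    qualifying: list,
    parent_groups: pd.Series | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    per_cluster: bool = True,
    min_confidence: float | None = None,
) -> pd.DataFrame:
    """Flag entities whose water trajectory changes shape with nitrogen.

    ``parent_groups`` maps each qualifying entity to its optimal-N
    cluster; the two-component fit runs within each group (or globally
    when ``per_cluster`` is False or no grouping is given). Strata with
    fewer than two entities cannot support a two-component fit and are
    passed through unflagged. With ``min_confidence`` set, a flag
    additionally requires both observations' max responsibility to reach
    that level.
    """
    if per_cluster and parent_groups is not None:
        strata = {
            g: [e for e in qualifying if parent_groups.get(e) == g]
            for g in sorted(pd.unique(parent_groups.loc[qualifying]))
        }
    else:
        strata = {0: list(qualifying)}
    out = []
    for g, ids in strata.items():
        if len(ids) < 2:
            log.warning(
                "trend stratum %s has %d entit(y/ies); passed through unflagged",
                g, len(ids),
            )
            for e in ids:
                out.append(
                    {"entity_id": e, "parent_group": g, "optN_component": 0,
                     "limN_component": 0, "different_trend": False, "tested": False}
                )
            continue
        X = np.vstack([profiles_opt.loc[ids].to_numpy(), profiles_lim.loc[ids].to_numpy()])
        try:
            model, assign = fit_em(X, G=2, n_restarts=n_restarts, seed=seed)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            log.warning("trend stratum %s: two-component fit failed (%s)", g, exc)
            for e in ids:
                out.append(
                    {"entity_id": e, "parent_group": g, "optN_component": 0,
                     "limN_component": 0, "different_trend": False, "tested": False}
                )
            continue
        labels = assign["map_group"].to_numpy()
        conf = assign[["z1", "z2"]].to_numpy().max(axis=1)
        k = len(ids)
        for i, e in enumerate(ids):
            differ = bool(labels[i] != labels[k + i])
            if min_confidence is not None:
                differ = differ and conf[i] >= min_confidence and conf[k + i] >= min_confidence
            out.append(
                {
                    "entity_id": e,
                    "parent_group": g,
                    "optN_component": int(labels[i]),
                    "limN_component": int(labels[k + i]),
                    "different_trend": differ,
                    "tested": True,
                }
            )
    return pd.DataFrame(out).set_index("entity_id")


def summarize_trends(results: pd.DataFrame) -> tuple[int, int, float]:
    """(n qualifying, n with different trend, percentage to one decimal)."""
    n_q = len(results)
    n_diff = int(results["different_trend"].sum()) if n_q else 0
    pct = round(100.0 * n_diff / n_q, 1) if n_q else float("nan")
    return n_q, n_diff, pct
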