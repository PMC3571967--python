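"""Summary tables, physiology utilities, and machine-readable run reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import significant_set

log = logging.getLogger(__name__)

#: Entities on the microarray used by this experimental platform.
CHIP_TOTAL = 46784


def rwc(fw: float, tw: float, dw: float) -> float:
    """Relative water content (%) of a leaf disc from fresh, turgid and
    dry weights: 100 * (FW - DW) / (TW - DW)."""
    if tw <= dw:
        raise ValueError("turgid weight must exceed dry weight")
    if not dw <= fw <= tw:
        warnings.warn(
            f"fresh weight {fw} outside [dry, turgid] = [{dw}, {tw}]; "
            "returning the unclamped value",
            stacklevel=2,
        )
    return 100.0 * (fw - dw) / (tw - dw)


def relative_to_reference(values, reference) -> np.ndarray:
    """Each value divided by the mean of the reference group."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference group")
    ref_mean = reference.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(values, dtype=float) / ref_mean


def percent_of_chip(count: int, chip_total: int = CHIP_TOTAL) -> float:
    """Share of chip entities, one decimal (round-half-even)."""
    if not 0 <= count <= chip_total:
        raise ValueError(f"count {count} outside [0, {chip_total}]")
    return round(100.0 * count / chip_total, 1)


def stress_overview_table(
    de_results: dict[tuple[str, str], pd.DataFrame], chip_total: int = CHIP_TOTAL
) -> pd.DataFrame:
    """Per-organ counts of water-stress-responsive entities.

    ``de_results`` maps (organ, comparison) to a de_call result; the
    "total" column is the size of the union of the mild- and severe-
    stress significant sets (an entity responsive to both is counted
    once), with its chip percentage alongside.
    """
    organs = sorted({o for o, _c in de_results})
    rows = []
    union_mild: set = set()
    union_severe: set = set()
    for organ in organs:
        mild = significant_set(de_results[(organ, "mild")]) if (organ, "mild") in de_results else None
        severe = significant_set(de_results[(organ, "severe")]) if (organ, "severe") in de_results else None
        if mild is None or severe is None:
            rows.append({"organ": organ, "mild": np.nan, "severe": np.nan,
                         "total": np.nan, "pct_of_chip": np.nan})
            continue
        union_mild |= mild
        union_severe |= severe
        total = len(mild | severe)
        rows.append(
            {"organ": organ, "mild": len(mild), "severe": len(severe),
             "total": total, "pct_of_chip": percent_of_chip(total, chip_total)}
        )
    rows.append(
        {
            "organ": "all",
            "mild": len(union_mild),
            "severe": len(union_severe),
            "total": len(union_mild | union_severe),
            "pct_of_chip": percent_of_chip(len(union_mild | union_severe), chip_total),
        }
    )
    return pd.DataFrame(rows).set_index("organ")


def interaction_table(
    interaction_results: dict[str, pd.DataFrame], chip_total: int = CHIP_TOTAL
) -> pd.DataFrame:
    """Per-organ interaction-stage counts, exclusive counts in parentheses.

    Columns follow the nitrogen / water / nitrogen x water layout; the
    "exclusive" parenthetical for the main effects counts entities
    responsive to that effect only, and for the interaction column the
    exclusively-interaction-responsive entities.
    """
    rows = []
    for organ, res in sorted(interaction_results.items()):
        n_resp = res["nitrogen_responsive"]
        w_resp = res["water_responsive"]
        i_resp = res["interaction_responsive"]
        rows.append(
            {
                "organ": organ,
                "prescreened": len(res),
                "nitrogen": f"{int(n_resp.sum())} ({int((n_resp & ~w_resp & ~i_resp).sum())})",
                "water": f"{int(w_resp.sum())} ({int((w_resp & ~n_resp & ~i_resp).sum())})",
                "nitrogen_x_water": f"{int(i_resp.sum())} ({int(res['exclusive_interaction'].sum())})",
            }
        )
    return pd.DataFrame(rows).set_index("organ")


def trend_table(trend_summaries: dict[str, tuple[int, int, float]]) -> pd.DataFrame:
    """Per-organ trend-change summary: qualifying, different, percent."""
    rows = [
        {"organ": organ, "n_qualifying": nq, "n_different": nd, "percent_different": pct}
        for organ, (nq, nd, pct) in sorted(trend_summaries.items())
    ]
    return pd.DataFrame(rows).set_index("organ")


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    parameters: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)  # stage -> entity count
    seed: int | None = None
    software_version: str = "nwstress 0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_stage(self, name: str, count: int) -> None:
        self.stage_counts[name] = int(count)

    def validate_monotone(self, chain: list[str]) -> None:
        """Counts along a filter chain must be nonincreasing."""
        counts = [self.stage_counts[s] for s in chain if s in self.stage_counts]
        for a, b in zip(counts, counts[1:]):
            if b > a:
                raise ValueError(f"filter chain count increased along {chain}: {counts}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def plot_cluster_trajectories(
    profiles: pd.DataFrame,
    assignment: pd.DataFrame,
    path: str | Path,
    subgroup: pd.Series | None = None,
) -> None:
    """One panel per MAP group: member trajectories plus the group mean.

    With ``subgroup`` given, members are coloured blue (up) / red (down).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(assignment["map_group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(3 * len(groups), 3), squeeze=False)
    x = np.arange(1, profiles.shape[1] + 1)
    for ax, g in zip(axes[0], groups):
        ids = assignment.index[assignment["map_group"] == g]
        block = profiles.loc[ids]
        for eid, row in block.iterrows():
            if subgroup is not None:
                color = "tab:blue" if subgroup.get(eid) == "up" else "tab:red"
            else:
                color = "0.7"
            ax.plot(x, row.to_numpy(), color=color, alpha=0.3, lw=0.6)
        ax.plot(x, block.mean(axis=0).to_numpy(), color="black", lw=2)
        ax.set_title(f"group {g} (n={len(ids)})")
        ax.set_xticks(x)
        ax.set_xlabel("water condition")
    axes[0][0].set_ylabel("log2 expression (baselined)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
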