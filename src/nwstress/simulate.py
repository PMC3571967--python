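"""Synthetic expression data with the 30-condition factorial structure.

Generates entity x sample matrices that mimic the study design — three
organs x two nitrogen regimes x five ordered water conditions, each with
replicated arrays — with known planted signal so every downstream stage
(detection filtering, differential expression, interaction ANOVA,
longitudinal clustering, trend comparison) can be validated against
ground truth. All signal is constructed on the log2 scale:

    log2 value = baseline + cluster trajectory (nitrogen-specific for
    trend-change entities) + nitrogen main effect + planted N x W
    interaction term + N(0, noise_sigma) replicate noise,

and the raw-scale export is 2**log2, clamped at a configurable floor.
The interaction term is planted on the 2x2 subdesign {optimal, limiting
N} x {optimal, severe W}: by default as a bump on the (limiting N,
severe water) cell alone (style ``cell``), or as a cross-over pattern
with zero 2x2 marginal means (style ``crossover``). Either way the
planted cell-mean contrast

    mean(optN,optW) - mean(optN,sevW) - mean(limN,optW) + mean(limN,sevW)

equals ``interaction_effect`` exactly when noise_sigma = 0. Trend-change
entities swap to a different trajectory shape under limiting nitrogen,
making their truth unambiguous for the trend detector; the interaction
and trend-change entity sets are disjoint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionMatrix, NITROGEN_LEVELS, ORGANS, SampleMetadata, WATER_LEVELS

#: Unit-amplitude trajectory library over the 5 ordered water conditions:
#: flat, monotone-down, monotone-up, stress-peak-with-recovery,
#: stress-trough-with-recovery.
_BASE_SHAPES = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, -0.25, -0.5, -0.75, -1.0],
        [0.0, 0.25, 0.5, 0.75, 1.0],
        [0.0, 0.6, 1.0, 0.4, 0.1],
        [0.0, -0.6, -1.0, -0.4, -0.1],
    ]
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic factorial design; all effects in log2 units."""

    n_entities: int = 2000
    organs: tuple[str, ...] = ORGANS
    n_replicates: int = 3
    n_clusters: int = 4
    cluster_amplitude: float = 3.0
    noise_sigma: float = 0.25
    frac_interaction: float = 0.05
    interaction_effect: float = 1.5
    frac_trend_change: float = 0.10
    interaction_style: str = "cell"
    nitrogen_effect: float = 0.0
    baseline_mean: float = 8.0
    raw_floor: float = 1.0
    cluster_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < self.n_clusters or self.n_clusters < 1:
            raise ValueError("need n_entities >= n_clusters >= 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("frac_interaction", "frac_trend_change"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_interaction + self.frac_trend_change > 1.0:
            raise ValueError("interaction and trend-change fractions overlap")
        if self.frac_trend_change > 0 and self.n_clusters < 2:
            raise ValueError("trend changes require at least 2 cluster shapes")
        if self.interaction_style not in ("cell", "crossover"):
            raise ValueError("interaction_style must be 'cell' or 'crossover'")
        unknown = set(self.organs) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organs: {sorted(unknown)}")
        if self.cluster_weights is not None:
            w = np.asarray(self.cluster_weights, dtype=float)
            if len(w) != self.n_clusters or (w < 0).any() or w.sum() <= 0:
                raise ValueError("cluster_weights must be n_clusters nonnegative values")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "organs" in raw:
            raw["organs"] = tuple(raw["organs"])
        if raw.get("cluster_weights") is not None:
            raw["cluster_weights"] = tuple(raw["cluster_weights"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth: labels, flags and noiseless mean profiles."""

    cluster_opt: np.ndarray  # planted cluster id under optimal N, 1..G
    cluster_lim: np.ndarray  # planted cluster id under limiting N
    is_interaction: np.ndarray
    is_trend_change: np.ndarray
    mean_profiles_opt: np.ndarray  # n_entities x 5, log2 units
    mean_profiles_lim: np.ndarray
    entity_ids: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "entity_id": self.entity_ids,
                "cluster_opt": self.cluster_opt,
                "cluster_lim": self.cluster_lim,
                "is_interaction": self.is_interaction,
                "is_trend_change": self.is_trend_change,
            }
        )
        for k in range(5):
            df[f"mean_optN_W{k + 1}"] = self.mean_profiles_opt[:, k]
            df[f"mean_limN_W{k + 1}"] = self.mean_profiles_lim[:, k]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_cluster_shapes(
    n_clusters: int, amplitude: float, seed: int = 0
) -> np.ndarray:
    """Return ``n_clusters`` distinct mean trajectories over the 5 conditions.

    Shapes come from a fixed library (flat, monotone-down, monotone-up,
    stress-peak-with-recovery, stress-trough-with-recovery) scaled by
    ``amplitude``. Beyond the five library shapes, additional shapes are
    produced by seeded smooth random perturbations of the library. Pairwise
    L2 separation of at least amplitude/2 is enforced.
    """
    if not 1 <= n_clusters <= 8:
        raise ValueError("n_clusters must lie in [1, 8]")
    shapes = [amplitude * s for s in _BASE_SHAPES[: min(n_clusters, 5)]]
    if n_clusters > 5:
        rng = np.random.default_rng(seed)
        while len(shapes) < n_clusters:
            base = shapes[rng.integers(len(shapes))]
            # smooth perturbation: random quadratic in the condition index
            t = np.linspace(-1.0, 1.0, 5)
            coef = rng.uniform(-1.0, 1.0, size=3) * amplitude
            cand = base + coef[0] + coef[1] * t + coef[2] * t**2
            cand = cand - cand[0]  # anchor at the optimal-water condition
            dists = [np.linalg.norm(cand - s) for s in shapes]
            if min(dists) >= amplitude / 2:
                shapes.append(cand)
    out = np.asarray(shapes)
    if n_clusters >= 2 and amplitude > 0:
        d = np.linalg.norm(out[:, None, :] - out[None, :, :], axis=2)
        iu = np.triu_indices(n_clusters, k=1)
        assert d[iu].min() >= amplitude / 2 - 1e-9
    return out


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for organ in config.organs:
        for nitrogen in NITROGEN_LEVELS:
            for water in WATER_LEVELS:
                for rep in range(1, config.n_replicates + 1):
                    nit = "optN" if nitrogen == "optimal" else "limN"
                    rows.append(
                        {
                            "sample_id": f"{organ}_{nit}_W{water}_r{rep}",
                            "organ": organ,
                            "nitrogen": nitrogen,
                            "water": water,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def simulate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic experiment; identical seeds give identical output.

    Returns a raw-scale (linear intensity) matrix with
    ``len(organs) * 2 * 5 * n_replicates`` sample columns, the matching
    metadata, and the planted truth. The planted signal is shared across
    organs (organ contributes no planted effect); replicate noise is drawn
    independently for every sample.
    """
    rng = np.random.default_rng(config.seed)
    n, G = config.n_entities, config.n_clusters
    shapes = make_cluster_shapes(G, config.cluster_amplitude, seed=config.seed)

    if config.cluster_weights is not None:
        w = np.asarray(config.cluster_weights, dtype=float)
        p = w / w.sum()
    else:
        p = np.full(G, 1.0 / G)
    cluster_opt = rng.choice(np.arange(1, G + 1), size=n, p=p)

    perm = rng.permutation(n)
    n_int = int(round(config.frac_interaction * n))
    n_trend = int(round(config.frac_trend_change * n))
    is_interaction = np.zeros(n, dtype=bool)
    is_trend = np.zeros(n, dtype=bool)
    is_interaction[perm[:n_int]] = True
    is_trend[perm[n_int : n_int + n_trend]] = True

    cluster_lim = cluster_opt.copy()
    if n_trend:
        trend_idx = np.flatnonzero(is_trend)
        shift = rng.integers(1, G, size=len(trend_idx))
        cluster_lim[trend_idx] = (cluster_opt[trend_idx] - 1 + shift) % G + 1

    prof_opt = config.baseline_mean + shapes[cluster_opt - 1]
    prof_lim = (
        config.baseline_mean + config.nitrogen_effect + shapes[cluster_lim - 1]
    )
    prof_opt = prof_opt.copy()
    prof_lim = prof_lim.copy()
    if config.interaction_style == "cell":
        # bump on the (limiting N, severe water) cell only
        prof_lim[is_interaction, 2] += config.interaction_effect
    else:
        # cross-over with zero 2x2 marginal means: +-effect/4 on the
        # optimal/severe-water cells, opposite signs per nitrogen level
        q = config.interaction_effect / 4.0
        prof_opt[is_interaction, 0] += q
        prof_opt[is_interaction, 2] -= q
        prof_lim[is_interaction, 0] -= q
        prof_lim[is_interaction, 2] += q

    meta = _sample_table(config)
    cols = meta["sample_id"].tolist()
    log2_vals = np.empty((n, len(cols)))
    for j, row in enumerate(meta.itertuples(index=False)):
        base = prof_opt if row.nitrogen == "optimal" else prof_lim
        log2_vals[:, j] = base[:, row.water - 1]
    if config.noise_sigma > 0:
        log2_vals = log2_vals + rng.normal(0.0, config.noise_sigma, size=log2_vals.shape)

    entity_ids = [f"ent{i:05d}" for i in range(n)]
    raw = np.maximum(np.exp2(log2_vals), config.raw_floor)
    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=entity_ids, columns=cols), scale="raw"
    )
    truth = SyntheticTruth(
        cluster_opt=cluster_opt,
        cluster_lim=cluster_lim,
        is_interaction=is_interaction,
        is_trend_change=is_trend,
        mean_profiles_opt=prof_opt,
        mean_profiles_lim=prof_lim,
        entity_ids=entity_ids,
        config=dataclasses.replace(config),
    )
    return matrix, SampleMetadata(meta), truth
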