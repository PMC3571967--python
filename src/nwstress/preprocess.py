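"""Matrix preprocessing: log transform, baseline centring, detection
filtering, and collapse of replicates to 5-point condition profiles.

The pipeline accepts an already-summarized entity x sample matrix (probe
summarization such as RMA happens upstream). Preprocessing then mirrors
the standard microarray sequence: log2-transform, baseline each entity to
its median across all arrays, drop entities never detected above a raw
intensity threshold in all replicates of any one condition, and take the
replicate median per water condition to obtain one ordered 5-vector per
entity per organ x nitrogen stratum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    SampleMetadata,
    WATER_LEVELS,
    check_matrix_metadata,
)

log = logging.getLogger(__name__)

#: Raw-intensity detection threshold used throughout the analysis.
DEFAULT_DETECTION_THRESHOLD = 20.0


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the same intensity distribution.

    Classic rank-based quantile normalization (each value is replaced by
    the across-sample mean of its rank's order statistic; rank ties get
    the average). Optional and off by default in the pipeline: the
    generator already produces arrays on a common scale.
    """
    if matrix.scale != "raw":
        raise ValueError("quantile normalization operates on the raw matrix")
    vals = matrix.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.entity_ids, columns=matrix.sample_ids),
        scale="raw",
    )


def log_and_baseline(
    matrix: ExpressionMatrix, floor: float = 1.0, baseline: str = "per-entity-median"
) -> ExpressionMatrix:
    """log2-transform a raw matrix and centre each entity to its median.

    Values are floored at ``floor`` before the log so that near-zero
    intensities cannot produce -inf. With the default baseline mode each
    output row has median exactly 0; ``baseline="none"`` skips centring
    and returns a plain log2 matrix.
    """
    if matrix.scale != "raw":
        raise ValueError(f"expected a raw-scale matrix, got scale={matrix.scale!r}")
    if baseline not in ("per-entity-median", "none"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    vals = np.maximum(matrix.values.to_numpy(dtype=float), floor)
    bad = np.flatnonzero(~(vals > 0).all(axis=1))
    if len(bad):
        raise ValueError(
            f"non-positive values after flooring for entity {matrix.entity_ids[bad[0]]!r}"
        )
    logged = np.log2(vals)
    if baseline == "none":
        return ExpressionMatrix(
            pd.DataFrame(logged, index=matrix.entity_ids, columns=matrix.sample_ids),
            scale="log2",
        )
    centred = logged - np.median(logged, axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(centred, index=matrix.entity_ids, columns=matrix.sample_ids),
        scale="log2-baselined",
    )


def detection_filter(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    strict: bool = True,
) -> list[str]:
    """Entities whose raw signal clears ``threshold`` in every replicate of
    at least one condition.

    ``strict`` controls the tie rule at exactly ``threshold``: strictly
    greater (default) versus greater-or-equal.
    """
    if matrix.scale != "raw":
        raise ValueError("detection filter operates on the raw-scale matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    check_matrix_metadata(matrix, metadata)
    if matrix.values.empty:
        return []
    vals = matrix.values
    keep = np.zeros(len(vals), dtype=bool)
    for _cond, samples in metadata.conditions():
        present = [s for s in samples if s in vals.columns]
        if not present:
            continue
        cond_min = vals[present].to_numpy().min(axis=1)
        keep |= (cond_min > threshold) if strict else (cond_min >= threshold)
    retained = [e for e, k in zip(vals.index, keep) if k]
    log.info(
        "detection filter: %d of %d entities above %g in all replicates of >=1 condition",
        len(retained),
        len(vals),
        threshold,
    )
    return retained


def condition_profiles(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    organ: str,
    nitrogen: str,
) -> pd.DataFrame:
    """Replicate-median 5-point water trajectories for one organ x nitrogen
    stratum.

    Returns a DataFrame indexed by entity id with columns W1..W5 (ordered
    water conditions); the median is used rather than the mean because it
    is less sensitive to a single outlying replicate array.
    """
    if matrix.scale not in ("log2", "log2-baselined"):
        raise ValueError("condition profiles require a log2-scale matrix")
    check_matrix_metadata(matrix, metadata)
    cols = {}
    missing = []
    for water in WATER_LEVELS:
        samples = [
            s
            for s in metadata.samples_for(organ=organ, nitrogen=nitrogen, water=water)
            if s in matrix.values.columns
        ]
        if not samples:
            missing.append(water)
            continue
        cols[f"W{water}"] = np.median(matrix.values[samples].to_numpy(), axis=1)
    if missing:
        raise ValueError(
            f"missing water conditions {missing} for organ={organ!r}, nitrogen={nitrogen!r}"
        )
    return pd.DataFrame(cols, index=matrix.entity_ids)
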