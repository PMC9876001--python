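"""Site cleaning, outlier-sample detection and sample alignment.

Mirrors the standard pre-processing of 450K beta matrices: failed probes
(zero or missing beta) are removed, outlying samples are identified on a
hierarchical sample tree, and the methylation and clinical tables are
restricted to their common samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datamodel import BetaMatrix, ClinicalTable

logger = logging.getLogger(__name__)

__all__ = ["clean_sites", "detect_outlier_samples", "align_samples"]

#: clinical fields that must be complete for a sample to survive alignment
DEFAULT_REQUIRED_FIELDS = ("group", "event", "time", "age", "stage_T", "stage_N", "stage_M")


def clean_sites(bm: BetaMatrix, zero_policy: str = "any") -> BetaMatrix:
    """Drop failed methylation sites.

    ``zero_policy="any"`` (default) removes a site when any sample has a
    missing beta or a beta of exactly 0 — zeros in a beta array indicate
    failed probes. ``"all"`` removes only sites that are zero/missing in
    every sample. Idempotent.
    """
    if zero_policy not in ("any", "all"):
        raise ValueError(f"zero_policy must be 'any' or 'all', got {zero_policy!r}")
    v = bm.values
    bad = v.isna() | (v == 0.0)
    drop = bad.any(axis=1) if zero_policy == "any" else bad.all(axis=1)
    kept = v.loc[~drop]
    if kept.shape[0] == 0:
        raise ValueError("clean_sites removed every site")
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("clean_sites: dropped %d of %d sites", n_drop, v.shape[0])
    return BetaMatrix(kept)


def detect_outlier_samples(
    bm: BetaMatrix, cut_height_quantile: float = 0.95
) -> list[str]:
    """Flag outlier samples on an average-linkage Euclidean sample tree.

    The dendrogram is cut at the given quantile of its merge heights and
    every sample outside the largest resulting cluster is reported. A
    quantile of 1.0 cuts at the root, so nothing is flagged.
    """
    if bm.shape[1] < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    if not (0.0 < cut_height_quantile <= 1.0):
        raise ValueError("cut_height_quantile must be in (0, 1]")
    X = bm.values.to_numpy(dtype=float).T  # samples as observations
    Z = linkage(X, method="average", metric="euclidean")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    labels = fcluster(Z, t=cut, criterion="distance")
    counts = pd.Series(labels).value_counts()
    # deterministic tie-break: among equally large clusters keep the lowest label
    top = counts.max()
    keep_label = int(min(counts.index[counts == top]))
    samples = bm.sample_ids
    outliers = [s for s, lab in zip(samples, labels) if lab != keep_label]
    if outliers:
        logger.info("detect_outlier_samples: %d outliers flagged", len(outliers))
    return outliers


def align_samples(
    bm: BetaMatrix,
    clin: ClinicalTable,
    required_fields: tuple[str, ...] = DEFAULT_REQUIRED_FIELDS,
) -> tuple[BetaMatrix, ClinicalTable]:
    """Restrict both tables, in identical order, to their common samples.

    Samples with missing values in ``required_fields`` are dropped (and
    logged), as incomplete clinical records cannot be used downstream.
    """
    common = [s for s in bm.sample_ids if s in set(clin.sample_ids)]
    if not common:
        raise ValueError("no samples shared between beta matrix and clinical table")
    sub = clin.table.loc[common]
    cols = [c for c in required_fields if c in sub.columns]
    complete = ~sub[cols].isna().any(axis=1)
    kept = [s for s, ok in zip(common, complete) if ok]
    n_drop = len(common) - len(kept)
    if n_drop:
        logger.info("align_samples: dropped %d samples with incomplete clinical data", n_drop)
    if not kept:
        raise ValueError("no samples with complete clinical data remain")
    return bm.subset_samples(kept), clin.subset(kept)
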