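"""Canonical-correlation weighting of a prior gene regulatory network.

The centrepiece of the pipeline: each gene's methylation sites are reduced
to a small block of principal-component scores, and every prior-network
edge between two genes is weighted by the first canonical correlation
between the two blocks — the maximum Pearson correlation attainable between
any linear combination of one gene's components and any linear combination
of the other's. Canonical correlations are invariant to invertible linear
transforms of either block, so the weight does not depend on how the PCA
basis is scaled or rotated, only on the subspaces the two genes span.

The first canonical correlation is computed from the singular values of the
whitened cross-covariance ``Sxx^{-1/2} Sxy Syy^{-1/2}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, PriorNetwork, SiteAnnotation, WeightedGeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeatureBlock",
    "restrict_prior_network",
    "reduce_gene_features",
    "canonical_weight",
    "build_weighted_network",
]


@dataclass
class GeneFeatureBlock:
    """Per-gene PCA score block: sample x component matrix of centered scores."""

    gene_symbol: str
    scores: pd.DataFrame  # samples x components
    explained_variance: np.ndarray  # per-component fraction of total variance
    n_sites_original: int

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def restrict_prior_network(
    prior: PriorNetwork, dmgs: set[str], policy: str = "both"
) -> PriorNetwork:
    """Keep prior edges whose endpoints are differentially methylated genes.

    ``policy="both"`` (default) requires both endpoints to be DMGs;
    ``"either"`` keeps an edge when at least one endpoint is.
    """
    if policy == "both":
        edges = [(a, b) for a, b in prior.edges if a in dmgs and b in dmgs]
    elif policy == "either":
        edges = [(a, b) for a, b in prior.edges if a in dmgs or b in dmgs]
    else:
        raise ValueError(f"policy must be 'both' or 'either', got {policy!r}")
    if not edges:
        n_hit = len(dmgs & prior.nodes)
        raise ValueError(
            f"no prior edges retained: {len(dmgs)} DMGs, {n_hit} present among "
            f"{len(prior.nodes)} network genes, policy={policy!r}"
        )
    return PriorNetwork(edges=edges, source=f"{prior.source} (restricted)")


def reduce_gene_features(
    bm: BetaMatrix,
    annot: SiteAnnotation,
    gene: str,
    var_retained: float = 0.9,
) -> GeneFeatureBlock:
    """PCA-reduce all methylation sites of one gene to leading score columns.

    Retains the smallest number of leading components whose cumulative
    explained variance reaches ``var_retained`` (default 0.9), at least one
    and at most n_samples - 1 so downstream CCA stays well-posed.
    """
    sites = [s for s in annot.sites_for_gene(gene) if s in bm.values.index]
    if not sites:
        raise ValueError(f"gene {gene!r} has no sites in the beta matrix")
    X = bm.values.loc[sites].to_numpy(dtype=float).T  # samples x sites
    n, p = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    if total <= 0:
        # constant gene: keep a single zero-score component; CCA will reject it
        frac = np.array([1.0])
        scores = np.zeros((n, 1))
    else:
        frac = S**2 / total
        k_max = min(p, max(n - 1, 1))
        k = int(np.searchsorted(np.cumsum(frac[:k_max]), var_retained) + 1)
        k = max(1, min(k, k_max))
        frac = frac[:k]
        scores = U[:, :k] * S[:k]
    return GeneFeatureBlock(
        gene_symbol=gene,
        scores=pd.DataFrame(scores, index=bm.sample_ids),
        explained_variance=frac,
        n_sites_original=len(sites),
    )


def _whitener(S: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of a covariance, ridged only if near-singular."""
    w, V = np.linalg.eigh(S)
    scale = float(w.max())
    if scale <= 0:
        raise ValueError("zero-variance feature block in canonical correlation")
    if w.min() < 1e-10 * scale:
        ridge = 1e-8 * np.trace(S) / S.shape[0]
        w = w + ridge
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def canonical_weight(
    a: GeneFeatureBlock, b: GeneFeatureBlock, method: str = "first"
) -> float:
    """First canonical correlation between two gene feature blocks, in [0, 1].

    ``method="first"`` (default) returns the largest canonical correlation;
    ``"mean"`` averages all min(p, q) canonical correlations.
    """
    if method not in ("first", "mean"):
        raise ValueError(f"method must be 'first' or 'mean', got {method!r}")
    if list(a.scores.index) != list(b.scores.index):
        raise ValueError("feature blocks must be over identical ordered samples")
    X = a.scores.to_numpy(dtype=float)
    Y = b.scores.to_numpy(dtype=float)
    n = X.shape[0]
    if n <= X.shape[1] + Y.shape[1]:
        warnings.warn(
            f"CCA between {a.gene_symbol} and {b.gene_symbol}: "
            f"{n} samples <= {X.shape[1]} + {Y.shape[1]} components",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    if float(np.trace(Sxx)) <= 0 or float(np.trace(Syy)) <= 0:
        raise ValueError("zero-variance feature block in canonical correlation")
    K = _whitener(Sxx) @ Sxy @ _whitener(Syy)
    svals = np.linalg.svd(K, compute_uv=False)
    rho = float(svals[0]) if method == "first" else float(svals.mean())
    return float(np.clip(rho, 0.0, 1.0))


def build_weighted_network(
    prior: PriorNetwork,
    blocks: dict[str, GeneFeatureBlock],
    method: str = "first",
) -> WeightedGeneNetwork:
    """Weight every prior edge by canonical correlation and label components.

    Genes without a feature block are dropped with a warning. Connected
    components are labelled by descending size (0 = largest); the largest
    component is the analysis network.
    """
    missing = sorted(prior.nodes - set(blocks))
    if missing:
        warnings.warn(
            f"{len(missing)} prior-network genes lack feature blocks and were dropped",
            stacklevel=2,
        )
    edges: list[tuple[str, str, float]] = []
    for gene_a, gene_b in prior.edges:
        if gene_a in blocks and gene_b in blocks:
            w = canonical_weight(blocks[gene_a], blocks[gene_b], method=method)
            edges.append((gene_a, gene_b, w))
    if not edges:
        raise ValueError("weighted network is empty: no edges with feature blocks")
    net = WeightedGeneNetwork.from_edges(edges)
    n_comp = len(set(net.component_id.values()))
    logger.info(
        "weighted network: %d genes, %d edges, %d components (largest %d genes)",
        len(net.nodes), len(edges), n_comp, len(net.largest_component_nodes()),
    )
    return net
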