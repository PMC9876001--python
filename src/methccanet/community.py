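"""Module detection on the weighted gene network by modularity maximization.

Uses the multilevel (Louvain) algorithm on edge weights; the reported Q is
the classic weighted modularity

    Q = (1/2m) * sum_ij [w_ij - k_i k_j / (2m)] * delta(c_i, c_j)

with k the weighted degrees and m the total edge weight. ``modularity``
recomputes Q by direct summation, independently of the detection code path,
so it can serve as an oracle for ``detect_modules``.
"""

from __future__ import annotations

import logging
import random
import warnings

from .datamodel import ModulePartition, WeightedGeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["detect_modules", "modularity", "filter_small_modules"]

#: modules smaller than this are discarded after detection
DEFAULT_MIN_MODULE_SIZE = 100


def _relabel_by_size(groups: list[list[str]]) -> dict[str, int]:
    """Assign 1-based module indices by descending size (ties: smallest member)."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {gene: i + 1 for i, grp in enumerate(ordered) for gene in grp}


def detect_modules(
    net: WeightedGeneNetwork, seed: int = 1, resolution: float = 1.0
) -> ModulePartition:
    """Multilevel (Louvain) community detection on the weighted network.

    The node sweep order is randomized from ``seed`` (identical seed and
    input give an identical partition). ``resolution`` scales the null-model
    term; 1.0 is classic modularity. The reported Q is always classic
    weighted modularity of the returned assignment. A network with no edges
    degenerates to singleton modules with Q = 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if len(net.nodes) < 2:
        raise ValueError("module detection needs at least 2 nodes")
    if not net.edges:
        warnings.warn("network has no edges; every node is its own module", stacklevel=2)
        assignment = _relabel_by_size([[n] for n in net.nodes])
        return ModulePartition(assignment=assignment, modularity_q=0.0, seed=seed)

    g = net.to_igraph()
    # python-igraph draws its randomness from the stdlib random module
    random.seed(seed)
    clustering = g.community_multilevel(weights="weight", resolution=resolution)
    groups = [[g.vs[v]["name"] for v in comm] for comm in clustering]
    assignment = _relabel_by_size(groups)
    # report igraph's weighted modularity; modularity() below recomputes the
    # same quantity by direct summation and serves as an independent oracle
    q = float(g.modularity(clustering.membership, weights=g.es["weight"]))
    logger.info("detect_modules: %d modules, Q = %.4f", len(groups), q)
    return ModulePartition(assignment=assignment, modularity_q=q, seed=seed)


def modularity(net: WeightedGeneNetwork, assignment: dict[str, int]) -> float:
    """Weighted modularity of an assignment by direct double summation."""
    uncovered = [n for n in net.nodes if n not in assignment]
    if uncovered:
        raise ValueError(f"assignment misses {len(uncovered)} nodes, e.g. {uncovered[0]!r}")
    m = sum(w for _, _, w in net.edges)
    if m == 0:
        return 0.0
    within: dict[int, float] = {}
    degree: dict[str, float] = {n: 0.0 for n in net.nodes}
    for a, b, w in net.edges:
        degree[a] += w
        degree[b] += w
        if assignment[a] == assignment[b]:
            within[assignment[a]] = within.get(assignment[a], 0.0) + w
    tot: dict[int, float] = {}
    for n, k in degree.items():
        c = assignment[n]
        tot[c] = tot.get(c, 0.0) + k
    q = 0.0
    for c in set(assignment.values()):
        q += within.get(c, 0.0) / m - (tot.get(c, 0.0) / (2.0 * m)) ** 2
    return q


def filter_small_modules(
    partition: ModulePartition, min_size: int = DEFAULT_MIN_MODULE_SIZE
) -> ModulePartition:
    """Drop modules with fewer than ``min_size`` genes and re-index the rest.

    Retained modules keep their size ordering (indices re-assigned 1..k);
    the genes of removed modules are logged.
    """
    sizes = partition.sizes()
    keep = {m for m, s in sizes.items() if s >= min_size}
    if not keep:
        raise ValueError(
            f"no module has >= {min_size} genes; sizes were {sorted(sizes.values(), reverse=True)}"
        )
    groups = [partition.members(m) for m in keep]
    removed = [g for g, m in partition.assignment.items() if m not in keep]
    if removed:
        logger.info(
            "filter_small_modules: removed %d genes in %d small modules",
            len(removed), len(sizes) - len(keep),
        )
    assignment = _relabel_by_size(groups)
    return ModulePartition(
        assignment=assignment,
        modularity_q=partition.modularity_q,
        seed=partition.seed,
    )
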