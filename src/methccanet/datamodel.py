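"""Core data containers for the methylation network pipeline.

All containers are thin, validated wrappers around pandas objects so that
every downstream stage can rely on a handful of invariants: unique site and
sample identifiers, beta values inside [0, 1], self-loop-free undirected
prior networks, and clinical tables with non-negative follow-up times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SiteAnnotation",
    "ClinicalTable",
    "PriorNetwork",
    "WeightedGeneNetwork",
    "ModulePartition",
    "ModuleEigengene",
    "CLINICAL_COLUMNS",
]

#: canonical clinical column order (sample_id is the index)
CLINICAL_COLUMNS = ["group", "event", "time", "age", "stage_T", "stage_N", "stage_M"]

#: the ordinal traits used for module-trait association
TRAIT_COLUMNS = ["event", "age", "stage_M", "stage_N", "stage_T"]


@dataclass
class BetaMatrix:
    """Site x sample matrix of methylation fractions (beta values).

    ``values`` is indexed by site id with sample ids as columns. Missing
    values (NaN) are allowed before cleaning; every non-missing entry must
    lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {arr[i, j]} outside [0, 1] at site "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_sites(self, sites) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(sites)])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)])


@dataclass
class SiteAnnotation:
    """Probe annotation mapping site ids to gene symbols.

    ``table`` is indexed by site id with columns ``gene_symbol`` and the
    optional ``chromosome`` / ``position``. Multi-gene probes are resolved
    at load time (first symbol kept), so the map is one site -> one gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene_symbol" not in self.table.columns:
            raise ValueError("annotation requires a gene_symbol column")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate site ids in annotation")

    def gene_of(self, site_id: str) -> str | None:
        if site_id not in self.table.index:
            return None
        g = self.table.at[site_id, "gene_symbol"]
        return None if pd.isna(g) else str(g)

    def sites_for_gene(self, gene: str) -> list[str]:
        mask = self.table["gene_symbol"] == gene
        return list(self.table.index[mask])

    def gene_map(self) -> pd.Series:
        """site id -> gene symbol series (annotated sites only)."""
        s = self.table["gene_symbol"].dropna()
        return s.astype(str)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    Indexed by sample id; columns follow :data:`CLINICAL_COLUMNS`:
    ``group`` (case/control), ``event`` (1 = death), ``time`` (days),
    ``age`` (years) and ordinal ``stage_T`` / ``stage_N`` / ``stage_M``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        missing = [c for c in CLINICAL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        ev = t["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        tm = t["time"].dropna()
        if (tm < 0).any():
            raise ValueError("follow-up time must be >= 0")
        for c in ("stage_T", "stage_N", "stage_M"):
            s = t[c].dropna()
            if (s < 0).any():
                raise ValueError(f"{c} must be a non-negative ordinal code")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def case_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "case"])

    def control_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "control"])

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(samples)])


def _canon_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PriorNetwork:
    """Undirected prior gene-regulatory network as a de-duplicated edge list."""

    edges: list[tuple[str, str]]
    source: str = "unknown"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        cleaned: list[tuple[str, str]] = []
        for a, b in self.edges:
            a, b = str(a), str(b)
            if a == b:
                continue
            e = _canon_edge(a, b)
            if e not in seen:
                seen.add(e)
                cleaned.append(e)
        self.edges = cleaned

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class WeightedGeneNetwork:
    """Genes as nodes, prior edges re-weighted by canonical correlation.

    ``edges`` are ``(gene_a, gene_b, weight)`` with weight in [0, 1];
    ``component_id`` labels connected components (0 = largest).
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    component_id: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValueError(f"edge weight {w} outside [0, 1] on ({a}, {b})")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str, float]], extra_nodes=()
    ) -> "WeightedGeneNetwork":
        """Build a network from a weighted edge list, labelling connected
        components by descending size (0 = largest)."""
        import igraph as ig

        nodes = sorted({g for e in edges for g in e[:2]} | set(extra_nodes))
        g = ig.Graph()
        g.add_vertices(nodes)
        g.add_edges([(a, b) for a, b, _ in edges])
        comps = g.connected_components()
        order = sorted(range(len(comps)), key=lambda i: (-len(comps[i]), i))
        rank = {old: new for new, old in enumerate(order)}
        component_id = {nodes[v]: rank[comps.membership[v]] for v in range(len(nodes))}
        return cls(nodes=nodes, edges=edges, component_id=component_id)

    def largest_component_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.component_id.get(n, 0) == 0]

    def analysis_network(self) -> "WeightedGeneNetwork":
        """Restrict to the largest connected component."""
        keep = set(self.largest_component_nodes())
        edges = [(a, b, w) for a, b, w in self.edges if a in keep and b in keep]
        return WeightedGeneNetwork(
            nodes=sorted(keep),
            edges=edges,
            component_id={n: 0 for n in keep},
        )

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph()
        g.add_vertices(self.nodes)
        if self.edges:
            g.add_edges([(a, b) for a, b, _ in self.edges])
            g.es["weight"] = [w for _, _, w in self.edges]
        return g


@dataclass
class ModulePartition:
    """Gene -> module assignment with its weighted modularity.

    Module indices are consecutive integers starting at 1, ordered by
    descending module size.
    """

    assignment: dict[str, int]
    modularity_q: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.assignment:
            idx = sorted(set(self.assignment.values()))
            if idx != list(range(1, len(idx) + 1)):
                raise ValueError("module indices must be consecutive from 1")
        if not (-0.5 - 1e-9 <= self.modularity_q <= 1.0 + 1e-9):
            raise ValueError(f"modularity {self.modularity_q} outside [-0.5, 1]")

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.assignment.values():
            out[m] = out.get(m, 0) + 1
        return dict(sorted(out.items()))

    def members(self, module: int) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == module)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "sizes": {str(k): v for k, v in self.sizes().items()},
                "modularity_q": self.modularity_q,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass
class ModuleEigengene:
    """First principal component of a module's significant sites.

    ``scores`` is a per-sample series (centered); the sign is fixed so that
    the eigengene correlates non-negatively with the module's mean beta.
    """

    module: int
    scores: pd.Series
    explained_variance: float
    sign_flipped: bool = False

    def __post_init__(self) -> None:
        scale = float(np.abs(self.scores.to_numpy()).max()) if len(self.scores) else 0.0
        if scale > 0 and abs(float(self.scores.mean())) > 1e-8 * scale:
            raise ValueError("eigengene scores must be centered")
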