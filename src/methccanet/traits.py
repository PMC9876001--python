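"""Module eigengenes, module-trait association and key-site screening.

A module eigengene (ME) is the first principal component of a module's
significant sites, summarizing the module's methylation per sample; the
sign is fixed so the ME correlates non-negatively with the module's mean
beta. Modules are associated with ordinal clinical traits (event, age,
M, N, T) by Spearman correlation. Within a trait-linked module, key sites
are screened by module membership (MM, Pearson correlation of a site with
the ME) and gene significance (GS, Spearman correlation of a site with the
trait), with strict per-module thresholds.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import dmp
from .datamodel import TRAIT_COLUMNS, BetaMatrix, ClinicalTable, ModuleEigengene

logger = logging.getLogger(__name__)

__all__ = [
    "significant_sites",
    "compute_me",
    "associate_traits",
    "screen_key_sites",
    "correlate_meth_expr",
]

#: key-site thresholds used in the study's primary module
DEFAULT_MM_THRESHOLD = 0.85
DEFAULT_GS_THRESHOLD = 0.17


def significant_sites(
    bm: BetaMatrix, groups: pd.Series | dict, alpha: float = 0.05,
    results: pd.DataFrame | None = None,
) -> list[str]:
    """Sites whose case-vs-control test has raw p < ``alpha``.

    ``alpha >= 1`` keeps every site. Precomputed per-site results from
    :func:`methccanet.dmp.test_sites` may be passed to avoid re-testing.
    """
    if alpha >= 1.0:
        return bm.site_ids
    if results is None:
        results = dmp.test_sites(bm, groups)
    res = results.set_index("site_id").reindex(bm.site_ids)
    return list(res.index[res["p_value"] < alpha])


def compute_me(bm: BetaMatrix, module_sites, module: int = 0) -> ModuleEigengene:
    """First principal component of a module's site x sample submatrix.

    Sites are the variables; scores are centered per-sample values with the
    sign convention corr(ME, per-sample mean beta of the module) >= 0.
    """
    sites = [s for s in module_sites if s in bm.values.index]
    if not sites:
        raise ValueError(f"module {module} has no sites in the beta matrix")
    X = bm.values.loc[sites].to_numpy(dtype=float).T  # samples x sites
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * S[0]
    total = float(np.sum(S**2))
    explained = float(S[0] ** 2 / total) if total > 0 else 1.0
    mean_beta = X.mean(axis=1)
    flipped = False
    cov = float(np.dot(scores - scores.mean(), mean_beta - mean_beta.mean()))
    if cov < 0:
        scores = -scores
        flipped = True
    return ModuleEigengene(
        module=module,
        scores=pd.Series(scores - scores.mean(), index=bm.sample_ids),
        explained_variance=explained,
        sign_flipped=flipped,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho, asymptotic p and n over pairwise-complete observations."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xr, yr = x[ok], y[ok]
    if np.all(xr == xr[0]) or np.all(yr == yr[0]):
        return np.nan, np.nan, n
    rho, p = stats.spearmanr(xr, yr)
    return float(rho), float(p), n


def associate_traits(
    mes: list[ModuleEigengene],
    clin: ClinicalTable,
    traits: tuple[str, ...] = tuple(TRAIT_COLUMNS),
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman association matrix between module eigengenes and traits.

    Returns a long-format table (module, trait, rho, p, n); a constant trait
    yields a missing cell with a warning. ``adjust`` adds BH-adjusted p
    across all cells.
    """
    rows = []
    for me in mes:
        samples = list(me.scores.index)
        sub = clin.table.loc[samples]
        for trait in traits:
            x = me.scores.to_numpy(dtype=float)
            y = sub[trait].to_numpy(dtype=float)
            rho, p, n = _spearman(x, y)
            if np.isnan(rho):
                warnings.warn(
                    f"trait {trait!r} is constant or too sparse for module {me.module}",
                    stacklevel=2,
                )
            rows.append({"module": me.module, "trait": trait, "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        ok = out["p"].notna()
        out.loc[ok, "p_adj"] = dmp.adjust_bh(out.loc[ok, "p"].to_numpy())
    return out


def screen_key_sites(
    bm: BetaMatrix,
    module_sites,
    me: ModuleEigengene,
    trait_values: pd.Series,
    mm_threshold: float = DEFAULT_MM_THRESHOLD,
    gs_threshold: float = DEFAULT_GS_THRESHOLD,
    mm_method: str = "pearson",
    gs_method: str = "spearman",
    annot=None,
) -> pd.DataFrame:
    """Screen a module's sites by module membership and gene significance.

    MM is the Pearson correlation of a site's beta with the module eigengene
    (WGCNA convention); GS is the Spearman correlation with the ordinal
    trait. A site passes iff |MM| > mm_threshold AND |GS| > gs_threshold
    (strict). Constant sites get missing MM/GS and fail.
    """
    samples = list(me.scores.index)
    e = me.scores.to_numpy(dtype=float)
    t = trait_values.reindex(samples).to_numpy(dtype=float)
    gene_map = annot.gene_map() if annot is not None else None
    rows = []
    for site in module_sites:
        if site not in bm.values.index:
            warnings.warn(f"site {site!r} absent from beta matrix", stacklevel=2)
            continue
        b = bm.values.loc[site, samples].to_numpy(dtype=float)
        if np.all(b == b[0]):
            mm, gs = np.nan, np.nan
        else:
            mm = _corr(b, e, mm_method)
            gs = _corr(b, t, gs_method)
        passes = bool(
            np.isfinite(mm) and np.isfinite(gs)
            and abs(mm) > mm_threshold and abs(gs) > gs_threshold
        )
        rows.append(
            {
                "site_id": site,
                "gene_symbol": gene_map.get(site) if gene_map is not None else None,
                "module": me.module,
                "mm": mm,
                "gs": gs,
                "passes": passes,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "gene_symbol", "module", "mm", "gs", "passes"])


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3 or np.all(y[ok] == y[ok][0]):
        return np.nan
    if method == "pearson":
        return float(stats.pearsonr(x[ok], y[ok])[0])
    if method == "spearman":
        return float(stats.spearmanr(x[ok], y[ok])[0])
    raise ValueError(f"unknown correlation method {method!r}")


def correlate_meth_expr(beta: pd.Series | np.ndarray, expression: pd.Series | np.ndarray) -> tuple[float, float]:
    """Spearman correlation between one site's methylation and gene expression."""
    b = np.asarray(beta, dtype=float)
    e = np.asarray(expression, dtype=float)
    if b.shape != e.shape:
        raise ValueError("methylation and expression vectors must be aligned")
    if b.size < 5:
        raise ValueError("need at least 5 paired samples")
    rho, p = stats.spearmanr(b, e)
    return float(rho), float(p)
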