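"""Per-site differential methylation between case and control groups.

Each site gets a two-sample Welch t-test (on the beta scale by default, or
on M-values), a fold change defined as the ratio of group mean betas, and a
Benjamini-Hochberg adjusted p. Differentially methylated positions (DMPs)
are the sites passing both a fold-change gate and a p-value gate; the genes
carrying at least one DMP are the differentially methylated genes (DMGs).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import BetaMatrix, SiteAnnotation

logger = logging.getLogger(__name__)

__all__ = ["test_sites", "adjust_bh", "select_dmps", "sites_to_genes"]

_MVALUE_EPS = 1e-6

#: default thresholds: |log2 FC| > |log2 0.235| and raw p < .05
DEFAULT_FC_THRESHOLD = 0.235
DEFAULT_P_THRESHOLD = 0.05


def _to_mvalue(beta: np.ndarray) -> np.ndarray:
    b = np.clip(beta, _MVALUE_EPS, 1.0 - _MVALUE_EPS)
    return np.log2(b / (1.0 - b))


def test_sites(
    bm: BetaMatrix,
    groups: pd.Series | dict,
    annot: SiteAnnotation | None = None,
    scale: str = "beta",
) -> pd.DataFrame:
    """Welch t-test of case vs control for every site.

    ``groups`` maps sample id -> "case"/"control". Group means and the fold
    change are always computed on the beta scale, whatever scale the test
    uses. Returns one row per site, in input site order, with columns
    site_id, gene_symbol, mean_case, mean_control, delta_beta, log_fc,
    t_stat, p_value, p_adj.
    """
    if scale not in ("beta", "mvalue"):
        raise ValueError(f"scale must be 'beta' or 'mvalue', got {scale!r}")
    g = pd.Series(groups)
    case_ids = [s for s in bm.sample_ids if g.get(s) == "case"]
    ctrl_ids = [s for s in bm.sample_ids if g.get(s) == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_ids)} case / {len(ctrl_ids)} control"
        )
    case = bm.values[case_ids].to_numpy(dtype=float)
    ctrl = bm.values[ctrl_ids].to_numpy(dtype=float)

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_fc = np.log2(mean_case / mean_ctrl)

    xc, xk = (case, ctrl) if scale == "beta" else (_to_mvalue(case), _to_mvalue(ctrl))
    # constant values within both groups: t undefined -> p = 1
    degenerate = (xc == xc[:, :1]).all(axis=1) & (xk == xk[:, :1]).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # scipy precision-loss chatter
        t_stat, p_value = stats.ttest_ind(xc, xk, axis=1, equal_var=False)
    degenerate |= ~np.isfinite(t_stat)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sites with zero variance in both groups; p set to 1",
            stacklevel=2,
        )
        t_stat = np.where(degenerate, 0.0, t_stat)
        p_value = np.where(degenerate, 1.0, p_value)

    res = pd.DataFrame(
        {
            "site_id": bm.site_ids,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "delta_beta": mean_case - mean_ctrl,
            "log_fc": log_fc,
            "t_stat": t_stat,
            "p_value": p_value,
        }
    )
    res["p_adj"] = adjust_bh(res["p_value"].to_numpy())
    gene_col = (
        annot.gene_map().reindex(res["site_id"]).to_numpy() if annot is not None else None
    )
    res.insert(1, "gene_symbol", gene_col)
    return res


# despite the name, this is a library function, not a pytest case
test_sites.__test__ = False


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_dmps(
    results: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_adjusted: bool = False,
    fc_mode: str = "ratio",
) -> pd.DataFrame:
    """Flag differentially methylated positions and return the flagged subset.

    The fold-change gate is |log2 FC| > |log2 fc_threshold| with FC the
    case/control beta ratio (``fc_mode="ratio"``, default) or
    |delta beta| > fc_threshold (``fc_mode="delta"``). The p gate uses the
    raw p by default (``use_adjusted`` switches to BH-adjusted p); both
    gates are strict inequalities.
    """
    if fc_mode == "ratio":
        gate_fc = np.abs(results["log_fc"]) > abs(np.log2(fc_threshold))
    elif fc_mode == "delta":
        gate_fc = np.abs(results["delta_beta"]) > fc_threshold
    else:
        raise ValueError(f"fc_mode must be 'ratio' or 'delta', got {fc_mode!r}")
    p = results["p_adj"] if use_adjusted else results["p_value"]
    flagged = results.loc[gate_fc.fillna(False) & (p < p_threshold)].copy()
    flagged["is_dmp"] = True
    return flagged


def sites_to_genes(dmps: pd.DataFrame, annot: SiteAnnotation) -> set[str]:
    """Unique gene symbols of the flagged sites; unannotated sites are dropped."""
    gene_map = annot.gene_map()
    genes: set[str] = set()
    n_unmapped = 0
    for site in dmps["site_id"]:
        if site in gene_map.index:
            genes.add(gene_map[site])
        else:
            n_unmapped += 1
    if n_unmapped:
        warnings.warn(f"{n_unmapped} flagged sites without gene annotation", stacklevel=2)
    return genes
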