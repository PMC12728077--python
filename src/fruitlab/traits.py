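"""Correlation analysis between colour parameters and DUS characteristics.

The trait matrix holds 16 variables per accession: the accession-mean
L*, a*, b* at harvest maturity (H-) and physiological ripeness (P-) and
the ten ordinal DUS notes.  Ordinal notes enter the Pearson correlation
as numeric scores; a Spearman option is available.  IFC is recorded only
for green and purple accessions, so correlations are pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TRAIT_ORDER", "DUS_TRAITS", "build_trait_matrix", "CorrelationResult", "pearson_matrix"]

DUS_TRAITS = ("ACH", "ACS", "ILG", "ACL", "FC", "FPC", "FSCH", "IFC", "FG", "FSCP")
TRAIT_ORDER = ("H-L*", "H-a*", "H-b*", "P-L*", "P-a*", "P-b*") + DUS_TRAITS


def build_trait_matrix(measurements: pd.DataFrame, dus: pd.DataFrame) -> pd.DataFrame:
    """Accession × 16 trait matrix from fruit measurements and DUS notes.

    Colour parameters are replicate means per accession and stage.
    """
    acc = measurements.groupby(["accession", "stage"])[["L", "a", "b"]].mean().unstack("stage")
    out = pd.DataFrame(index=acc.index)
    for stage in ("H", "P"):
        for ax in ("L", "a", "b"):
            col = f"{stage}-{ax}*"
            out[col] = acc[(ax, stage)] if (ax, stage) in acc.columns else np.nan
    d = dus.set_index("accession")
    for tr in DUS_TRAITS:
        out[tr] = d[tr] if tr in d.columns else np.nan
    return out[list(TRAIT_ORDER)]


@dataclass
class CorrelationResult:
    """Pairwise-complete correlation matrices with significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean, p < alpha (off-diagonal)
    n: pd.DataFrame  # per-pair complete observations
    alpha: float
    method: str


def pearson_matrix(m: pd.DataFrame, alpha: float = 0.05, method: str = "pearson",
                   fdr: bool = False, min_pairs: int = 3) -> CorrelationResult:
    """All-pairs correlation of a trait matrix.

    Pairwise-complete observations; two-sided p from the t transform
    t = r·sqrt((n−2)/(1−r²)) on n−2 df.  Pairs with a constant column or
    fewer than ``min_pairs`` complete rows are recorded as missing (NaN),
    never as zero.  ``fdr=True`` applies Benjamini–Hochberg across the
    off-diagonal pairs before masking at ``alpha``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cols = list(m.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n, m.notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            x, y = m[cols[i]], m[cols[j]]
            ok = x.notna() & y.notna()
            nn = int(ok.sum())
            n[i, j] = n[j, i] = nn
            xv, yv = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
            if nn < min_pairs or np.std(xv) == 0 or np.std(yv) == 0:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                continue
            if method == "pearson":
                rr, pp = stats.pearsonr(xv, yv)
            else:
                rr, pp = stats.spearmanr(xv, yv)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    pv = p.copy()
    if fdr:
        iu = np.triu_indices(k, 1)
        flat = p[iu]
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        pv[iu] = adj
        pv.T[iu] = adj
    sig = np.where(np.isfinite(pv), pv < alpha, False)
    np.fill_diagonal(sig, False)
    f = lambda a, dtype=float: pd.DataFrame(a, index=cols, columns=cols).astype(dtype)  # noqa: E731
    return CorrelationResult(f(r), f(pv), f(sig, bool), f(n, int), alpha, method)
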