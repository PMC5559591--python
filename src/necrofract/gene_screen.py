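"""Lacunarity-correlated gene screen and gene-set enrichment.

The screen selects genes whose expression has sample Pearson correlation
r > 0.3 with patient lacunarity — positive correlations only by default,
since the biological question concerns genes up-regulated with gappier
necrosis; an absolute-value mode is available as a switch. Expression
values are used as provided (an optional log2(x+1) transform is off by
default).

Enrichment of the selected genes against user-supplied GMT gene sets uses
the one-sided hypergeometric upper-tail test with Benjamini-Hochberg
adjustment across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from necrofract.errors import AlignmentError, ParameterError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_screen",
    "gene_correlations",
    "enrich",
    "correlate_features",
]


def gene_correlations(expr: pd.DataFrame, lacunarity: pd.Series | np.ndarray) -> pd.Series:
    """Sample Pearson r of every gene (row) against the lacunarity vector.

    Zero-variance genes get NaN (excluded downstream with a log entry).
    """
    if isinstance(lacunarity, pd.Series):
        if set(expr.columns) != set(lacunarity.index.astype(str)) and set(
            expr.columns
        ) != set(lacunarity.index):
            raise AlignmentError("expression columns and lacunarity index disagree")
        lac = lacunarity.reindex(expr.columns).to_numpy(float)
    else:
        lac = np.asarray(lacunarity, float)
        if lac.size != expr.shape[1]:
            raise AlignmentError(
                f"{expr.shape[1]} expression columns vs {lac.size} lacunarity values"
            )
    if lac.size < 3:
        raise ParameterError("at least 3 patients are required")
    if np.std(lac) == 0:
        raise UndefinedCorrelationError("lacunarity vector has zero variance")

    values = expr.to_numpy(float)
    vc = values - values.mean(axis=1, keepdims=True)
    lc = lac - lac.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (vc @ lc) / denom, np.nan)
    return pd.Series(r, index=expr.index, name="r")


def pearson_screen(
    expr: pd.DataFrame,
    lacunarity: pd.Series | np.ndarray,
    r_threshold: float = 0.3,
    absolute: bool = False,
) -> pd.DataFrame:
    """Select genes with r > ``r_threshold`` against lacunarity.

    Strictly positive rule by default (``absolute=True`` switches to
    ``|r| > r_threshold``). Returns a table (gene_id, r) sorted by
    descending r; zero-variance genes are logged and excluded.
    """
    r = gene_correlations(expr, lacunarity)
    n_dropped = int(r.isna().sum())
    if n_dropped:
        logger.warning("excluding %d zero-variance genes from the screen", n_dropped)
    r = r.dropna()
    keep = (r.abs() > r_threshold) if absolute else (r > r_threshold)
    out = r[keep].sort_values(ascending=False).reset_index()
    out.columns = ["gene_id", "r"]
    return out


def enrich(
    selected: list[str],
    sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    Sets are intersected with the universe; p is the one-sided upper-tail
    hypergeometric probability of an overlap at least as large as
    observed; q is the Benjamini-Hochberg adjustment across sets. Rows are
    ordered by (q, set name) for determinism.
    """
    universe_set = set(universe)
    selected_set = set(selected)
    if not universe_set or not selected_set:
        raise ParameterError("selection and universe must be non-empty")
    if not selected_set <= universe_set:
        raise ParameterError("selected genes must be a subset of the universe")
    M = len(universe_set)
    n_sel = len(selected_set)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & universe_set
        if not members:
            logger.warning("gene set %s has no members in the universe; skipped", name)
            continue
        k = len(members & selected_set)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_sel))
        rows.append({"set": name, "overlap": k, "size": len(members), "p": min(p, 1.0)})
    if not rows:
        raise ParameterError("no gene set overlaps the universe")
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["q", "set"], kind="mergesort").reset_index(drop=True)


def correlate_features(x, y) -> tuple[float, float]:
    """Sample Pearson r between two per-patient vectors with a two-sided p.

    Used to report the FD-lacunarity association of a cohort.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
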