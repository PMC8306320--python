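"""Environment statistics: normality screening, correlation tables,
keystone-taxon x chemistry networks, and ANOVA with Fisher's LSD.

Environmental variables are screened with Shapiro–Wilk and log-transformed
when non-normal, following common practice for water-chemistry data.
Correlations are Pearson with pairwise deletion of missing values;
significance convention is p <= 0.05 with no table-wide FDR (FDR is
reserved for network edges).
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix, CoNetwork

logger = logging.getLogger(__name__)


def normality_transform(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shapiro–Wilk screen each numeric column; log-transform non-normal ones.

    Transformed columns use log(x + shift), shift = 0 when min > 0 else
    |min| + a machine-safe epsilon. Returns the transformed table and a
    per-variable report (W, p, decision, shift). Constant columns are
    skipped with a log entry.
    """
    out = table.copy()
    report = {}
    for col in table.columns:
        x = pd.to_numeric(table[col], errors="coerce").dropna()
        if x.nunique() <= 1:
            logger.warning("skipping constant variable %r in normality screen", col)
            report[col] = {"W": np.nan, "p": np.nan, "transformed": False, "shift": 0.0}
            continue
        w, p = stats.shapiro(x)
        transformed = p < alpha
        shift = 0.0
        if transformed:
            mn = x.min()
            if mn <= 0:
                shift = abs(mn) + np.sqrt(np.finfo(float).eps)
            out[col] = np.log(pd.to_numeric(table[col], errors="coerce") + shift)
        report[col] = {"W": float(w), "p": float(p), "transformed": bool(transformed), "shift": shift}
    return out, pd.DataFrame.from_dict(report, orient="index")


def correlate(
    left: pd.DataFrame, right: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson correlation of every left column against every right column.

    Rows are aligned on the shared index; missing values are removed
    pairwise, so dropping a sample only affects cells it participated in.
    Cells with fewer than ``min_n`` complete pairs are reported empty.
    Returns a long-format table: row, column, r, p, n, significant.
    """
    idx = left.index.intersection(right.index)
    rows = []
    for a in left.columns:
        xa = pd.to_numeric(left.loc[idx, a], errors="coerce")
        for b in right.columns:
            xb = pd.to_numeric(right.loc[idx, b], errors="coerce")
            ok = xa.notna() & xb.notna()
            n = int(ok.sum())
            if n < min_n or xa[ok].nunique() <= 1 or xb[ok].nunique() <= 1:
                rows.append({"row": a, "column": b, "r": np.nan, "p": np.nan,
                             "n": n, "significant": False})
                continue
            r, p = stats.pearsonr(xa[ok], xb[ok])
            rows.append({"row": a, "column": b, "r": float(r), "p": float(p),
                         "n": n, "significant": bool(p <= 0.05)})
    return pd.DataFrame(rows)


def correlation_matrix(long: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot a long-format correlation table to a matrix."""
    return long.pivot(index="row", columns="column", values=value)


def keystone_env_network(
    keystones: list[str],
    matrix: AbundanceMatrix,
    env: pd.DataFrame,
    r_min: float = 0.8,
    alpha: float = 0.05,
) -> CoNetwork:
    """Bipartite keystone-taxon x environmental-variable correlation network.

    An edge joins a keystone taxon and a variable when |Pearson r| >= r_min
    and p <= alpha on the shared samples; edge sign follows r.
    """
    g = nx.Graph()
    if not keystones:
        logger.warning("no keystone taxa; returning empty keystone-environment network")
        return CoNetwork(g)
    rel = matrix.relative_abundance()
    present = [k for k in keystones if k in rel.columns]
    long = correlate(rel[present], env)
    for row in long.itertuples(index=False):
        if np.isnan(row.r) or abs(row.r) < r_min or row.p > alpha:
            continue
        g.add_edge(row.row, row.column, sign=int(np.sign(row.r)),
                   correlation=row.r, q_value=row.p)
        g.nodes[row.row]["kind"] = "taxon"
        g.nodes[row.column]["kind"] = "environment"
    if g.number_of_edges() == 0:
        logger.info("keystone-environment network is empty at r_min=%.2f", r_min)
    return CoNetwork(g)


def edge_sign_ratio(net: CoNetwork) -> dict:
    """Positive and negative edge counts and their ratio summary."""
    pos, neg = net.edge_signs()
    return {"positive": pos, "negative": neg,
            "neg_over_pos": neg / pos if pos else None}


def group_compare(values: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA with Fisher's LSD post hoc comparisons.

    LSD pairwise p-values use the pooled within-group variance (MSE) and
    its degrees of freedom, with no additional multiplicity correction
    (the LSD convention). Groups with a single observation are excluded
    with a warning.
    """
    df = pd.DataFrame({"y": pd.to_numeric(values, errors="coerce"), "g": groups}).dropna()
    sizes = df.groupby("g")["y"].size()
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        logger.warning("excluding single-observation groups from ANOVA: %s", singletons)
        df = df[~df["g"].isin(singletons)]
    levels = sorted(df["g"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    arrays = [df.loc[df["g"] == lv, "y"].to_numpy() for lv in levels]
    f_stat, p_value = stats.f_oneway(*arrays)

    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within

    pairwise = []
    for (i, a), (j, b) in combinations(enumerate(arrays), 2):
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        t = diff / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(t), df_within)
        pairwise.append({"group_a": levels[i], "group_b": levels[j],
                         "diff": float(diff), "t": float(t), "p": float(p)})
    return {"F": float(f_stat), "p": float(p_value), "df_within": df_within,
            "mse": float(mse), "pairwise": pd.DataFrame(pairwise)}
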