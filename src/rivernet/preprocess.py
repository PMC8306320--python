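"""Rarefaction, low-count filtering and alpha-diversity summaries.

Rarefaction subsamples each sample's reads without replacement
(hypergeometric) to a common depth, removing library-size effects before
diversity and network analyses. Chao1 defaults to the bias-corrected
estimator S_obs + F1(F1-1)/(2(F2+1)); Shannon is reported in nats.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha

from .io import AbundanceMatrix

logger = logging.getLogger(__name__)


def rarefy(matrix: AbundanceMatrix, depth: int, seed: int = 0) -> AbundanceMatrix:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning. One draw per call; deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = matrix.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in matrix.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    rows = []
    for s in keep:
        counts = matrix.counts.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    sub = pd.DataFrame(rows, index=keep, columns=matrix.counts.columns)
    sd = matrix.sample_data.loc[keep] if matrix.sample_data is not None else None
    return AbundanceMatrix(sub, taxonomy=matrix.taxonomy, sample_data=sd, attrs=dict(matrix.attrs))


def filter_taxa(matrix: AbundanceMatrix, min_total: int = 30) -> AbundanceMatrix:
    """Keep taxa whose summed count across the matrix is at least ``min_total``.

    Column order is preserved. The default of 30 reads mirrors the usual
    prefilter applied before co-occurrence network construction.
    """
    if min_total < 0:
        raise ValueError("min_total must be nonnegative")
    totals = matrix.counts.sum(axis=0)
    keep = [t for t in matrix.taxon_ids if totals[t] >= min_total]
    if not keep:
        logger.warning("filter_taxa removed every taxon (min_total=%d)", min_total)
    return matrix.subset_taxa(keep)


def alpha_diversity(matrix: AbundanceMatrix, chao1_bias_corrected: bool = True,
                    shannon_base: float = np.e) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon and Good's coverage.

    Returns a DataFrame with columns ``observed_otus``, ``chao1``,
    ``shannon``, ``goods_coverage``. Chao1 uses the bias-corrected form by
    default; Shannon defaults to nats (natural log).
    """
    rows = {}
    for s in matrix.sample_ids:
        counts = matrix.counts.loc[s].to_numpy()
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sample {s!r} has zero total count")
        f1 = int((counts == 1).sum())
        rows[s] = {
            "observed_otus": int((counts > 0).sum()),
            "chao1": float(_alpha.chao1(counts, bias_corrected=chao1_bias_corrected)),
            "shannon": float(_alpha.shannon(counts, base=shannon_base)),
            "goods_coverage": 1.0 - f1 / total,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[matrix.sample_ids]
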