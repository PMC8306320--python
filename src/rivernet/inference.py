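"""Ensemble co-occurrence network inference.

Association between every unordered taxon pair is scored with four
measures on per-sample relative abundances — Spearman and Pearson
correlation, Bray–Curtis dissimilarity and symmetrized Kullback–Leibler
divergence on per-taxon profiles. Significance comes from a permutation
null (each taxon shuffled independently across samples), with
Benjamini–Hochberg FDR control applied per measure. An edge enters the
network only when a rank/linear correlation exceeds the strength threshold
(|r| > 0.8 by default) and at least ``min_support`` measures are
significant with a direction concordant with the edge sign. Signs come
from the rank correlation (Pearson breaking ties); the dissimilarity
measures contribute support only — smaller-than-null BC/KL means
co-presence (positive direction), larger-than-null means exclusion
(negative).

Measures are computed on relative abundances without a compositionally
corrected null (no ReBoot-style renormalized bootstrap); this is a known
limitation on strongly compositional data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix, CoNetwork

logger = logging.getLogger(__name__)

MEASURES = ("spearman", "pearson", "braycurtis", "kl")
CORRELATION_MEASURES = ("spearman", "pearson")
DISSIMILARITY_MEASURES = ("braycurtis", "kl")


@dataclass
class InferenceConfig:
    r_threshold: float = 0.8
    alpha_fdr: float = 0.05
    n_permutations: int = 1000
    min_support: int = 2
    min_taxon_total: int = 30
    kl_pseudocount: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0.0 < self.alpha_fdr < 1.0:
            raise ValueError("alpha_fdr must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if not 1 <= self.min_support <= 4:
            raise ValueError("min_support must be between 1 and 4")


@dataclass
class PairwiseStats:
    """All four T x T association matrices plus the valid-pair mask."""

    taxa: list[str]
    stats: dict[str, np.ndarray]
    valid: np.ndarray  # boolean T x T; False where a constant taxon is involved
    rel_abundance: np.ndarray = field(repr=False, default=None)
    profiles: np.ndarray = field(repr=False, default=None)  # KL profiles (samples x taxa)
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    pvalues: dict[str, np.ndarray]
    direction: dict[str, np.ndarray]  # +1 co-presence / -1 exclusion, dissimilarities only


def _kl_profiles(rel: np.ndarray, pseudocount: float) -> np.ndarray:
    """Per-taxon probability profiles over samples, pseudocounted."""
    prof = rel + pseudocount
    return prof / prof.sum(axis=0, keepdims=True)


def _cross_stats(
    zx: np.ndarray,
    zy: np.ndarray,
    rx: np.ndarray,
    ry: np.ndarray,
    relx: np.ndarray,
    rely: np.ndarray,
    profx: np.ndarray,
    profy: np.ndarray,
) -> dict[str, np.ndarray]:
    """T x T matrices of the four measures between column sets x and y.

    ``z*`` are z-scored relative abundances, ``r*`` z-scored ranks,
    ``rel*`` raw relative abundances, ``prof*`` KL profiles.
    """
    n = zx.shape[0]
    pearson = zx.T @ zy / n
    spearman = rx.T @ ry / n
    # Bray-Curtis: sum |x-y| / sum (x+y), elementwise over samples
    num = np.abs(relx[:, :, None] - rely[:, None, :]).sum(axis=0)
    den = relx.sum(axis=0)[:, None] + rely.sum(axis=0)[None, :]
    braycurtis = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    # symmetrized KL via log-profile matmuls:
    # 0.5 [ H(x,x) + H(y,y) - x.log y - y.log x ] with H self cross-entropies
    logx, logy = np.log(profx), np.log(profy)
    ex = (profx * logx).sum(axis=0)
    ey = (profy * logy).sum(axis=0)
    kl = 0.5 * (ex[:, None] + ey[None, :] - profx.T @ logy - logx.T @ profy)
    return {"spearman": spearman, "pearson": pearson, "braycurtis": braycurtis, "kl": kl}


def _zscore(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.where(ok, x - mu, 0.0)
    z = np.divide(z, sd, out=np.zeros_like(z), where=ok)
    return z, ok


def pairwise_measures(matrix: AbundanceMatrix, kl_pseudocount: float = 1e-6) -> PairwiseStats:
    """Compute all four association measures for every unordered taxon pair.

    Taxa with zero variance across samples have their correlation-based
    pairs marked invalid (excluded from testing) with a log entry.
    """
    if matrix.n_samples < 4:
        raise ValueError(f"need at least 4 samples, got {matrix.n_samples}")
    rel = matrix.relative_abundance().to_numpy(dtype=float)
    z, ok = _zscore(rel)
    ranks = np.column_stack([rankdata(rel[:, j]) for j in range(rel.shape[1])])
    rz, _ = _zscore(ranks)
    prof = _kl_profiles(rel, kl_pseudocount)
    stats = _cross_stats(z, z, rz, rz, rel, rel, prof, prof)
    # clip tiny numerical overshoots of |r| <= 1
    for m in CORRELATION_MEASURES:
        np.clip(stats[m], -1.0, 1.0, out=stats[m])
    valid = np.outer(ok, ok)
    np.fill_diagonal(valid, False)
    if not ok.all():
        bad = [t for t, o in zip(matrix.taxon_ids, ok) if not o]
        logger.warning("constant taxa excluded from pair tests: %s", bad)
    return PairwiseStats(list(matrix.taxon_ids), stats, valid, rel, prof,
                         list(matrix.sample_ids))


def permutation_pvalues(
    stats: PairwiseStats, n_permutations: int = 1000, seed: int = 0
) -> PermutationResult:
    """Permutation p-values per pair and measure.

    The null permutes each taxon's values independently across samples;
    cross-statistics between the permuted and the observed matrix give, for
    pair (i, j), the null distribution of taxon i shuffled against taxon j.
    P-values use the add-one estimator (b + 1)/(B + 1), so none is exactly
    zero: correlations two-sided, dissimilarities as the smaller of the two
    one-sided tails with its direction recorded (+1 smaller-than-null BC/KL
    = co-presence; -1 = exclusion).

    The matrix is put into canonical (sorted-id) order before permuting, so
    the result is exactly invariant to sample and taxon ordering.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    rng = np.random.default_rng(seed)
    row_order = np.argsort(stats.sample_ids) if stats.sample_ids else np.arange(
        stats.rel_abundance.shape[0])
    col_order = np.argsort(stats.taxa)
    col_inverse = np.argsort(col_order)
    rel = stats.rel_abundance[np.ix_(row_order, col_order)]
    prof = stats.profiles[np.ix_(row_order, col_order)]
    n, t = rel.shape
    z, _ = _zscore(rel)
    ranks = np.column_stack([rankdata(rel[:, j]) for j in range(t)])
    rz, _ = _zscore(ranks)

    obs = {m: a[np.ix_(col_order, col_order)] for m, a in stats.stats.items()}
    obs_abs = {m: np.abs(obs[m]) for m in CORRELATION_MEASURES}
    exceed = {m: np.zeros((t, t)) for m in CORRELATION_MEASURES}
    count_low = {m: np.zeros((t, t)) for m in DISSIMILARITY_MEASURES}
    count_high = {m: np.zeros((t, t)) for m in DISSIMILARITY_MEASURES}

    for _ in range(n_permutations):
        perm = np.argsort(rng.random((n, t)), axis=0)  # independent per-column shuffles
        rows = perm
        cols = np.broadcast_to(np.arange(t), (n, t))
        zp = z[rows, cols]
        rzp = rz[rows, cols]
        relp = rel[rows, cols]
        profp = prof[rows, cols]
        null = _cross_stats(zp, z, rzp, rz, relp, rel, profp, prof)
        for m in CORRELATION_MEASURES:
            exceed[m] += np.abs(null[m]) >= obs_abs[m]
        for m in DISSIMILARITY_MEASURES:
            count_low[m] += null[m] <= obs[m]
            count_high[m] += null[m] >= obs[m]

    pvalues: dict[str, np.ndarray] = {}
    direction: dict[str, np.ndarray] = {}
    B = n_permutations
    back = np.ix_(col_inverse, col_inverse)
    for m in CORRELATION_MEASURES:
        p = (exceed[m] + 1.0) / (B + 1.0)
        pvalues[m] = (0.5 * (p + p.T))[back]  # symmetrize (i-vs-j and j-vs-i)
    for m in DISSIMILARITY_MEASURES:
        lo = 0.5 * (count_low[m] + count_low[m].T)
        hi = 0.5 * (count_high[m] + count_high[m].T)
        p_lo = (lo + 1.0) / (B + 1.0)
        p_hi = (hi + 1.0) / (B + 1.0)
        direction[m] = np.where(p_lo <= p_hi, 1, -1)[back]
        pvalues[m] = np.minimum(p_lo, p_hi)[back]
    return PermutationResult(pvalues, direction)


def build_network(
    matrix: AbundanceMatrix,
    stats: PairwiseStats,
    perms: PermutationResult,
    config: InferenceConfig,
) -> CoNetwork:
    """Assemble the signed network from statistics and permutation p-values.

    Per-measure Benjamini–Hochberg q-values are computed over all tested
    pairs; an edge is kept iff a correlation measure exceeds the strength
    threshold, at least ``min_support`` measures are significant at
    ``alpha_fdr`` with direction concordant with the edge sign, and the
    edge sign comes from Spearman (Pearson as tie-breaker when its
    magnitude is at least as large and its sign differs). Isolated nodes
    are dropped.
    """
    t = len(stats.taxa)
    iu = np.triu_indices(t, k=1)
    tested = stats.valid[iu]
    qvals: dict[str, np.ndarray] = {}
    for m in MEASURES:
        q = np.full(len(iu[0]), np.nan)
        p = perms.pvalues[m][iu]
        if tested.any():
            _, q_bh, _, _ = multipletests(p[tested], alpha=config.alpha_fdr, method="fdr_bh")
            q[tested] = q_bh
        qvals[m] = q

    rel_mean = matrix.relative_abundance().mean(axis=0)
    phylum = {}
    if matrix.taxonomy is not None and "phylum" in matrix.taxonomy.columns:
        phylum = matrix.taxonomy["phylum"].to_dict()

    g = nx.Graph()
    sp = stats.stats["spearman"][iu]
    pe = stats.stats["pearson"][iu]
    for k in range(len(iu[0])):
        if not tested[k]:
            continue
        if max(abs(sp[k]), abs(pe[k])) <= config.r_threshold:
            continue
        # edge sign: Spearman authoritative, Pearson breaks ties
        sign = int(np.sign(sp[k]))
        if sign == 0 or (abs(sp[k]) <= abs(pe[k]) and np.sign(pe[k]) != sign):
            sign = int(np.sign(pe[k]))
        if sign == 0:
            continue
        i, j = iu[0][k], iu[1][k]
        support = 0
        support_q = []
        for m in CORRELATION_MEASURES:
            r = stats.stats[m][i, j]
            if qvals[m][k] <= config.alpha_fdr and np.sign(r) == sign:
                support += 1
                support_q.append(qvals[m][k])
        for m in DISSIMILARITY_MEASURES:
            if qvals[m][k] <= config.alpha_fdr and perms.direction[m][i, j] == sign:
                support += 1
                support_q.append(qvals[m][k])
        if support < config.min_support:
            continue
        a, b = stats.taxa[i], stats.taxa[j]
        corr = sp[k] if abs(sp[k]) > config.r_threshold else pe[k]
        if int(np.sign(corr)) != sign:
            continue  # threshold passed only by the measure disagreeing in sign
        g.add_edge(
            a,
            b,
            sign=sign,
            correlation=float(corr),
            support=int(support),
            q_value=float(max(support_q)),
        )
    for node in g.nodes:
        g.nodes[node]["phylum"] = phylum.get(node, "unclassified")
        g.nodes[node]["mean_abundance"] = float(rel_mean[node])
    return CoNetwork(g)


def infer_network(matrix: AbundanceMatrix, config: InferenceConfig | None = None) -> CoNetwork:
    """Full inference pipeline: measures -> permutation null -> FDR -> network."""
    config = config or InferenceConfig()
    stats = pairwise_measures(matrix, kl_pseudocount=config.kl_pseudocount)
    perms = permutation_pvalues(stats, config.n_permutations, config.seed)
    return build_network(matrix, stats, perms, config)
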