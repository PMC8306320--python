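"""Synthetic community generators with known ground truth.

Two community models are emulated:

* *Planted-block* communities — groups of taxa share a latent Gaussian
  factor on the log-abundance scale, giving controllable pairwise rank
  correlation inside each block; a chosen fraction of within-block pairs is
  made negative by flipping factor loadings. Latent abundances pass through
  a softmax and multinomial sampling, so the tables are compositional
  counts like real 16S data.
* *Neutral* communities — each sample's taxon proportions are drawn from
  the Beta latent implied by Sloan's neutral model, Beta(N_T m p,
  N_T m (1-p)) for a taxon of source relative abundance p, followed by
  multinomial sampling at the fixed depth. This matches the fitted model's
  own assumptions, which is exactly what parameter-recovery tests need.

Environmental covariates and land-use tables spanning a human-activity
gradient are generated alongside, so the full downstream pipeline is
exercisable without any sequencing data. Sequencing error, chimeras and
taxonomy-assignment noise are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LANDUSE_CLASSES, AbundanceMatrix, LandUseTable


@dataclass
class PlantedDesign:
    """Design for a planted-correlation-block community."""

    n_samples: int = 60
    n_taxa: int = 60
    block_sizes: tuple[int, ...] = (10, 10)
    within_block_corr: float = 0.9
    frac_negative: float = 0.0
    depth: int = 57_068
    seed: int = 0
    #: spread of per-taxon baseline log-abundances (log-normal heterogeneity)
    base_sigma: float = 0.5
    #: scale of the latent log-abundance fluctuations
    latent_sigma: float = 1.0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) > self.n_taxa:
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)} > n_taxa={self.n_taxa}"
            )
        if not 0.0 <= self.within_block_corr <= 1.0:
            raise ValueError("within_block_corr must be in [0, 1]")
        if not 0.0 <= self.frac_negative <= 1.0:
            raise ValueError("frac_negative must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class NeutralDesign:
    """Design for a neutrally assembled community with known migration rate."""

    n_samples: int = 50
    n_taxa: int = 500
    m_true: float = 0.3
    depth: int = 10_000
    source_abundances: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.m_true <= 1.0:
            raise ValueError("m_true must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.source_abundances is not None:
            p = np.asarray(self.source_abundances, dtype=float)
            if (p < 0).any():
                raise ValueError("source_abundances must be nonnegative")
            if not np.isclose(p.sum(), 1.0, atol=1e-8):
                raise ValueError("source_abundances must sum to 1")
            if p.size != self.n_taxa:
                raise ValueError("source_abundances length must equal n_taxa")


def _block_membership(design: PlantedDesign) -> np.ndarray:
    """Block index per taxon; -1 for background taxa."""
    member = np.full(design.n_taxa, -1, dtype=int)
    start = 0
    for b, size in enumerate(design.block_sizes):
        member[start : start + size] = b
        start += size
    return member


def _negative_loading_count(block_size: int, frac_negative: float) -> int:
    """Number of sign-flipped taxa giving the requested fraction of negative pairs.

    Flipping k of n loadings makes k(n-k) of the n(n-1)/2 within-block pairs
    negative; pick the k whose realized fraction is closest to the request.
    """
    if frac_negative == 0 or block_size < 2:
        return 0
    n_pairs = block_size * (block_size - 1) / 2
    ks = np.arange(block_size // 2 + 1)
    realized = ks * (block_size - ks) / n_pairs
    return int(ks[np.argmin(np.abs(realized - frac_negative))])


def generate_planted_counts(design: PlantedDesign) -> AbundanceMatrix:
    """Generate a compositional count table with planted correlation blocks.

    Taxa within a block load on a shared standard-normal factor. The factor
    loading is chosen so the latent pairwise *Spearman* correlation equals
    ``within_block_corr``: for a Gaussian copula the rank correlation of a
    pair with Pearson correlation rho is (6/pi) asin(rho/2), so the latent
    Pearson target is 2 sin(pi c / 6). Ground truth (block membership,
    factors, loading signs, pre-softmax latents) is stored in ``attrs`` for
    downstream recovery tests.
    """
    rng = np.random.default_rng(design.seed)
    n, t = design.n_samples, design.n_taxa
    member = _block_membership(design)
    n_blocks = len(design.block_sizes)

    pearson_target = 2.0 * np.sin(np.pi * design.within_block_corr / 6.0)
    loading = np.sqrt(pearson_target)
    loading_sign = np.ones(t)
    for b, size in enumerate(design.block_sizes):
        k = _negative_loading_count(size, design.frac_negative)
        idx = np.flatnonzero(member == b)[:k]
        loading_sign[idx] = -1.0

    factors = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, t))
    base = rng.normal(0.0, design.base_sigma, size=t)

    z = noise.copy()
    for j in range(t):
        b = member[j]
        if b >= 0:
            z[:, j] = loading * loading_sign[j] * factors[:, b] + np.sqrt(
                max(0.0, 1.0 - pearson_target)
            ) * noise[:, j]
    log_abund = base[None, :] + design.latent_sigma * z
    # softmax per sample -> compositional relative abundances
    shifted = log_abund - log_abund.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(design.depth, probs[i]) for i in range(n)])

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    taxon_ids = [f"OTU{j + 1:04d}" for j in range(t)]
    phyla = [f"Phylum_block{member[j] + 1}" if member[j] >= 0 else "Phylum_bg" for j in range(t)]
    taxonomy = pd.DataFrame({"phylum": phyla}, index=pd.Index(taxon_ids, name="taxon"))
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    return AbundanceMatrix(
        counts_df,
        taxonomy=taxonomy,
        attrs={
            "design": design,
            "block_membership": dict(zip(taxon_ids, member)),
            "block_factors": pd.DataFrame(
                factors, index=sample_ids, columns=[f"block{b + 1}" for b in range(n_blocks)]
            ),
            "loading_sign": dict(zip(taxon_ids, loading_sign)),
            "latent_log_abundance": pd.DataFrame(log_abund, index=sample_ids, columns=taxon_ids),
        },
    )


def planted_pairs(matrix: AbundanceMatrix) -> list[tuple[str, str, int]]:
    """Within-block taxon pairs with their planted association sign."""
    member = matrix.attrs["block_membership"]
    sign = matrix.attrs["loading_sign"]
    taxa = matrix.taxon_ids
    pairs = []
    for i, a in enumerate(taxa):
        if member[a] < 0:
            continue
        for b in taxa[i + 1 :]:
            if member[b] == member[a]:
                pairs.append((a, b, int(sign[a] * sign[b])))
    return pairs


def generate_neutral_counts(design: NeutralDesign) -> AbundanceMatrix:
    """Generate counts from Sloan's neutral model at known (N_T, m).

    A taxon with source relative abundance p has per-sample latent proportion
    drawn from Beta(N_T m p, N_T m (1-p)); proportions are renormalized and
    counts drawn by multinomial sampling at the design depth. Taxa with p = 0
    are never observed.
    """
    rng = np.random.default_rng(design.seed)
    n, t = design.n_samples, design.n_taxa
    if design.source_abundances is None:
        # log-series-like skewed source pool, typical of 16S surveys
        raw = rng.lognormal(mean=0.0, sigma=1.5, size=t)
        p = raw / raw.sum()
    else:
        p = np.asarray(design.source_abundances, dtype=float)

    nm = design.depth * design.m_true
    a = nm * p
    b = nm * (1.0 - p)
    latent = np.zeros((n, t))
    pos = p > 0
    latent[:, pos] = rng.beta(a[pos], b[pos], size=(n, pos.sum()))
    row_sums = latent.sum(axis=1, keepdims=True)
    probs = np.divide(latent, row_sums, out=np.zeros_like(latent), where=row_sums > 0)
    counts = np.vstack([rng.multinomial(design.depth, probs[i]) for i in range(n)])

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    taxon_ids = [f"OTU{j + 1:04d}" for j in range(t)]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    return AbundanceMatrix(
        counts_df,
        attrs={"design": design, "source_abundances": pd.Series(p, index=taxon_ids)},
    )


def generate_env_table(
    matrix: AbundanceMatrix,
    linked_block: int,
    strength: float,
    variable_names: list[str],
    seed: int = 0,
    n_noise_vars: int = 0,
) -> pd.DataFrame:
    """Environmental variables tied to one planted block's abundance signal.

    The anchor is the standardized block-mean relative abundance (the
    realized common signal of the block's taxa — the latent factor as it
    survives compositional closure and count noise). Each named variable is
    ``strength * anchor + sqrt(1-strength^2) * noise``, so its correlation
    with the observed block-mean abundance equals ``strength`` in
    expectation. ``n_noise_vars`` extra independent standard-normal columns
    (named noise1, noise2, ...) are appended.
    """
    if not -1.0 <= strength <= 1.0:
        raise ValueError("strength must be in [-1, 1]")
    factors: pd.DataFrame = matrix.attrs["block_factors"]
    col = f"block{linked_block + 1}"
    if col not in factors.columns:
        raise ValueError(f"block index {linked_block} not in generating design")
    rng = np.random.default_rng(seed)
    member = matrix.attrs["block_membership"]
    block_taxa = [t for t, b in member.items() if b == linked_block]
    signal = matrix.relative_abundance()[block_taxa].mean(axis=1).to_numpy()
    f = (signal - signal.mean()) / signal.std()
    data = {}
    for name in variable_names:
        eps = rng.standard_normal(len(f))
        data[name] = strength * f + np.sqrt(1.0 - strength**2) * eps
    for i in range(n_noise_vars):
        data[f"noise{i + 1}"] = rng.standard_normal(len(f))
    return pd.DataFrame(data, index=factors.index)


def generate_landuse_table(
    n_subbasins: int,
    gradient: list[float],
    total_areas: list[float] | None = None,
    seed: int = 0,
) -> LandUseTable:
    """Land-use areas spanning a low-to-high human-activity gradient.

    ``gradient[i]`` is the human-influenced fraction (farmland + urban) of
    sub-basin i's area; the human share is split 3:1 farmland:urban and the
    remainder 70/20/10 among forest, freshwater and other cover, roughly the
    mix of a subtropical agricultural watershed.
    """
    if len(gradient) != n_subbasins:
        raise ValueError("gradient length must equal n_subbasins")
    if any(not 0.0 <= g <= 1.0 for g in gradient):
        raise ValueError("human-activity fractions must be in [0, 1]")
    if total_areas is None:
        rng = np.random.default_rng(seed)
        total_areas = list(rng.uniform(100.0, 600.0, size=n_subbasins))
    if len(total_areas) != n_subbasins:
        raise ValueError("total_areas length must equal n_subbasins")

    rows = []
    for g, total in zip(gradient, total_areas):
        human = g * total
        natural = total - human
        rows.append(
            {
                "farmlands": 0.75 * human,
                "urban": 0.25 * human,
                "forests": 0.70 * natural,
                "freshwaters": 0.20 * natural,
                "others": 0.10 * natural,
            }
        )
    idx = pd.Index([f"Y{i + 1:02d}" for i in range(n_subbasins)], name="sub_basin")
    areas = pd.DataFrame(rows, index=idx)[list(LANDUSE_CLASSES)]
    return LandUseTable(areas, pd.Series(list(total_areas), index=idx, dtype=float))
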