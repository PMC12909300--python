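"""Founder-haplotype genetics for derived traits.

Diversity outbred animals carry chromosomes mosaicked from 8 inbred founder
strains. Each marker is summarized by an animals x 8 founder-dosage matrix
(expected founder-of-origin allele counts, rows summing to 2). Three
procedures are implemented:

* an additive fixed-effect founder-dosage scan (likelihood-ratio test of the
  8-founder model over a diet/cohort covariate model) with adaptive sequential
  permutation p-values;
* the cluster-specific FDR procedure that converts a markers x phenotypes
  p-value matrix into a single genome-wide significance threshold by
  per-variant Benjamini-Hochberg within phenotype clusters, per-variant
  p-value sampling, and a genome-wide Benjamini-Hochberg pass;
* founder-allele-pattern (FAP) grouping for fine-mapping: variants are grouped
  by the founder subset carrying the minor allele and groups are ranked by the
  largest LOD score among their variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FOUNDERS = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
LOD_PER_LRT = 1.0 / (2.0 * np.log(10.0))


@dataclass
class FounderDosage:
    marker_id: str
    chrom: str
    pos_bp: int
    dosages: np.ndarray  # animals x 8, rows sum to 2

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(FOUNDERS):
            raise ValueError(f"{self.marker_id}: dosage matrix must be animals x 8")
        if np.any(self.dosages < 0) or np.any(np.abs(self.dosages.sum(axis=1) - 2) > 1e-6):
            raise ValueError(f"{self.marker_id}: rows must be non-negative and sum to 2")


@dataclass
class ScanResult:
    marker_id: str
    lrt_stat: float
    lod: float
    p_perm: float
    n_perm_used: int


@dataclass
class FAPGroup:
    pattern: frozenset
    variants: list  # (variant_id, pos_bp, lod)
    max_lod: float
    rank: int


# ---------------------------------------------------------------------------
# association scan


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _lrt_stat(y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> float:
    n = y.size
    rss0, rss1 = _rss(y, X0), _rss(y, X1)
    floor = 1e-12 * max(1.0, float(y @ y))  # degenerate (perfect) fits
    if rss0 <= floor:
        return 0.0
    if rss1 <= floor:
        return np.inf
    return max(n * np.log(rss0 / rss1), 0.0)


def adaptive_permutation_p(
    observed_stat: float,
    stat_under_permutation,
    max_perm: int = 10000,
    target_exceed: int = 10,
    seed: int = 0,
) -> tuple[float, int]:
    """Adaptive sequential permutation p-value.

    Permutations are drawn until ``target_exceed`` permuted statistics reach or
    exceed the observed one, or ``max_perm`` permutations are spent; the
    estimate is (1 + #exceedances) / (1 + #permutations). Deterministic given
    the seed.
    """
    if max_perm < 100:
        raise ValueError("max_perm must be >= 100")
    rng = np.random.default_rng(seed)
    exceed = 0
    n = 0
    while n < max_perm:
        n += 1
        if stat_under_permutation(rng) >= observed_stat:
            exceed += 1
            if exceed >= target_exceed:
                break
    return (1.0 + exceed) / (1.0 + n), n


def founder_scan(
    trait: np.ndarray,
    dosages: list[FounderDosage],
    covariates: np.ndarray | None = None,
    max_perm: int = 10000,
    target_exceed: int = 10,
    seed: int = 0,
) -> list[ScanResult]:
    """Additive founder-of-origin scan with permutation p-values.

    Per marker: likelihood-ratio test of covariates + 7 founder-dosage columns
    (one column dropped - rows sum to 2, so the full set is collinear with the
    intercept) against covariates alone; LOD = LRT / (2 ln 10); the p-value
    comes from adaptively permuting the phenotype vector. Rank-deficient
    dosage submatrices lose their dependent columns (noted in the log).
    """
    y = np.asarray(trait, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("trait must have no missing values (apply listwise deletion first)")
    n = y.size
    if n < 30:
        raise ValueError("need at least 30 animals for the scan")
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    results = []
    for k, mk in enumerate(dosages):
        if mk.dosages.shape[0] != n:
            raise ValueError(f"{mk.marker_id}: dosage rows do not match trait length")
        G = mk.dosages[:, 1:]  # drop one founder column for identifiability
        X1 = np.column_stack([X0, G])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            logger.info("%s: rank-deficient design, dependent columns dropped by lstsq",
                        mk.marker_id)
        obs = _lrt_stat(y, X0, X1)

        def perm_stat(rng, X0=X0, X1=X1, y=y):
            yp = y[rng.permutation(n)]
            return _lrt_stat(yp, X0, X1)

        p, used = adaptive_permutation_p(
            obs, perm_stat, max_perm=max_perm, target_exceed=target_exceed,
            seed=seed + k,
        )
        results.append(ScanResult(
            marker_id=mk.marker_id, lrt_stat=obs, lod=obs * LOD_PER_LRT,
            p_perm=p, n_perm_used=used,
        ))
    return results


# ---------------------------------------------------------------------------
# cluster-FDR genome-wide threshold


def _bh_threshold(pvals: np.ndarray, alpha: float) -> float:
    """Largest p-value rejected by Benjamini-Hochberg (0.0 if none pass)."""
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")[:1]
    return float(pvals[reject].max()) if reject.any() else 0.0


def cluster_fdr_threshold(
    P: pd.DataFrame,
    clusters: dict,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict, float]:
    """Genome-wide significance threshold with phenotype-cluster FDR control.

    ``P`` is markers x phenotypes with entries in (0, 1]; ``clusters`` maps
    each phenotype column to a cluster label. Within each cluster: (1) each
    variant's p-values across the cluster's phenotypes are BH-corrected at
    ``alpha``; (2) each variant contributes one sampled p-value - drawn from
    all its phenotype p-values if none is significant, from the significant
    subset otherwise; (3) BH across variants on the sampled vector yields the
    cluster threshold (largest sampled p rejected; 0.0, flagged, if nothing
    passes). The study-wide threshold is the minimum over clusters with at
    least one rejection; it is 0.0 only when no cluster rejects anything.
    """
    vals = P.to_numpy(float)
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    missing = [c for c in P.columns if c not in clusters]
    if missing:
        raise ValueError(f"phenotypes without a cluster assignment: {missing}")
    rng = np.random.default_rng(seed)
    per_cluster: dict = {}
    for label in sorted(set(clusters.values()), key=str):
        cols = [c for c in P.columns if clusters[c] == label]
        sub = P[cols].to_numpy(float)
        m, q = sub.shape
        if q == 1:
            sampled = sub[:, 0]  # sampling is the identity for a singleton cluster
        else:
            order = np.argsort(sub, axis=1)
            sorted_p = np.take_along_axis(sub, order, axis=1)
            crit = alpha * np.arange(1, q + 1) / q
            passing = sorted_p <= crit[None, :]
            # BH: reject everything up to the largest passing rank
            kmax = np.where(passing.any(axis=1), q - 1 - np.argmax(passing[:, ::-1], axis=1), -1)
            sampled = np.empty(m)
            for i in range(m):
                if kmax[i] < 0:
                    sampled[i] = sub[i, rng.integers(q)]
                else:
                    sig = sorted_p[i, : kmax[i] + 1]
                    sampled[i] = sig[rng.integers(sig.size)]
        thr = _bh_threshold(sampled, alpha)
        if thr == 0.0:
            logger.info("cluster %r: no variant passes genome-wide BH (threshold 0)", label)
        per_cluster[label] = thr
    positive = [t for t in per_cluster.values() if t > 0]
    study = min(positive) if positive else 0.0
    return per_cluster, study


def cluster_phenotypes(corr: pd.DataFrame, n_clusters: int = 2) -> dict:
    """Average-linkage clustering of a trait correlation matrix into groups.

    Convenience plumbing for assembling the ``clusters`` input; distance is
    1 - correlation.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    d = 1.0 - corr.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    labels = fcluster(linkage(squareform(d, checks=False), method="average"),
                      t=n_clusters, criterion="maxclust")
    return {pheno: int(lab) for pheno, lab in zip(corr.columns, labels)}


# ---------------------------------------------------------------------------
# founder-allele-pattern fine-mapping


def _founder_key(pattern: frozenset) -> tuple:
    return tuple(sorted(FOUNDERS.index(f) for f in pattern))


def minor_allele_pattern(allele_sets: tuple) -> frozenset | None:
    """The founder subset carrying the minor allele.

    ``allele_sets`` holds the two founder sets of a biallelic variant. The
    minor allele is the one carried by fewer founders; a 4-vs-4 split resolves
    to the lexicographically smaller set in fixed founder order (logged).
    Returns None for non-segregating variants (0 or 8 founders).
    """
    a, b = (frozenset(s) for s in allele_sets)
    if a | b != set(FOUNDERS) or (a & b):
        raise ValueError("allele sets must partition the 8 founders")
    if len(a) == 0 or len(b) == 0:
        return None
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    logger.info("4-vs-4 founder split: lexicographically smaller set taken as minor")
    return a if _founder_key(a) < _founder_key(b) else b


def fap_group_variants(variants, window=None) -> list[FAPGroup]:
    """Group fine-mapped variants by founder-allele-pattern and rank by LOD.

    ``variants`` is an iterable of (variant_id, pos_bp, allele_sets, lod) where
    ``allele_sets`` is the pair of founder subsets carrying each allele.
    Variants outside the closed bp ``window`` (if given) or non-segregating are
    excluded (logged). Groups are ranked 1..n by descending max LOD; exact LOD
    ties break by the founder-order key of the pattern.
    """
    groups: dict[frozenset, list] = {}
    for vid, pos, allele_sets, lod in variants:
        if window is not None and not (window[0] <= pos <= window[1]):
            continue
        pattern = minor_allele_pattern(allele_sets)
        if pattern is None:
            logger.info("%s: non-segregating variant excluded", vid)
            continue
        groups.setdefault(pattern, []).append((vid, int(pos), float(lod)))
    ranked = sorted(
        groups.items(),
        key=lambda kv: (-max(v[2] for v in kv[1]), _founder_key(kv[0])),
    )
    return [
        FAPGroup(pattern=pat, variants=sorted(vs, key=lambda v: v[1]),
                 max_lod=max(v[2] for v in vs), rank=r + 1)
        for r, (pat, vs) in enumerate(ranked)
    ]


def fap_table(groups: list[FAPGroup]) -> pd.DataFrame:
    """Flatten ranked FAP groups to the output table."""
    return pd.DataFrame([
        {
            "group_rank": g.rank,
            "pattern": "/".join(sorted(g.pattern, key=FOUNDERS.index)),
            "n_variants": len(g.variants),
            "max_lod": g.max_lod,
            "start_bp": min(v[1] for v in g.variants),
            "end_bp": max(v[1] for v in g.variants),
        }
        for g in groups
    ])
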