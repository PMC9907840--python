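"""Distribution similarity and layer-enrichment statistics.

Marker mean distributions are compared with the Jensen-Shannon divergence
(base-2 logs, so JSD and its square root — the JS distance, a metric — both
live in [0, 1]); similarity is the multiplicative inverse of the distance,
capped for near-identical distributions. Layer enrichment across a cohort of
vessels is tested two ways: a one-sided Welch two-sample t-test and a
one-sided label-permutation test on the difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import rel_entr

__all__ = [
    "SimilarityMatrix",
    "LayerTestResult",
    "jensen_shannon_divergence",
    "js_distance",
    "similarity",
    "similarity_matrix",
    "layer_t_test",
    "permutation_layer_test",
]

SIMILARITY_CAP = 1e6


def _validate_density(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D probability vector")
    if (v < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {v.sum():.12f}, expected 1")
    return v


def jensen_shannon_divergence(p, q, log_base: float = 2.0) -> float:
    """JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m the midpoint mixture.

    Zero bins contribute nothing (0 log 0 = 0); no pseudocounts are added
    because the mixture m is non-zero wherever p or q is. Base-2 logs bound
    the result in [0, 1].
    """
    p = _validate_density(p, "p")
    q = _validate_density(q, "q")
    if p.size != q.size:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    m = 0.5 * (p + q)
    jsd = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()  # nats
    jsd /= np.log(log_base)
    return float(min(max(jsd, 0.0), 1.0)) if log_base == 2.0 else float(max(jsd, 0.0))


def js_distance(p, q, log_base: float = 2.0) -> float:
    """Square root of the JSD; a metric on probability vectors."""
    return float(np.sqrt(jensen_shannon_divergence(p, q, log_base)))


def similarity(p, q, cap: float = SIMILARITY_CAP, additive: bool = False) -> float:
    """Inverse JS distance, the similarity score between two distributions.

    Default is the multiplicative inverse 1/d, capped at ``cap`` so identical
    distributions report the cap rather than infinity. ``additive=True``
    switches to the bounded variant 1 - d.
    """
    d = js_distance(p, q)
    if additive:
        return 1.0 - d
    if d < 1.0 / cap:
        return float(cap)
    return float(1.0 / d)


@dataclass
class SimilarityMatrix:
    markers: list[str]
    distance: np.ndarray
    similarity: np.ndarray
    reference: str | None = None
    reference_ranking: pd.DataFrame | None = None

    def to_frame(self, which: str = "similarity") -> pd.DataFrame:
        m = self.similarity if which == "similarity" else self.distance
        return pd.DataFrame(m, index=self.markers, columns=self.markers)


def similarity_matrix(
    mean_dists: dict[str, np.ndarray],
    reference: str | None = None,
    cap: float = SIMILARITY_CAP,
    additive: bool = False,
) -> SimilarityMatrix:
    """Pairwise JS distances and similarities between marker mean profiles.

    When ``reference`` is given, a table ranking every other marker by
    similarity to the reference is attached.
    """
    markers = list(mean_dists)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers for a similarity matrix")
    vecs = [_validate_density(mean_dists[m], m) for m in markers]
    n_bins = {v.size for v in vecs}
    if len(n_bins) != 1:
        raise ValueError(f"markers have mismatched bin counts: {sorted(n_bins)}")
    k = len(markers)
    dist = np.zeros((k, k))
    sim = np.full((k, k), cap if not additive else 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            d = js_distance(vecs[i], vecs[j])
            dist[i, j] = dist[j, i] = d
            s = similarity(vecs[i], vecs[j], cap=cap, additive=additive)
            sim[i, j] = sim[j, i] = s
    ranking = None
    if reference is not None:
        if reference not in markers:
            raise KeyError(f"reference marker {reference!r} not in {markers}")
        r = markers.index(reference)
        others = [i for i in range(k) if i != r]
        ranking = (
            pd.DataFrame(
                {
                    "marker": [markers[i] for i in others],
                    "js_distance": dist[r, others],
                    "similarity": sim[r, others],
                }
            )
            .sort_values("similarity", ascending=False, kind="stable")
            .reset_index(drop=True)
        )
    return SimilarityMatrix(markers, dist, sim, reference, ranking)


@dataclass
class LayerTestResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    method: str  # "t_test" | "permutation"
    n_per_group: tuple[int, int]
    alternative: str  # "greater" | "less" (first group vs second)
    n_perm: int | None = None
    seed: int | None = None


def layer_t_test(
    scores_a,
    scores_b,
    alternative: str = "greater",
    pair: tuple[str, str] = ("media", "intima"),
) -> LayerTestResult:
    """Welch one-sided two-sample t-test of group a against group b.

    ``alternative="greater"`` tests mean(a) > mean(b). Two constant, equal
    groups carry no directional evidence and report p = 0.5 by convention.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        stat, p = 0.0, 0.5
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    return LayerTestResult(
        pair=pair,
        statistic=stat,
        p_value=p,
        method="t_test",
        n_per_group=(a.size, b.size),
        alternative=alternative,
    )


def permutation_layer_test(
    scores_a,
    scores_b,
    alternative: str = "greater",
    n_perm: int = 10_000,
    seed: int = 0,
    pair: tuple[str, str] = ("media", "intima"),
) -> LayerTestResult:
    """One-sided label-permutation test on the difference of group means.

    Group labels are shuffled ``n_perm`` times under the given seed and the
    p-value is ``(1 + #{permuted statistic at least as extreme}) /
    (n_perm + 1)``, the add-one estimator that keeps the test exact-level.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, a.size + b.size
    rng = np.random.default_rng(seed)
    # One shuffled copy of the pooled sample per permutation, vectorized.
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, n_total)), axis=1)
    perm_stat = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    if alternative == "greater":
        exceed = int((perm_stat >= observed).sum())
    else:
        exceed = int((perm_stat <= observed).sum())
    p = (1 + exceed) / (n_perm + 1)
    return LayerTestResult(
        pair=pair,
        statistic=float(observed),
        p_value=float(p),
        method="permutation",
        n_per_group=(a.size, b.size),
        alternative=alternative,
        n_perm=n_perm,
        seed=seed,
    )
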