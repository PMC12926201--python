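"""Enrichment and concordance statistics.

* A randomization (permutation) test of interval-set overlap, in the style
  of genomic region randomization tools: query intervals are re-placed
  uniformly at random inside an allowed universe (e.g. intergenic space),
  preserving length and chromosome, and the overlap count is compared with
  the permuted null via a z-score and an add-one empirical p-value.
* A chi-square test of whether interacting gene pairs fall into the same
  expression cluster more often than the independence null predicts.
* An upper-tail hypergeometric gene-set overlap test.
* A two-sample Wilcoxon rank-sum comparison (normal approximation with tie
  correction) for conservation-score distributions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import intervals as iv


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    p_empirical: float
    n_perm: int
    alternative: str
    seed: int


def _count_overlapping(query: pd.DataFrame, reference: pd.DataFrame) -> int:
    return int(iv.overlaps_any(query, reference).sum())


def permutation_overlap_test(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    universe: pd.DataFrame,
    n_perm: int = 500,
    seed: int = 0,
    alternative: str = "greater",
) -> OverlapTestResult:
    """Randomization test of query/reference interval overlap.

    ``observed`` is the number of query intervals overlapping the reference
    by >= 1 bp. Each permutation re-places every query interval uniformly
    at random within the universe (length- and chromosome-preserving;
    placed intervals may overlap each other), and the count is recomputed.
    The empirical p uses the add-one estimator (1 + #{perm as extreme}) /
    (1 + n_perm), so p is never 0.
    """
    if query.empty or reference.empty:
        raise ValueError("query and reference must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)

    # vectorized placement: per query interval, sample n_perm random starts
    uni = iv.merge(universe)
    pieces = {
        chrom: (sub["start"].to_numpy(np.int64), (sub["end"] - sub["start"]).to_numpy(np.int64))
        for chrom, sub in uni.groupby("chrom", sort=False)
    }
    ref_arrays = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in iv.merge(reference).groupby("chrom", sort=False)
    }
    observed = _count_overlapping(query, reference)
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for row in query.itertuples(index=False):
        length = row.end - row.start
        if row.chrom not in pieces:
            raise ValueError(f"no universe space on chromosome {row.chrom!r}")
        starts, plens = pieces[row.chrom]
        cap = np.maximum(plens - length + 1, 0)
        total = int(cap.sum())
        if total == 0:
            raise ValueError(
                f"query interval of length {length} does not fit in the universe on {row.chrom}"
            )
        cum = np.cumsum(cap)
        r = rng.integers(0, total, size=n_perm)
        j = np.searchsorted(cum, r, side="right")
        offs = r - np.where(j > 0, cum[np.maximum(j - 1, 0)], 0)
        s = starts[j] + offs
        e = s + length
        if row.chrom in ref_arrays:
            rs, re = ref_arrays[row.chrom]
            idx = np.searchsorted(rs, e, side="left")
            hit = (idx > 0) & (re[np.maximum(idx - 1, 0)] > s)
            perm_counts += hit
    perm_mean = float(perm_counts.mean())
    perm_sd = float(perm_counts.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - perm_mean) / perm_sd if perm_sd > 0 else float("nan")
    if alternative == "greater":
        extreme = int((perm_counts >= observed).sum())
    elif alternative == "less":
        extreme = int((perm_counts <= observed).sum())
    else:
        dev = np.abs(perm_counts - perm_mean)
        extreme = int((dev >= abs(observed - perm_mean)).sum())
    p = (1 + extreme) / (1 + n_perm)
    return OverlapTestResult(
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z=z,
        p_empirical=p,
        n_perm=n_perm,
        alternative=alternative,
        seed=seed,
    )


def cocluster_chisq(
    pairs: list[tuple[str, str]],
    clusters: dict[str, int],
    marginals: str = "pairs",
) -> dict:
    """Chi-square test of expression-cluster concordance for gene pairs.

    ``observed_same`` counts pairs whose genes share a cluster. The
    independence null puts P(same) = sum_k f_k^2 with f_k the cluster
    frequencies among the distinct genes appearing in pairs (``marginals=
    "pairs"``, default) or among all assigned genes (``marginals="all"``).
    A 1-df goodness-of-fit chi-square compares the (same, different) split
    with its expectation. Pairs with an unassigned gene are excluded and
    reported.
    """
    usable = [(a, b) for a, b in pairs if a in clusters and b in clusters]
    n_excluded = len(pairs) - len(usable)
    if not usable:
        raise ValueError("no pair has both genes assigned to clusters")
    if marginals == "pairs":
        gene_pool = {g for pair in usable for g in pair}
    elif marginals == "all":
        gene_pool = set(clusters)
    else:
        raise ValueError(f"unknown marginals mode {marginals!r}")
    assignments = pd.Series({g: clusters[g] for g in gene_pool})
    freqs = assignments.value_counts(normalize=True)
    if len(freqs) < 2:
        raise ValueError("need >= 2 clusters for a concordance test")
    p_same = float((freqs**2).sum())
    n = len(usable)
    observed_same = sum(1 for a, b in usable if clusters[a] == clusters[b])
    expected_same = n * p_same
    expected = np.array([expected_same, n - expected_same])
    observed = np.array([observed_same, n - observed_same])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return {
        "chi2": chi2,
        "df": 1,
        "p": p,
        "observed_same": observed_same,
        "expected_same": expected_same,
        "n_pairs": n,
        "n_excluded": n_excluded,
    }


def geneset_hypergeom(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> dict:
    """Upper-tail hypergeometric overlap test: P(X >= |A & B|).

    Population |universe|, |B| successes, |A| draws.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    p_upper = float(sps.hypergeom.sf(overlap - 1, len(universe), len(set_b), len(set_a)))
    return {"overlap": overlap, "p_upper": p_upper, "n_a": len(set_a), "n_b": len(set_b), "n_universe": len(universe)}


def ranksum_compare(scores_a, scores_b) -> dict:
    """Two-sample Wilcoxon rank-sum test (normal approximation, tie-corrected),
    two-sided."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"W": float(res.statistic), "p": float(res.pvalue)}
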