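"""Set algebra, overlap tests, signed-FDR ranking and GSEA-like enrichment.

The enrichment statistic is the classic unweighted running sum over a ranked
gene list: walking the list from the most significantly up-regulated gene,
the sum gains 1/|S| at each gene in the tested set S and loses 1/(N-|S|)
otherwise; the enrichment score (ES) is the signed maximal deviation from
zero.  Significance comes from resampling same-size gene sets from the
ranked universe (the per-gene differential-expression table is the only
expression information the pipeline holds, so a phenotype-permutation null
is not available).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# set algebra

@dataclass
class LigandSets:
    clip1: set[str]
    clip2: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.clip1 & self.clip2

    @property
    def union(self) -> set[str]:
        return self.clip1 | self.clip2

    def summary(self) -> dict[str, int]:
        inter, union = self.intersection, self.union
        return {
            "clip1": len(self.clip1), "clip2": len(self.clip2),
            "intersection": len(inter), "union": len(union),
            "clip1_only": len(self.clip1 - self.clip2),
            "clip2_only": len(self.clip2 - self.clip1),
        }

    def containment_of_clip2(self) -> float:
        """Fraction of the (higher-stringency) second set shared with the
        first, e.g. 293/394."""
        return len(self.intersection) / len(self.clip2)


def build_sets(clip1_ligands, clip2_ligands) -> LigandSets:
    return LigandSets(set(clip1_ligands), set(clip2_ligands))


# ---------------------------------------------------------------------------
# chi-square on 2x2 tables

@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p: float


def chi_square_2x2(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square with 1 df on a 2x2 table; continuity correction off
    by default.  Raises on any zero margin (expected counts undefined)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=correction)
    return ContingencyResult(observed=obs, expected=expected, chi2=float(chi2), p=float(p))


def overlap_test(set_a, set_b, universe) -> ContingencyResult:
    """Independence test of two gene-set memberships over a universe.

    Rows = (in A, not in A), columns = (in B, not in B).  Expected counts are
    row x column margins / total, as displayed in the original contingency
    tables.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be contained in the universe")
    n_ab = len(a & b)
    table = [[n_ab, len(a) - n_ab],
             [len(b) - n_ab, len(u) - len(a) - len(b) + n_ab]]
    return chi_square_2x2(table)


# ---------------------------------------------------------------------------
# ranking and GSEA

def rank_genes(de_table: pd.DataFrame, lfc_col: str = "log2fc",
               fdr_col: str = "fdr") -> pd.DataFrame:
    """Rank genes by signed FDR: sign(log2FC) x (-log10 FDR), descending, so
    the most significantly up-regulated genes in the knockout come first.

    FDR values of exactly 0 are capped at half the smallest positive FDR in
    the table before the log; ties are broken by |log2FC| descending then
    gene_id, making the order total and deterministic.
    """
    de = de_table.copy()
    if de[[lfc_col, fdr_col]].isna().any().any():
        raise ValueError("missing log2FC or FDR values")
    fdr = de[fdr_col].to_numpy(dtype=float)
    if np.any(fdr < 0) or np.any(fdr > 1):
        raise ValueError("FDR values must lie in [0, 1]")
    pos = fdr[fdr > 0]
    if np.any(fdr == 0):
        if pos.size == 0:
            raise ValueError("all FDR values are zero; cannot cap")
        fdr = np.where(fdr == 0, pos.min() / 2.0, fdr)
    de["rank_stat"] = np.sign(de[lfc_col]) * (-np.log10(fdr))
    de["_abs_lfc"] = de[lfc_col].abs()
    de = de.sort_values(["rank_stat", "_abs_lfc", "gene_id"],
                        ascending=[False, False, True], kind="mergesort")
    return de.drop(columns="_abs_lfc").reset_index(drop=True)[["gene_id", "rank_stat"]]


@dataclass
class GseaResult:
    es: float
    running_profile: np.ndarray
    leading_edge: set[str] = field(default_factory=set)
    p_perm: float | None = None
    n_perm: int = 0
    n_hits: int = 0
    n_dropped: int = 0


def gsea_es(ranked_ids, gene_set) -> GseaResult:
    """Unweighted running-sum enrichment score of ``gene_set`` in a ranked
    gene list.

    The running sum gains 1/|S| at each hit and loses 1/(N-|S|) at each miss,
    so it returns to 0 at the end of the list; ES is the running value of
    maximal absolute deviation (signed).  For positive ES the leading edge is
    the set members at or before the argmax of the running profile.

    Genes of the set absent from the ranked list are dropped with a logged
    count; the set must hit strictly between 0 and N genes of the list.
    """
    ids = list(ranked_ids)
    n = len(ids)
    sset = set(gene_set)
    hits = np.array([g in sset for g in ids], dtype=bool)
    k = int(hits.sum())
    n_dropped = len(sset) - k
    if n_dropped:
        logger.info("gsea_es: %d set genes absent from the ranked list", n_dropped)
    if k == 0 or k == n:
        raise ValueError("gene set must hit strictly between 0 and N ranked genes")
    steps = np.where(hits, 1.0 / k, -1.0 / (n - k))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    if es > 0:
        leading = {g for j, g in enumerate(ids[:i + 1]) if hits[j]}
    else:
        leading = {g for j, g in enumerate(ids[i:], start=i) if hits[j]}
    return GseaResult(es=es, running_profile=running, leading_edge=leading,
                      n_hits=k, n_dropped=n_dropped)


def _es_from_sorted_positions(pos: np.ndarray, n: int, k: int) -> np.ndarray:
    """Vectorized ES for many permutations from sorted 0-based hit positions.

    ``pos`` has shape (n_perm, k).  The running profile attains its local
    maxima immediately after hits and its minima immediately before hits, so
    the signed maximal deviation follows in closed form from the hit
    positions alone.  This closed form is cross-checked against the explicit
    cumulative sum of :func:`gsea_es` in the test suite.
    """
    i = np.arange(1, k + 1)
    at_hit = i / k - (pos + 1 - i) / (n - k)
    before_hit = (i - 1) / k - (pos - (i - 1)) / (n - k)
    max_run = at_hit.max(axis=1)
    min_run = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(max_run >= -min_run, max_run, min_run)


def gsea_permutation_p(ranked_ids, gene_set, n_perm: int = 1000,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       tail: str = "signed") -> GseaResult:
    """Gene-set resampling p-value for the enrichment score.

    Random same-size sets are drawn without replacement from the ranked
    universe.  The one-sided p-value on the observed sign carries an add-one
    correction, so it is never exactly 0.  With ``tail="signed"`` (the GSEA
    convention, and the default) a positive observed ES is compared against
    the positive permutation scores only,

        p = (1 + #{ES_perm >= ES_obs}) / (1 + #{ES_perm >= 0}),

    mirrored for negative ES; this makes p uniform under the null.
    ``tail="global"`` divides by n_perm + 1 instead (all permutations in the
    denominator), which is conservative by roughly a factor of two.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("signed", "global"):
        raise ValueError("tail must be 'signed' or 'global'")
    if rng is None:
        rng = np.random.default_rng(seed)
    result = gsea_es(ranked_ids, gene_set)
    n = len(result.running_profile)
    k = result.n_hits
    # k uniform hit-positions without replacement per permutation
    u = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
    es_perm = _es_from_sorted_positions(pos, n, k)
    if result.es >= 0:
        more_extreme = int(np.sum(es_perm >= result.es))
        same_sign = int(np.sum(es_perm >= 0))
    else:
        more_extreme = int(np.sum(es_perm <= result.es))
        same_sign = int(np.sum(es_perm < 0))
    denom = (1 + same_sign) if tail == "signed" else (n_perm + 1)
    result.p_perm = (1 + more_extreme) / denom
    result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# rank-sum test

def rank_sum_test(values_in_set, values_out_of_set, method: str = "auto") -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    ``auto`` uses the exact null distribution when both samples are small
    (n, m <= 10) and tie-free, and the normal approximation with tie
    correction otherwise.  Fully tied pooled samples return p = 1.
    """
    x = np.asarray(values_in_set, dtype=float)
    y = np.asarray(values_out_of_set, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        has_ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
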