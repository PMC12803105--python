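"""Cross-link sites, permutation-FDR peak calling and cluster scoring.

The model follows the standard iCLIP statistic: every read marks one
cross-link event at (or one nucleotide upstream of) its 5' end; events
aggregate into *sites* scored by read count; a site is a *peak* when the
summed signal in a +/-3 nt window is unexpectedly high compared with the same
number of events thrown uniformly onto the gene span; peaks closer than
20 nt merge into *clusters* whose score adds the adjacent non-peak signal.

FDR estimation
--------------
For a gene with total signal ``n`` events over span ``L``, the null
redistributes the ``n`` individual events uniformly over ``L`` and, for each
observed window height ``h``, estimates

    FDR(h) = E_perm[ #{random event positions with height >= h} ]
             / #{observed sites with height >= h}

clipped to [0, 1] and monotonized (running minimum over increasing ``h``), so
that the cut "FDR < alpha" is well defined.  Each permutation consumes exactly
one ``rng.integers(start, end, size=n)`` draw, which keeps the random stream
reproducible and easy to re-implement in an independent oracle.
"""
from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .models import GeneModel

PEAK_COLUMNS = ["chrom", "pos", "strand", "score", "gene_id", "window_height", "fdr"]
CLUSTER_COLUMNS = ["gene_id", "chrom", "strand", "start", "end",
                   "member_peak_positions", "n_peaks", "cluster_score"]


def derive_crosslink_sites(alignments: Iterable, offset: int = -1,
                           gene_models: dict[str, GeneModel] | None = None,
                           ) -> tuple[pd.DataFrame, int]:
    """Collapse read alignments into scored cross-link sites.

    Each mapped, stranded read contributes one event at its 5'-terminal
    aligned position shifted by ``offset`` toward the 5' direction of the
    transcript (``offset=-1`` is the iCLIP truncation convention: the
    cross-link sits one nucleotide upstream of the read start; ``offset=0``
    places the event exactly at the read terminus).

    Parameters
    ----------
    alignments : iterable of pysam.AlignedSegment
    offset : event position = 5'-end + offset on '+', 5'-end - offset on '-'.
    gene_models : optional; when given, sites are assigned a gene_id by span
        lookup (genes assumed non-overlapping).

    Returns
    -------
    (sites, n_rejected) : site table with one row per (chrom, strand, pos)
        scored by read count, and the number of unmapped/strandless records
        rejected.
    """
    events: dict[tuple[str, str, int], int] = {}
    rejected = 0
    for read in alignments:
        if getattr(read, "is_unmapped", False):
            rejected += 1
            continue
        chrom = read.reference_name
        if chrom is None:
            rejected += 1
            continue
        if read.is_reverse:
            pos = (read.reference_end - 1) - offset
            strand = "-"
        else:
            pos = read.reference_start + offset
            strand = "+"
        key = (chrom, strand, int(pos))
        events[key] = events.get(key, 0) + 1

    if not events:
        sites = pd.DataFrame(columns=["chrom", "pos", "strand", "score", "gene_id"])
        return sites, rejected
    rows = sorted((c, p, s, n) for (c, s, p), n in events.items())
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score"])
    sites["gene_id"] = pd.NA
    if gene_models is not None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in gene_models.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            genes.sort(key=lambda g: g.start)
            starts = np.array([g.start for g in genes])
            mask = sites["chrom"] == chrom
            idx = np.searchsorted(starts, sites.loc[mask, "pos"].to_numpy(), side="right") - 1
            assigned = []
            for i, p in zip(idx, sites.loc[mask, "pos"].to_numpy()):
                g = genes[i] if i >= 0 else None
                assigned.append(g.gene_id if g is not None and g.start <= p < g.end else pd.NA)
            sites.loc[mask, "gene_id"] = assigned
    return sites, rejected


def _window_heights(positions: np.ndarray, scores: np.ndarray, window: int) -> np.ndarray:
    """Summed score within +/-window nt of each position (positions sorted)."""
    csum = np.concatenate([[0], np.cumsum(scores)])
    lo = np.searchsorted(positions, positions - window, side="left")
    hi = np.searchsorted(positions, positions + window, side="right")
    return csum[hi] - csum[lo]


def _null_height_counts(rng: np.random.Generator, span: tuple[int, int], n_events: int,
                        thresholds: np.ndarray, n_perm: int, window: int) -> np.ndarray:
    """Total (over permutations) number of random event positions whose window
    height reaches each threshold.  One uniform draw of ``n_events`` positions
    per permutation."""
    start, end = span
    L = end - start
    totals = np.zeros(len(thresholds), dtype=np.int64)
    w = window
    # height[i] = events in [i-w, i+w] clipped to the span
    hi = np.minimum(np.arange(L) + w + 1, L)
    lo = np.maximum(np.arange(L) - w, 0)
    for _ in range(n_perm):
        pos = rng.integers(start, end, size=n_events)
        counts = np.bincount(pos - start, minlength=L)
        csum = np.concatenate([[0], np.cumsum(counts)])
        occupied = counts > 0
        h_occ = np.sort((csum[hi] - csum[lo])[occupied])
        totals += h_occ.size - np.searchsorted(h_occ, thresholds, side="left")
    return totals


def call_peaks(sites: pd.DataFrame, gene_span: tuple[int, int], n_perm: int = 100,
               window: int = 3, alpha: float = 0.05,
               seed: int | None = None, rng: np.random.Generator | None = None,
               return_all_sites: bool = False) -> pd.DataFrame:
    """Permutation-FDR peak calling for the sites of one gene.

    Parameters
    ----------
    sites : table with columns pos, score (one gene; chrom/strand/gene_id
        carried through when present).
    gene_span : (start, end), 0-based half-open; the uniform randomization
        domain.
    n_perm : number of uniform redistributions of the gene's events.
    window : half-width of the height window (+/-window nt, inclusive).
    alpha : FDR cut; sites with FDR < alpha are peaks.
    return_all_sites : when True, return every site with its window_height and
        FDR instead of only the significant ones (useful for calibration).

    Returns
    -------
    Peak table with the site columns plus ``window_height`` and ``fdr``.
    """
    start, end = gene_span
    if end <= start:
        raise ValueError("empty gene span")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(sites) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)

    sites = sites.sort_values("pos", kind="mergesort", ignore_index=True)
    positions = sites["pos"].to_numpy(dtype=int)
    scores = sites["score"].to_numpy(dtype=int)
    heights = _window_heights(positions, scores, window)
    n_events = int(scores.sum())

    thresholds = np.unique(heights)  # ascending
    obs_ge = len(heights) - np.searchsorted(np.sort(heights), thresholds, side="left")
    null_tot = _null_height_counts(rng, (start, end), n_events, thresholds, n_perm, window)
    fdr_at = np.clip((null_tot / n_perm) / obs_ge, 0.0, 1.0)
    fdr_at = np.minimum.accumulate(fdr_at)  # monotone non-increasing in height

    fdr = fdr_at[np.searchsorted(thresholds, heights)]
    out = sites.copy()
    out["window_height"] = heights
    out["fdr"] = fdr
    if return_all_sites or alpha >= 1.0:  # alpha = 1 keeps every site
        return out
    return out[out["fdr"] < alpha].reset_index(drop=True)


def cluster_peaks(peaks: pd.DataFrame, all_sites: pd.DataFrame, max_gap: int = 20,
                  flank: int = 3) -> pd.DataFrame:
    """Merge peaks of one gene into clusters and score them.

    Peaks merge transitively while consecutive positions differ by strictly
    less than ``max_gap``.  The cluster interval is
    [min_peak - flank, max_peak + flank + 1) and the cluster score is the sum
    of member peak scores plus the scores of non-peak sites inside the
    interval ("peak and adjacent signal").
    """
    if len(peaks) == 0:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    peaks = peaks.sort_values("pos", kind="mergesort", ignore_index=True)
    ppos = peaks["pos"].to_numpy(dtype=int)
    pscore = peaks["score"].to_numpy(dtype=int)
    breaks = np.flatnonzero(np.diff(ppos) >= max_gap) + 1
    groups = np.split(np.arange(len(ppos)), breaks)

    non_peak = all_sites[~all_sites["pos"].isin(set(ppos.tolist()))]
    np_pos = non_peak["pos"].to_numpy(dtype=int)
    np_score = non_peak["score"].to_numpy(dtype=int)
    order = np.argsort(np_pos)
    np_pos, np_score = np_pos[order], np_score[order]
    np_csum = np.concatenate([[0], np.cumsum(np_score)])

    first = peaks.iloc[0]
    rows = []
    for idx in groups:
        lo, hi = ppos[idx[0]], ppos[idx[-1]]
        start, end = max(0, lo - flank), hi + flank + 1
        a = np.searchsorted(np_pos, start, side="left")
        b = np.searchsorted(np_pos, end, side="left")
        score = int(pscore[idx].sum() + (np_csum[b] - np_csum[a]))
        rows.append({
            "gene_id": first.get("gene_id", pd.NA), "chrom": first.get("chrom", pd.NA),
            "strand": first.get("strand", pd.NA), "start": start, "end": end,
            "member_peak_positions": ppos[idx].tolist(), "n_peaks": len(idx),
            "cluster_score": score,
        })
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def assign_region(cluster_start: int, cluster_end: int, gene: GeneModel) -> str:
    """Region label of the cluster midpoint, precedence 3UTR > 5UTR > CDS >
    intron, 'other' when the midpoint lies outside every annotated feature."""
    mid = (cluster_start + cluster_end) // 2
    return gene.region_of(mid)


def annotate_cluster_regions(clusters: pd.DataFrame,
                             gene_models: dict[str, GeneModel]) -> pd.DataFrame:
    """Add a ``region`` column to a cluster table."""
    if len(clusters) == 0:
        out = clusters.copy()
        out["region"] = pd.Series(dtype=object)
        return out
    out = clusters.copy()
    out["region"] = [
        assign_region(int(r.start), int(r.end), gene_models[r.gene_id])
        for r in clusters.itertuples(index=False)
    ]
    return out


def region_distribution(clusters: pd.DataFrame) -> tuple[dict[str, float], dict[str, int]]:
    """Fraction and count of clusters per gene region; fractions sum to 1.

    Empty input returns empty fractions and a counts dict with an explicit
    zero total.
    """
    if len(clusters) == 0 or "region" not in clusters.columns:
        return {}, {"total": 0}
    counts = clusters["region"].value_counts().to_dict()
    total = int(sum(counts.values()))
    fractions = {k: v / total for k, v in counts.items()}
    out_counts = {k: int(v) for k, v in counts.items()}
    out_counts["total"] = total
    return fractions, out_counts


def call_peaks_and_clusters(sites: pd.DataFrame, gene_models: dict[str, GeneModel],
                            n_perm: int = 100, window: int = 3, alpha: float = 0.05,
                            max_gap: int = 20, flank: int = 3,
                            seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run peak calling and clustering over every gene of a site table.

    One RNG is derived per gene from ``seed`` and the gene id, so results do
    not depend on iteration order.
    """
    from .simulate import substream

    peak_tables, cluster_tables = [], []
    for gid, gsites in sites.groupby("gene_id", sort=True):
        gene = gene_models[gid]
        rng = substream(seed if seed is not None else 0, f"peaks-{gid}")
        peaks = call_peaks(gsites, gene.span, n_perm=n_perm, window=window,
                           alpha=alpha, rng=rng)
        if len(peaks):
            peak_tables.append(peaks)
            cluster_tables.append(cluster_peaks(peaks, gsites, max_gap=max_gap, flank=flank))
    peaks_all = (pd.concat(peak_tables, ignore_index=True) if peak_tables
                 else pd.DataFrame(columns=PEAK_COLUMNS))
    clusters_all = (pd.concat(cluster_tables, ignore_index=True) if cluster_tables
                    else pd.DataFrame(columns=CLUSTER_COLUMNS))
    clusters_all = annotate_cluster_regions(clusters_all, gene_models)
    return peaks_all, clusters_all
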