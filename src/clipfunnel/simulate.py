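"""Synthetic-data generator for the whole pipeline.

Emulates two iCLIP pseudo-experiments on a synthetic chromosome: genes with
5'UTR/CDS/optional-intron/3'UTR structure, UGU-rich binding sites planted in
the 3'UTRs of a chosen ligand subset, expression-correlated background
cross-linking, two sequencing depths standing in for the two RNase
stringencies, a knockout-vs-wild-type differential-expression table in which
planted ligands are upregulated, and annotation resources (citation counts,
disease-list membership, lens-enrichment scores) for the prioritization
funnel.

Ground truth (which genes are ligands, where the sites are) is emitted
alongside the data and is never consumed by the analysis modules except in
tests.  Identical config + seed gives byte-identical outputs.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage RNG: global seed combined with a stable hash of
    the stage name, so each output is reproducible independently of the order
    in which stages run."""
    return np.random.default_rng([seed % (2**31), zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Lengths are in nucleotides, expression in arbitrary TPM-like units,
    depth factors are dimensionless multipliers on the expected event count
    (the second experiment emulates a harsher RNase digest with ~5x fewer
    uniquely mapped reads).
    """

    n_genes: int = 500
    utr3_len_mean: float = 750.0
    utr3_len_sd: float = 350.0
    utr5_len_mean: float = 150.0
    cds_len_mean: float = 1200.0
    intron_len_mean: float = 800.0
    intron_prob: float = 0.5
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G U
    n_ligands: int = 50
    sites_per_ligand: int = 3
    site_motif: str = "TGTTGTTGTTGT"  # 4 tandem UGUs on the transcript
    signal_fraction: float = 0.8
    expression_lognormal_mu: float = 2.5
    expression_lognormal_sigma: float = 0.7
    reads_per_gene_scale: float = 8.0
    depth_factor_exp1: float = 1.0
    depth_factor_exp2: float = 0.2
    de_lfc_mean: float = 1.0
    de_lfc_sd: float = 0.5
    minus_strand_fraction: float = 0.0
    intergenic_gap: int = 200
    # funnel annotation resources
    pubs_nb_mean: float = 1.0
    pubs_nb_alpha: float = 2.0
    pubs_ligand_factor: float = 5.0
    disease_rate_background: float = 0.05
    disease_rate_ligand: float = 0.35
    lens_enrichment_ligand_shift: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 non-negative probabilities summing to 1")
        if self.n_ligands > self.n_genes:
            raise ValueError("n_ligands cannot exceed n_genes")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        for name in ("utr3_len_mean", "utr3_len_sd", "utr5_len_mean", "cds_len_mean",
                     "intron_len_mean", "reads_per_gene_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth_factor_exp1 <= 0 or self.depth_factor_exp2 <= 0:
            raise ValueError("depth factors must be > 0")
        if self.n_genes < 0 or self.n_ligands < 0 or self.sites_per_ligand <= 0:
            raise ValueError("counts must be non-negative (sites_per_ligand > 0)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_composition"] = list(self.base_composition)
        return d


@dataclass
class GroundTruth:
    """Planted truth; consumed only by tests and evaluation code."""

    ligand_gene_ids: set[str] = field(default_factory=set)
    #: per gene, (start, end) 0-based half-open in 3'UTR transcript-local coords
    planted_site_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class Transcriptome:
    genes: dict[str, GeneModel]
    chrom: str
    chrom_seq: str
    utr3_seqs: dict[str, str]  # transcript orientation, DNA alphabet
    expression: pd.Series  # index = gene_id, TPM-like

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


def _lognormal_lengths(rng: np.random.Generator, mean: float, sd: float, n: int,
                       minimum: int) -> np.ndarray:
    """Integer lengths from a log-normal with the requested arithmetic mean/sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.maximum(minimum, np.round(rng.lognormal(mu, np.sqrt(sigma2), size=n))).astype(int)


def simulate_transcriptome(cfg: SimulationConfig) -> tuple[Transcriptome, GroundTruth]:
    """Lay out ``n_genes`` single-isoform genes on one synthetic chromosome and
    plant ``sites_per_ligand`` motif-rich binding sites in the 3'UTR of each of
    ``n_ligands`` randomly chosen ligand genes."""
    cfg.validate()
    rng = substream(cfg.seed, "transcriptome")
    n = cfg.n_genes
    if n == 0:
        empty = Transcriptome({}, "chrS", "", {}, pd.Series(dtype=float, name="expression"))
        return empty, GroundTruth()

    width = max(4, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    l5 = _lognormal_lengths(rng, cfg.utr5_len_mean, cfg.utr5_len_mean / 2, n, 30)
    lcds = _lognormal_lengths(rng, cfg.cds_len_mean, cfg.cds_len_mean / 3, n, 90)
    l3 = _lognormal_lengths(rng, cfg.utr3_len_mean, cfg.utr3_len_sd, n,
                            max(60, 2 * len(cfg.site_motif)))
    has_intron = rng.random(n) < cfg.intron_prob
    lint = np.where(has_intron,
                    _lognormal_lengths(rng, cfg.intron_len_mean, cfg.intron_len_mean / 2, n, 60),
                    0)
    strands = np.where(rng.random(n) < cfg.minus_strand_fraction, "-", "+")

    genes: dict[str, GeneModel] = {}
    cursor = cfg.intergenic_gap
    for i, gid in enumerate(gene_ids):
        # transcript-order blocks: 5'UTR, CDS(1), [intron, CDS(2)], 3'UTR
        if has_intron[i]:
            half = int(lcds[i]) // 2
            blocks = [("5UTR", int(l5[i])), ("CDS", half), ("intron", int(lint[i])),
                      ("CDS", int(lcds[i]) - half), ("3UTR", int(l3[i]))]
        else:
            blocks = [("5UTR", int(l5[i])), ("CDS", int(lcds[i])), ("3UTR", int(l3[i]))]
        if strands[i] == "-":
            blocks = blocks[::-1]  # genomic order reverses on the minus strand
        start = cursor
        feats: dict[str, list[tuple[int, int]]] = {"5UTR": [], "CDS": [], "intron": [], "3UTR": []}
        for label, length in blocks:
            feats[label].append((cursor, cursor + length))
            cursor += length
        genes[gid] = GeneModel(
            gene_id=gid, chrom="chrS", strand=str(strands[i]), start=start, end=cursor,
            five_prime_utr=feats["5UTR"], cds=feats["CDS"], introns=feats["intron"],
            three_prime_utr=feats["3UTR"],
        )
        cursor += cfg.intergenic_gap
    chrom_len = cursor

    comp = np.asarray(cfg.base_composition, dtype=float)
    seq = rng.choice(np.array(list("ACGT")), size=chrom_len, p=comp / comp.sum())

    ligands = sorted(rng.choice(gene_ids, size=cfg.n_ligands, replace=False).tolist())
    motif = cfg.site_motif.upper().replace("U", "T")
    m = len(motif)
    truth = GroundTruth(ligand_gene_ids=set(ligands), planted_site_intervals={})
    for gid in ligands:
        gene = genes[gid]
        u0, u1 = gene.utr3_interval()
        ulen = u1 - u0
        k = min(cfg.sites_per_ligand, ulen // m)
        # one site per equal segment of the UTR guarantees non-overlap
        seg = ulen // k
        sites = []
        for j in range(k):
            off = j * seg + int(rng.integers(0, seg - m + 1))
            sites.append((off, off + m))
            if gene.strand == "+":
                seq[u0 + off:u0 + off + m] = list(motif)
            else:
                seq[u1 - off - m:u1 - off] = list(_revcomp(motif))
        truth.planted_site_intervals[gid] = sites

    chrom_seq = "".join(seq)
    utr3_seqs = {}
    for gid, gene in genes.items():
        u0, u1 = gene.utr3_interval()
        s = chrom_seq[u0:u1]
        utr3_seqs[gid] = s if gene.strand == "+" else _revcomp(s)

    expr = pd.Series(
        rng.lognormal(cfg.expression_lognormal_mu, cfg.expression_lognormal_sigma, size=n),
        index=gene_ids, name="expression",
    )
    return Transcriptome(genes, "chrS", chrom_seq, utr3_seqs, expr), truth


def _simulate_events_one_gene(rng: np.random.Generator, gene: GeneModel,
                              n_events: int, signal_fraction: float,
                              sites: list[tuple[int, int]] | None) -> np.ndarray:
    """Genomic positions of individual cross-link events for one gene."""
    if n_events == 0:
        return np.empty(0, dtype=int)
    pos = rng.integers(gene.start, gene.end, size=n_events)
    if sites and signal_fraction > 0:
        in_site = rng.random(n_events) < signal_fraction
        k = int(in_site.sum())
        if k:
            u0, u1 = gene.utr3_interval()
            idx = rng.integers(0, len(sites), size=k)
            starts = np.array([s for s, _ in sites])
            lens = np.array([e - s for s, e in sites])
            local = starts[idx] + rng.integers(0, lens.max(), size=k) % lens[idx]
            if gene.strand == "+":
                gpos = u0 + local
            else:
                gpos = u1 - 1 - local
            pos[in_site] = gpos
    return pos


def simulate_clip_events(cfg: SimulationConfig, transcriptome: Transcriptome,
                         truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two iCLIP pseudo-experiments.

    Per gene, the event count is Poisson(expression x reads_per_gene_scale x
    depth_factor); each event falls into a planted site with probability
    ``signal_fraction`` (ligand genes only), otherwise lands uniformly on the
    gene's genomic span (introns included).  Events are aggregated into
    cross-link sites scored by event count, so per gene the site scores sum
    to the number of simulated events.

    Returns one site table per experiment with columns
    (chrom, pos, strand, score, gene_id).
    """
    cfg.validate()
    tables = []
    for exp_name, depth in (("clip1", cfg.depth_factor_exp1), ("clip2", cfg.depth_factor_exp2)):
        if depth <= 0:
            raise ValueError("depth factor must be > 0")
        rng = substream(cfg.seed, f"events-{exp_name}")
        rows = []
        for gid, gene in transcriptome.genes.items():
            lam = transcriptome.expression[gid] * cfg.reads_per_gene_scale * depth
            n_events = int(rng.poisson(lam))
            sites = truth.planted_site_intervals.get(gid) if gid in truth.ligand_gene_ids else None
            pos = _simulate_events_one_gene(rng, gene, n_events, cfg.signal_fraction, sites)
            if pos.size == 0:
                continue
            upos, counts = np.unique(pos, return_counts=True)
            rows.append(pd.DataFrame({
                "chrom": gene.chrom, "pos": upos, "strand": gene.strand,
                "score": counts.astype(int), "gene_id": gid,
            }))
        if rows:
            table = pd.concat(rows, ignore_index=True)
            table = table.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                                      ignore_index=True)
        else:
            table = pd.DataFrame(columns=["chrom", "pos", "strand", "score", "gene_id"])
        tables.append(table)
    return tables[0], tables[1]


def simulate_de_table(cfg: SimulationConfig, truth: GroundTruth,
                      gene_ids: list[str]) -> pd.DataFrame:
    """Knockout-vs-wild-type differential expression with ligands upregulated.

    Non-ligand genes draw log2FC ~ Normal(0, sd); ligand genes are shifted by
    ``de_lfc_mean`` (positive = up in the knockout).  P-values derive from the
    same draw (two-sided normal on log2FC/sd), so null p-values are exactly
    Uniform(0,1) and ligand p-values are correspondingly small.  FDR is
    Benjamini-Hochberg.
    """
    from statsmodels.stats.multitest import multipletests

    rng = substream(cfg.seed, "de")
    is_ligand = np.array([g in truth.ligand_gene_ids for g in gene_ids])
    lfc = rng.normal(0.0, cfg.de_lfc_sd, size=len(gene_ids))
    lfc[is_ligand] += cfg.de_lfc_mean
    pvals = 2.0 * stats.norm.sf(np.abs(lfc) / cfg.de_lfc_sd)
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(gene_ids) else np.empty(0)
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc, "pvalue": pvals, "fdr": fdr})


def simulate_annotations(cfg: SimulationConfig, truth: GroundTruth,
                         gene_ids: list[str]) -> pd.DataFrame:
    """Funnel annotation resources: citation counts (negative binomial, ligand
    mean scaled up), disease-list membership (Bernoulli, elevated among
    ligands) and a continuous lens-enrichment score (ligands shifted)."""
    rng = substream(cfg.seed, "annotations")
    n = len(gene_ids)
    is_ligand = np.array([g in truth.ligand_gene_ids for g in gene_ids], dtype=bool)

    mean = np.where(is_ligand, cfg.pubs_nb_mean * cfg.pubs_ligand_factor, cfg.pubs_nb_mean)
    r = 1.0 / cfg.pubs_nb_alpha
    p = r / (r + mean)
    n_pubs = rng.negative_binomial(r, p, size=n) if n else np.empty(0, dtype=int)

    disease_rate = np.where(is_ligand, cfg.disease_rate_ligand, cfg.disease_rate_background)
    in_disease = rng.random(n) < disease_rate

    lens = rng.normal(0.0, 1.0, size=n) + np.where(is_ligand,
                                                   cfg.lens_enrichment_ligand_shift, 0.0)
    return pd.DataFrame({
        "gene_id": gene_ids,
        "expressed": True,
        "n_pubs": n_pubs.astype(int),
        "in_disease_list": in_disease,
        "lens_enrichment": lens,
    })


def emit_alignments(transcriptome: Transcriptome, sites: pd.DataFrame,
                    read_len: int = 25, offset: int = -1) -> str:
    """Thin SAM emitter: one read per event whose 5' end sits ``-offset`` nt
    downstream of the cross-link, so :func:`clipfunnel.peaks.derive_crosslink_sites`
    with the same offset recovers the input site table exactly."""
    chrom, L = transcriptome.chrom, len(transcriptome.chrom_seq)
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{L}"]
    records = []
    for row in sites.itertuples(index=False):
        pos, strand, score = int(row.pos), row.strand, int(row.score)
        if strand == "+":
            start = pos - offset  # 5' end of the read
            span = (start, start + read_len)
            flag = 0
        else:
            five = pos + offset  # 5'-terminal aligned base on the reference
            span = (five - read_len + 1, five + 1)
            flag = 16
        if span[0] < 0 or span[1] > L:
            continue
        seq = transcriptome.chrom_seq[span[0]:span[1]]
        for k in range(score):
            qname = f"r_{row.gene_id}_{pos}_{k}"
            records.append((span[0], f"{qname}\t{flag}\t{chrom}\t{span[0] + 1}\t255\t"
                                     f"{read_len}M\t*\t0\t0\t{seq}\t*"))
    records.sort(key=lambda t: (t[0], t[1]))
    lines.extend(r for _, r in records)
    return "\n".join(lines) + "\n"


def simulate_luciferase_wells(effects: dict[str, float], control_construct: str = "empty",
                              n_bio: int = 6, n_tech: int = 4, sigma: float = 0.05,
                              seed: int = 0) -> pd.DataFrame:
    """Dual-luciferase wells with a planted per-construct log2 effect.

    ``effects`` maps construct_id -> true log2 activity under the effector
    relative to the control effector; the control construct is added with
    effect 0.  Noise is multiplicative (2**Normal(0, sigma)) on firefly, and
    each biological replicate carries its own multiplicative batch factor,
    which the normalization chain must cancel.
    """
    rng = np.random.default_rng(seed)
    constructs = dict(effects)
    constructs.setdefault(control_construct, 0.0)
    rows = []
    for b in range(1, n_bio + 1):
        batch = 2.0 ** rng.normal(0.0, 0.5)  # per-replicate transfection efficiency
        for construct, eff in sorted(constructs.items()):
            base_fr = 2.0 ** rng.normal(0.0, 0.2)  # construct/bio-rep baseline F/R
            for condition in ("effector", "control_effector"):
                shift = eff if condition == "effector" else 0.0
                for t in range(1, n_tech + 1):
                    renilla = 1000.0 * batch * 2.0 ** rng.normal(0.0, sigma)
                    firefly = renilla * base_fr * 2.0 ** (shift + rng.normal(0.0, sigma))
                    rows.append((construct, condition, f"b{b}", f"t{t}", firefly, renilla))
    return pd.DataFrame(rows, columns=["construct_id", "condition", "biological_replicate",
                                       "technical_replicate", "firefly", "renilla"])
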