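"""Readers and writers: BED6 cross-link sites, GTF gene models, FASTA,
TSV tables, ground-truth JSON.  Internal coordinates are 0-based half-open;
GTF (1-based inclusive) is converted at this boundary."""
from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FEATURE_TO_REGION, REGION_TO_FEATURE, GeneModel
from .simulate import GroundTruth


# ---------------------------------------------------------------------------
# BED6 cross-link sites

def read_crosslink_bed(path) -> pd.DataFrame:
    """Read a BED6 of single-nucleotide cross-link sites.

    Column 4 (name) carries the gene id, column 5 the integer read count.
    Malformed lines are rejected with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i - start_i != 1:
                raise ValueError(f"{path}:{lineno}: cross-link interval must have width 1")
            try:
                score_i = int(score)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: score must be an integer read count") from None
            if score_i < 1:
                raise ValueError(f"{path}:{lineno}: score must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
            rows.append((chrom, start_i, strand, score_i, name))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score", "gene_id"])


def write_crosslink_bed(sites: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in sites.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.pos)}\t{int(r.pos) + 1}\t{r.gene_id}\t"
                     f"{int(r.score)}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# GTF gene models

def read_gene_models(path) -> dict[str, GeneModel]:
    """Parse a GTF into GeneModel objects (gene, five_prime_utr, CDS,
    three_prime_utr and intron features; 1-based inclusive -> 0-based
    half-open)."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    feats: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for f in gffutils.iterators.DataIterator(str(path)):
        attrs = dict(f.attributes)
        if "gene_id" not in attrs:
            raise ValueError(f"feature without gene_id attribute at {f.seqid}:{f.start}")
        gid = attrs["gene_id"][0]
        iv = (f.start - 1, f.end)
        if f.featuretype == "gene":
            spans[gid] = (f.seqid, f.strand, iv[0], iv[1])
        elif f.featuretype in FEATURE_TO_REGION:
            region = FEATURE_TO_REGION[f.featuretype]
            feats.setdefault(gid, {"5UTR": [], "CDS": [], "intron": [], "3UTR": []})
            feats[gid][region].append(iv)
    genes: dict[str, GeneModel] = {}
    for gid, (chrom, strand, start, end) in spans.items():
        f = feats.get(gid, {"5UTR": [], "CDS": [], "intron": [], "3UTR": []})
        ivs = sorted(iv for lst in f.values() for iv in lst)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{gid}: overlapping features [{s1},{e1}) and [{s2},{e2})")
        genes[gid] = GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, start=start, end=end,
            five_prime_utr=sorted(f["5UTR"]), cds=sorted(f["CDS"]),
            introns=sorted(f["intron"]), three_prime_utr=sorted(f["3UTR"]),
        )
    return genes


def write_gtf(genes: dict[str, GeneModel], path, source: str = "clipfunnel") -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes):
            g = genes[gid]
            attr = f'gene_id "{gid}";'

            def line(ftype: str, s: int, e: int) -> str:
                return (f"{g.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attr}\n")

            fh.write(line("gene", g.start, g.end))
            for region, ivs in g.regions().items():
                ftype = REGION_TO_FEATURE[region]
                for s, e in sorted(ivs):
                    fh.write(line(ftype, s, e))


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables and JSON ground truth

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "ligand_gene_ids": sorted(truth.ligand_gene_ids),
        "planted_site_intervals": {
            g: [list(iv) for iv in ivs]
            for g, ivs in sorted(truth.planted_site_intervals.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        ligand_gene_ids=set(payload["ligand_gene_ids"]),
        planted_site_intervals={
            g: [tuple(iv) for iv in ivs]
            for g, ivs in payload["planted_site_intervals"].items()
        },
    )


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
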