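"""File-format I/O: VCF 4.2, BED masks, TSV resources, MEME motifs.

All text formats are uncompressed. VCF coordinates are 1-based on disk and in
:class:`~clonehema.types.VariantCall`; BED intervals are 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import motifs as bio_motifs
from intervaltree import IntervalTree

from .channels import CHANNELS
from .types import MutationCatalog, SignatureProfile, SiteKey, VariantCall

# ---------------------------------------------------------------- VCF

_VCF_HEADER_LINES = [
    '##FILTER=<ID=LowQual,Description="Failed caller quality filter">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=GLC,Number=0,Type=Flag,Description="Also found by germline calling">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def write_vcf(
    calls: Sequence[VariantCall],
    path: str,
    sample_id: str,
    contigs: dict[str, int],
) -> None:
    """Write calls for one sample as a sorted uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    header.add_sample(sample_id)

    order = {name: i for i, name in enumerate(contigs)}
    calls = sorted(calls, key=lambda c: (order.get(c.chrom, len(order)), c.pos))
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt)
            )
            rec.filter.add("PASS" if c.caller_pass else "LowQual")
            if c.gene is not None:
                rec.info["GENE"] = c.gene
            if c.consequence is not None:
                rec.info["CSQ"] = c.consequence
            if c.germline_called:
                rec.info["GLC"] = True
            if c.depth is not None and c.alt_reads is not None:
                rec.samples[sample_id]["AD"] = (c.depth - c.alt_reads, c.alt_reads)
                rec.samples[sample_id]["DP"] = c.depth
            out.write(rec)


def read_vcf(path: str, sample_id: Optional[str] = None) -> list[VariantCall]:
    """Read one-sample VCF into VariantCall records.

    VAF is recomputed from AD/DP when present (reproducibility over trust in
    caller-reported fields).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        sid = sample_id or (samples[0] if samples else "unknown")
        for rec in vf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            ad = dp = None
            if samples:
                fmt = rec.samples[samples[0]]
                if fmt.get("AD") is not None:
                    ad = fmt["AD"][1]
                if fmt.get("DP") is not None:
                    dp = fmt["DP"]
            vaf = (ad / dp) if (ad is not None and dp) else 0.0
            calls.append(
                VariantCall(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_reads=ad,
                    depth=dp,
                    vaf=vaf,
                    caller_pass=("PASS" in rec.filter or len(rec.filter) == 0),
                    sample_id=sid,
                    gene=rec.info.get("GENE"),
                    consequence=rec.info.get("CSQ"),
                    germline_called=bool(rec.info.get("GLC", False)),
                )
            )
    return calls


# ---------------------------------------------------------------- BED / masks


def read_bed(path: str) -> dict[str, IntervalTree]:
    """Read a BED file into per-chromosome interval trees (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise ValueError(f"invalid BED interval: {line}")
            data = fields[3] if len(fields) > 3 else None
            trees.setdefault(chrom, IntervalTree()).addi(start, end, data)
    return trees


def write_bed(intervals: Iterable[tuple[str, int, int, Optional[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            if name is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------- TSV tables


def read_frequency_tsv(path: str) -> dict[SiteKey, float]:
    """TSV with columns chrom, pos, ref, alt, af -> site-keyed frequencies."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(r.af)
        for r in df.itertuples()
    }


def write_frequency_tsv(freqs: dict[SiteKey, float], path: str) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "af": v}
        for k, v in sorted(freqs.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


def write_catalog_tsv(catalogs: Sequence[MutationCatalog], path: str) -> None:
    """96 rows (channel labels) x one column per sample."""
    df = pd.DataFrame(
        {c.sample_id: c.counts.astype(int) for c in catalogs},
        index=list(CHANNELS),
    )
    df.to_csv(path, sep="\t", index_label="channel")


def read_catalog_tsv(path: str) -> list[MutationCatalog]:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    if list(df.index) != list(CHANNELS):
        raise ValueError("catalog TSV channels are not in canonical SBS96 order")
    return [MutationCatalog(col, df[col].to_numpy(float)) for col in df.columns]


def write_signature_tsv(signatures: Sequence[SignatureProfile], path: str) -> None:
    df = pd.DataFrame(
        {s.name: s.probs for s in signatures}, index=list(CHANNELS)
    )
    df.to_csv(path, sep="\t", index_label="channel")


def read_signature_tsv(path: str) -> list[SignatureProfile]:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    if list(df.index) != list(CHANNELS):
        raise ValueError("signature TSV channels are not in canonical SBS96 order")
    return [SignatureProfile(col, df[col].to_numpy(float)) for col in df.columns]


# ---------------------------------------------------------------- MEME motifs


def read_meme(path: str):
    """Read a minimal-MEME motif file; returns Bio.motifs motif objects."""
    with open(path) as fh:
        return bio_motifs.parse(fh, "minimal")


def write_meme_minimal(
    motif_matrices: dict[str, np.ndarray],
    path: str,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write position probability matrices (L x 4, ACGT) in minimal MEME format."""
    bg = list(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for name, mat in motif_matrices.items():
            mat = np.asarray(mat, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
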