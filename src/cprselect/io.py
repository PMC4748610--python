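"""Readers and writers for the pipeline's on-disk formats.

Per-CPR alignments travel as FASTA (one record per line ID), SNP calls as
VCF v4.2 with haploid genotypes, CPR intervals as BED (0-based half-open),
expression as a TSV (transcript, line, sex, replicate, value[, heritability]),
motifs as JASPAR count matrices, per-base depth as samtools-depth-style TSV,
and the synthetic truth record as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CprAlignment
from .duplication import DepthTrack
from .linkage import HaplotypeMatrix

__all__ = [
    "write_fasta_alignment",
    "read_fasta_alignment",
    "write_bed",
    "read_bed",
    "write_expression",
    "read_expression",
    "write_vcf",
    "read_vcf",
    "write_depth",
    "read_depth",
    "write_truth",
    "read_truth",
    "alignment_from_vcf",
]


def write_fasta_alignment(aln: CprAlignment, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=lid, description=aln.cpr_id)
        for lid, seq in aln.haplotypes().items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta_alignment(
    path, cpr_id: str = "cpr", chrom: str = "chr", start: int = 0, strand: str = "+"
) -> CprAlignment:
    from Bio import SeqIO

    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return CprAlignment.from_strings(
        pairs, cpr_id=cpr_id, chrom=chrom, start=start, strand=strand
    )


def write_bed(intervals: dict[str, tuple[str, int, int]], path) -> None:
    """``intervals``: cpr_id -> (chrom, start, end), 0-based half-open."""
    with open(path, "w") as fh:
        for cpr_id, (chrom, start, end) in intervals.items():
            fh.write(f"{chrom}\t{start}\t{end}\t{cpr_id}\n")


def read_bed(path) -> dict[str, tuple[str, int, int]]:
    out: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"region{i}"
            out[name] = (parts[0], int(parts[1]), int(parts[2]))
    return out


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript", "line", "sex", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def write_vcf(h: HaplotypeMatrix, path) -> None:
    """Plain-text VCF v4.2 with one haploid GT column per line."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={h.chrom}>\n")
        cols = "\t".join(h.line_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(h.n_snps):
            gts = "\t".join(
                "." if c == -1 else str(int(c)) for c in h.codes[:, j]
            )
            fh.write(
                f"{h.chrom}\t{h.positions[j]}\t.\t{h.ref[j]}\t{h.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> HaplotypeMatrix:
    """Read a haploid biallelic VCF back into a HaplotypeMatrix."""
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[list[int]] = []
    line_ids: list[str] = []
    chrom = "chr"
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                line_ids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom = parts[0]
            positions.append(int(parts[1]))
            ref.append(parts[3])
            alt.append(parts[4])
            calls = []
            for g in parts[9:]:
                g = g.split(":")[0]
                if g in (".", "./.", ".|."):
                    calls.append(-1)
                else:
                    calls.append(int(g.replace("|", "/").split("/")[0]))
            rows.append(calls)
    codes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(line_ids), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=int),
        ref=ref,
        alt=alt,
        line_ids=line_ids,
        codes=codes,
    )


def alignment_from_vcf(
    h: HaplotypeMatrix,
    cpr_id: str,
    chrom: str,
    start: int,
    end: int,
    reference: str,
) -> CprAlignment:
    """Reconstruct per-line haplotype sequences from homozygous SNP calls.

    ``reference`` is the CPR reference sequence over [start, end); SNPs with
    positions inside the interval substitute their ALT base for carriers and
    N for missing calls.
    """
    L = end - start
    if len(reference) != L:
        raise ValueError("reference length must match the interval")
    seqs = np.tile(np.array(list(reference.upper()), dtype="<U1"), (len(h.line_ids), 1))
    for j in h.in_interval(start + 1, end):
        col = h.positions[j] - 1 - start
        codes = h.codes[:, j]
        seqs[codes == 1, col] = h.alt[j].upper()
        seqs[codes == -1, col] = "N"
        seqs[codes == 0, col] = h.ref[j].upper()
    return CprAlignment(
        cpr_id=cpr_id,
        chrom=chrom,
        start=start,
        end=end,
        strand="+",
        line_ids=list(h.line_ids),
        seqs=seqs,
    )


def write_depth(tracks: dict[str, DepthTrack], path) -> None:
    """samtools-depth-style TSV: chrom, 1-based pos, one depth column per line."""
    lines = sorted(tracks)
    first = tracks[lines[0]]
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(lines) + "\n")
        for pos in first.depth.index:
            vals = "\t".join(str(int(tracks[l].depth.get(pos, 0))) for l in lines)
            fh.write(f"{first.chrom}\t{pos}\t{vals}\n")


def read_depth(path, genes: pd.DataFrame) -> dict[str, DepthTrack]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    chrom = df["chrom"].iloc[0]
    out = {}
    for col in df.columns[2:]:
        out[col] = DepthTrack(
            line_id=col,
            chrom=chrom,
            depth=pd.Series(df[col].to_numpy(dtype=float), index=df["pos"].to_numpy()),
            genes=genes,
        )
    return out


def write_truth(truth, path) -> None:
    import yaml

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(truth.to_dict()), fh, sort_keys=True)


def read_truth(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def write_cohort(cohort, outdir) -> None:
    """Persist a synthetic cohort to a directory of plain-text files."""
    from .motifs import write_jaspar

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(cohort.cpr_intervals, out / "cprs.bed")
    write_expression(cohort.expression, out / "expression.tsv")
    write_jaspar(cohort.motifs, out / "motifs.jaspar")
    write_truth(cohort.truth, out / "truth.yaml")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for cpr_id, aln in cohort.cpr_alignments.items():
        write_fasta_alignment(aln, aln_dir / f"{cpr_id}.fasta")
    vcf_dir = out / "flanks"
    vcf_dir.mkdir(exist_ok=True)
    for cpr_id, h in cohort.flank_haplotypes.items():
        write_vcf(h, vcf_dir / f"{cpr_id}.vcf")
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    by_cpr: dict[str, dict[str, DepthTrack]] = {}
    for (lid, cpr_id), tr in cohort.depth_tracks.items():
        by_cpr.setdefault(cpr_id, {})[lid] = tr
    for cpr_id, tracks in by_cpr.items():
        write_depth(tracks, depth_dir / f"{cpr_id}.depth.tsv")
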