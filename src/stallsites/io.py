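"""Readers and writers for the pipeline's plain-text interchange formats.

Canonical formats: FASTA for transcript and aligned sequences (gap
character '-'), TSV for footprints (transcript_id, five_prime_pos, length,
count), offsets (length, offset_nt), annotation, peak and conserved-site
tables, and a minimal VCF-like/2-column TSV for SNPs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_footprints(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_footprints(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "five_prime_pos", "length", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    return df


def write_offsets(offsets: Mapping[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(offsets.items()), columns=["length", "offset_nt"]
    ).to_csv(path, sep="\t", index=False)


def read_offsets(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["length"].astype(int), df["offset_nt"].astype(int)))


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Flat TSV annotation (canonical) or a transcript-space GTF subset."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf_transcript_space(path)
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


def _read_gtf_transcript_space(path: Path) -> pd.DataFrame:
    """Parse transcript/exon/CDS features of a GTF whose coordinates are in
    transcript space (1-based, inclusive; converted to 0-based half-open).
    Genome-coordinate GTFs are not supported."""
    records: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            feature, start, end, attrs = (
                fields[2], int(fields[3]) - 1, int(fields[4]), fields[8]
            )
            attr = dict(
                (kv.strip().split(" ", 1)[0],
                 kv.strip().split(" ", 1)[1].strip('"'))
                for kv in attrs.rstrip(";").split(";")
                if kv.strip()
            )
            tx = attr.get("transcript_id")
            if tx is None:
                continue
            rec = records.setdefault(
                tx,
                {
                    "transcript_id": tx,
                    "gene_id": attr.get("gene_id", tx),
                    "organism": attr.get("organism", ""),
                    "transcript_length": 0,
                    "cds_start": None,
                    "cds_end": None,
                    "exon_bounds": [],
                },
            )
            if feature == "transcript":
                rec["transcript_length"] = end - start
            elif feature == "exon":
                rec["exon_bounds"].append((start, end))
            elif feature == "CDS":
                rec["cds_start"] = start if rec["cds_start"] is None else min(
                    rec["cds_start"], start
                )
                rec["cds_end"] = end if rec["cds_end"] is None else max(
                    rec["cds_end"], end
                )
    rows = []
    for rec in records.values():
        bounds = sorted(rec.pop("exon_bounds"))
        if rec["transcript_length"] == 0 and bounds:
            rec["transcript_length"] = bounds[-1][1]
        rec["exon_boundaries"] = ";".join(str(e) for _, e in bounds[:-1])
        rows.append(rec)
    return pd.DataFrame(rows)


def read_snps(path: str | Path) -> pd.DataFrame:
    """Minimal VCF (CHROM used as transcript id, POS 1-based) or a TSV with
    transcript_id / pos columns (0-based)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split("\t")
                rows.append(
                    {
                        "transcript_id": f[0],
                        "pos": int(f[1]) - 1,
                        "ref": f[3],
                        "alt": f[4],
                    }
                )
        return pd.DataFrame(rows, columns=["transcript_id", "pos", "ref", "alt"])
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "pos"} <= set(df.columns):
        raise ValueError("SNP table needs transcript_id and pos columns")
    return df


def write_snps_vcf(snps: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in snps.iterrows():
            fh.write(
                f"{row['transcript_id']}\t{int(row['pos']) + 1}\t.\t"
                f"{row.get('ref', 'N')}\t{row.get('alt', 'N')}\t.\tPASS\t.\n"
            )
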