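"""Readers and writers for the pipeline's on-disk formats.

FASTA and FASTQ go through Biopython; BED/GFF3/TSV tables through pandas.
Coordinates are 0-based half-open internally and in BED; GFF3 is written
1-based inclusive as the format requires.  Every reader raises
:class:`FormatError` naming the file (and where possible the line) on
malformed input, and ``read(write(x)) == x`` round-trips hold for all
formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import ReferenceSet
from .simulate import ReadPair

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------- FASTA


def write_fasta(refset: ReferenceSet, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in refset.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> ReferenceSet:
    try:
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceSet(records)


# --------------------------------------------------------------------- FASTQ


def write_fastq_pairs(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    def rec(rid: str, seq: str, qual: np.ndarray) -> SeqRecord:
        r = SeqRecord(Seq(seq), id=rid, description="")
        r.letter_annotations["phred_quality"] = [int(q) for q in qual]
        return r

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            SeqIO.write([rec(p.read_id, p.seq1, p.qual1)], f1, "fastq")
            SeqIO.write([rec(p.read_id, p.seq2, p.qual2)], f2, "fastq")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    def load(path):
        try:
            return [
                (r.id, str(r.seq), np.array(r.letter_annotations["phred_quality"], dtype=np.int64))
                for r in SeqIO.parse(str(path), "fastq")
            ]
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    m1, m2 = load(r1_path), load(r2_path)
    if len(m1) != len(m2):
        raise FormatError(f"{r1_path}/{r2_path}: mate counts differ ({len(m1)} vs {len(m2)})")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(m1, m2):
        if id1 != id2:
            raise FormatError(f"{r1_path}: mate id mismatch {id1!r} vs {id2!r}")
        pairs.append(ReadPair(id1, s1, s2, q1, q2, source="junction"))
    return pairs


# ----------------------------------------------------------------- BED/GFF3


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=BED_COLUMNS, usecols=range(6),
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for i, (s, e) in enumerate(zip(df["start"], df["end"])):
        if e <= s:
            raise FormatError(f"{path}: line {i + 1}: end {e} <= start {s}")
    return df


def write_gff3(df: pd.DataFrame, path: str | Path, source: str = "piggytools",
               feature: str = "dispersed_repeat") -> None:
    """BED-like frame (contig, start, end, family, strand) to GFF3 (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in df.iterrows():
            attrs = f"Name={row.get('family', row.get('name', '.'))}"
            fh.write(
                "\t".join(
                    [
                        str(row["contig"]), source, feature,
                        str(int(row["start"]) + 1), str(int(row["end"])),
                        ".", str(row.get("strand", "+")), ".", attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """GFF3 to a BED-like frame (0-based half-open, family from Name=)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(parts)}")
            contig, _src, _feat, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad coordinates") from exc
            family = "."
            for kv in attrs.split(";"):
                if kv.startswith("Name="):
                    family = kv[5:]
            rows.append((contig, start_i, end_i, family, 0, strand))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "family", "score", "strand"])


# ------------------------------------------------------------------ TSV/JSON


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
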