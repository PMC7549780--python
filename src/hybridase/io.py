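"""Standard-format adapters: FASTA, FASTQ (Phred+33), minimal SAM, TSV.

FASTA/FASTQ go through Biopython SeqIO; SAM through pysam.  Internal
coordinates are 0-based half-open; SAM conversion to 1-based POS is
handled by pysam.  Files the package writes round-trip byte-identically.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import ParentalReferencePair

QUALITY_CHAR = "I"  # constant Phred+33 quality 40; qualities are unused downstream


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_reference_pair(
    refs: ParentalReferencePair, path_a: str, path_b: str
) -> None:
    write_fasta(path_a, zip(refs.gene_ids, refs.seqs_a))
    write_fasta(path_b, zip(refs.gene_ids, refs.seqs_b))


def read_reference_pair(
    path_a: str, path_b: str, divergence_rate: float = float("nan"), seed: int = -1
) -> ParentalReferencePair:
    rec_a, rec_b = read_fasta(path_a), read_fasta(path_b)
    ids_a = [r[0] for r in rec_a]
    ids_b = [r[0] for r in rec_b]
    if ids_a != ids_b:
        raise ValueError("reference FASTA files disagree on gene ids or order")
    return ParentalReferencePair(
        ids_a, [r[1] for r in rec_a], [r[1] for r in rec_b], divergence_rate, seed
    )


def write_fastq_pairs(
    records: Sequence[tuple[str, str, str]], path_r1: str, path_r2: str
) -> None:
    """Write (read_id, mate1, mate2) triples as an R1/R2 FASTQ pair."""

    def _rec(rid: str, seq: str, mate: int) -> SeqRecord:
        r = SeqRecord(Seq(seq), id=f"{rid}/{mate}", description="")
        r.letter_annotations["phred_quality"] = [
            ord(QUALITY_CHAR) - 33
        ] * len(seq)
        return r

    SeqIO.write((_rec(rid, m1, 1) for rid, m1, _ in records), str(path_r1), "fastq")
    SeqIO.write((_rec(rid, m2, 2) for rid, _, m2 in records), str(path_r2), "fastq")


def read_fastq_pairs(path_r1: str, path_r2: str) -> list[tuple[str, str, str]]:
    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 FASTQ files have different record counts")
    out = []
    for a, b in zip(r1, r2):
        ida, idb = a.id.rsplit("/", 1)[0], b.id.rsplit("/", 1)[0]
        if ida != idb:
            raise ValueError(f"mate id mismatch: {a.id} vs {b.id}")
        out.append((ida, str(a.seq), str(b.seq)))
    return out


def sam_header(refs: ParentalReferencePair, genome: str) -> dict:
    seqs = refs.seqs_a if genome == "A" else refs.seqs_b
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g, "LN": len(s)} for g, s in zip(refs.gene_ids, seqs)],
    }


def write_pairs_sam(
    path: str,
    refs: ParentalReferencePair,
    genome: str,
    placements: Iterable[dict],
) -> None:
    """Write accepted concordant pairs as a minimal SAM file.

    Each placement needs: read_id, gene, plus mate fields
    (pos1/strand1/mm1/seq1, pos2/strand2/mm2/seq2) with 0-based internal
    positions.  Flags carry paired/proper-pair/strand/mate-strand; the NM
    tag carries the per-mate mismatch count.
    """
    header = pysam.AlignmentHeader.from_dict(sam_header(refs, genome))
    tid = {g: i for i, g in enumerate(refs.gene_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in placements:
            mates = []
            for mate in (1, 2):
                a = pysam.AlignedSegment(header)
                a.query_name = p["read_id"]
                seq = p[f"seq{mate}"]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    QUALITY_CHAR * len(seq)
                )
                a.reference_id = tid[p["gene"]]
                a.reference_start = p[f"pos{mate}"]
                a.cigarstring = f"{len(seq)}M"
                a.set_tag("NM", int(p[f"mm{mate}"]))
                mates.append(a)
            for i, a in enumerate(mates):
                other = mates[1 - i]
                flag = 1 | 2  # paired, proper pair
                flag |= 64 if i == 0 else 128
                if p[f"strand{i + 1}"] == "-":
                    flag |= 16
                if p[f"strand{2 - i}"] == "-":
                    flag |= 32
                a.flag = flag
                a.next_reference_id = other.reference_id
                a.next_reference_start = other.reference_start
                out.write(a)


def write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_design_table(path: str) -> pd.DataFrame:
    """Sample design table: sample, series, stage, sex, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "series", "stage", "sex", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df.set_index("sample")


def read_annotations(path: str) -> dict[str, set[str]]:
    """Two-column gene→term TSV (optional third column: term name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("annotation table needs columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
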