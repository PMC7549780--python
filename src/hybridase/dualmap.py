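"""Competitive dual-genome read-pair classification.

Read pairs from a hybrid library are aligned to BOTH parental transcript
sets and each pair is classified as A-specific, B-specific, common (maps
concordantly to both genomes, removed before allelic counting), or
discarded with a reason (unmapped, multimapped, too many mismatches is
implicit in the hit filter, orphan, discordant).

The aligner is an exact k-mer seed-and-verify scheme: every location
reachable by any exact k-mer seed of the read (either strand) is verified
by a full-length ungapped (Hamming) comparison, and all locations within
the mismatch budget are returned.  Substitution-only references make
ungapped verification exact; the operative filter is the <=2-mismatch rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simdata import ParentalReferencePair, revcomp

VALID = frozenset(b"ACGTN")
DISCARD_REASONS = ("unmapped", "multimapped", "orphan", "discordant")


@dataclass(frozen=True)
class AlignmentHit:
    """One verified ungapped alignment of a single mate."""

    genome: str  # "A" or "B"
    gene: str
    position: int  # 0-based start of the window on the transcript forward strand
    strand: str  # "+" or "-"
    mismatches: int


@dataclass
class PairAlignment:
    """All verified hits for a read pair, per mate and genome."""

    read_pair_id: str
    hits1: dict[str, list[AlignmentHit]]  # genome -> mate1 hits
    hits2: dict[str, list[AlignmentHit]]
    read_length: int

    def mate_maps(self, genome: str) -> tuple[bool, bool]:
        return bool(self.hits1.get(genome)), bool(self.hits2.get(genome))


@dataclass(frozen=True)
class OriginCall:
    """Final classification of one read pair."""

    read_pair_id: str
    call: str  # A_specific | B_specific | common | discarded
    reason: str | None = None  # set iff call == discarded
    gene: str | None = None  # gene of the accepted concordant pairing
    mismatches: int | None = None  # best pairing mismatch total


class DualIndex:
    """Exact k-mer lookup over the forward strands of both genomes.

    Reverse-strand alignment is handled at query time by also seeding the
    reverse complement of the read, so only forward k-mers are stored.
    """

    def __init__(self, refs: ParentalReferencePair, k: int = 31):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.refs = refs
        self.k = k
        self.gene_ids = refs.gene_ids
        self._arrays = {
            "A": [np.frombuffer(s.encode(), dtype=np.uint8) for s in refs.seqs_a],
            "B": [np.frombuffer(s.encode(), dtype=np.uint8) for s in refs.seqs_b],
        }
        table: dict[bytes, list[tuple[str, int, int]]] = {}
        for genome, seqs in (("A", refs.seqs_a), ("B", refs.seqs_b)):
            for gi, seq in enumerate(seqs):
                enc = seq.encode()
                for pos in range(len(enc) - k + 1):
                    table.setdefault(enc[pos : pos + k], []).append((genome, gi, pos))
        self._table = table

    def n_kmer_positions(self, genome: str, gene: str) -> int:
        """Number of forward k-mer positions recorded for one gene."""
        gi = self.gene_ids.index(gene)
        return sum(
            1
            for locs in self._table.values()
            for g, i, _ in locs
            if g == genome and i == gi
        )

    def map_read(
        self, read: str, genome: str, max_mismatches: int = 2
    ) -> list[AlignmentHit]:
        """Seed-and-verify alignment of one mate against one genome.

        Returns every location (both strands) reachable by an exact k-mer
        seed and verified at <= ``max_mismatches`` full-length Hamming
        distance, each location once.  ``N`` in the read matches nothing
        and therefore counts as a mismatch at every position.
        """
        enc = read.encode()
        if not VALID.issuperset(enc):
            bad = sorted(set(chr(c) for c in enc) - {"A", "C", "G", "T", "N"})
            raise ValueError(f"read contains invalid characters: {bad}")
        k, L = self.k, len(enc)
        if L < k:
            return []
        arrays = self._arrays[genome]
        candidates: set[tuple[int, int, str]] = set()
        for strand, query in (("+", enc), ("-", revcomp(read).encode())):
            for i in range(L - k + 1):
                for g, gi, pos in self._table.get(query[i : i + k], ()):
                    if g != genome:
                        continue
                    start = pos - i
                    if 0 <= start and start + L <= len(arrays[gi]):
                        candidates.add((gi, start, strand))
        hits = []
        q_plus = np.frombuffer(enc, dtype=np.uint8)
        q_minus = np.frombuffer(revcomp(read).encode(), dtype=np.uint8)
        for gi, start, strand in candidates:
            q = q_plus if strand == "+" else q_minus
            mm = int((arrays[gi][start : start + L] != q).sum())
            if mm <= max_mismatches:
                hits.append(AlignmentHit(genome, self.gene_ids[gi], start, strand, mm))
        hits.sort(key=lambda h: (h.gene, h.position, h.strand))
        return hits


def map_read_bruteforce(
    read: str, refs: ParentalReferencePair, genome: str, max_mismatches: int = 2
) -> list[AlignmentHit]:
    """Exhaustive all-window scan; the oracle the seeded search must match
    whenever an intact seed exists."""
    seqs = refs.seqs_a if genome == "A" else refs.seqs_b
    L = len(read)
    hits = []
    for gene, seq in zip(refs.gene_ids, seqs):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, query in (("+", read), ("-", revcomp(read))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            for start in range(len(arr) - L + 1):
                mm = int((arr[start : start + L] != q).sum())
                if mm <= max_mismatches:
                    hits.append(AlignmentHit(genome, gene, start, strand, mm))
    hits.sort(key=lambda h: (h.gene, h.position, h.strand))
    return hits


def _concordant_pairings(
    hits1: Sequence[AlignmentHit],
    hits2: Sequence[AlignmentHit],
    read_length: int,
    fragment_window: tuple[int, int],
) -> list[tuple[str, int, int, int]]:
    """All FR-concordant pairings as (gene, plus_pos, minus_pos, total_mm).

    Concordance: same gene, opposite strands, the forward-strand mate
    upstream, fragment span (minus-mate end - plus-mate start) inside the
    window.
    """
    lo, hi = fragment_window
    by_gene2: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits2:
        by_gene2.setdefault((h.gene, h.strand), []).append(h)
    out = []
    for h1 in hits1:
        other = "-" if h1.strand == "+" else "+"
        for h2 in by_gene2.get((h1.gene, other), ()):
            plus, minus = (h1, h2) if h1.strand == "+" else (h2, h1)
            span = minus.position + read_length - plus.position
            if plus.position <= minus.position and lo <= span <= hi:
                out.append(
                    (h1.gene, plus.position, minus.position, h1.mismatches + h2.mismatches)
                )
    return out


def _best_concordant(
    pa: PairAlignment, genome: str, fragment_window: tuple[int, int]
) -> tuple[str, str | None, int | None]:
    """Resolve one genome to ('none'|'multi'|'unique', gene, best_mm)."""
    pairings = _concordant_pairings(
        pa.hits1.get(genome, ()), pa.hits2.get(genome, ()), pa.read_length, fragment_window
    )
    if not pairings:
        return "none", None, None
    best = min(p[3] for p in pairings)
    locs = {(g, p1, p2) for g, p1, p2, mm in pairings if mm == best}
    if len(locs) > 1:
        return "multi", None, best
    gene = next(iter(locs))[0]
    return "unique", gene, best


def classify_pair(
    pa: PairAlignment,
    mode: str,
    conspecific: str | None = None,
    fragment_window: tuple[int, int] = (150, 350),
) -> OriginCall:
    """Classify one read pair from its dual-genome alignments.

    Decision order: (1) within each consulted genome keep only the
    best-mismatch concordant pairing; more than one distinct best location
    in a genome discards the pair as multimapped; (2) with no concordant
    pairing anywhere, a pair with no mapped mate is unmapped, with exactly
    one mapped mate orphan, otherwise discordant; (3) in hybrid mode a pair
    concordant in A only is A_specific, in B only B_specific, in both
    common (removed from allelic counting); in parental mode only the
    conspecific genome is consulted and any unique concordant pairing is
    accepted.
    """
    if mode not in ("parental", "hybrid"):
        raise ValueError(f"mode must be 'parental' or 'hybrid', got {mode!r}")
    if mode == "parental":
        if conspecific not in ("A", "B"):
            raise ValueError("parental mode requires conspecific genome 'A' or 'B'")
        genomes = [conspecific]
    else:
        genomes = ["A", "B"]

    status = {g: _best_concordant(pa, g, fragment_window) for g in genomes}
    rid = pa.read_pair_id

    if any(st[0] == "multi" for st in status.values()):
        return OriginCall(rid, "discarded", "multimapped")

    concordant = {g: st for g, st in status.items() if st[0] == "unique"}
    if not concordant:
        m1 = any(pa.mate_maps(g)[0] for g in genomes)
        m2 = any(pa.mate_maps(g)[1] for g in genomes)
        if not m1 and not m2:
            return OriginCall(rid, "discarded", "unmapped")
        if m1 != m2:
            return OriginCall(rid, "discarded", "orphan")
        return OriginCall(rid, "discarded", "discordant")

    if mode == "parental":
        _, gene, mm = concordant[conspecific]
        call = "A_specific" if conspecific == "A" else "B_specific"
        return OriginCall(rid, call, gene=gene, mismatches=mm)

    if len(concordant) == 2:
        # presence in both genomes, regardless of which side has fewer mismatches
        _, gene, mm = concordant["A"]
        return OriginCall(rid, "common", gene=gene, mismatches=mm)
    genome = next(iter(concordant))
    _, gene, mm = concordant[genome]
    return OriginCall(
        rid, "A_specific" if genome == "A" else "B_specific", gene=gene, mismatches=mm
    )


def align_pairs(
    records: Iterable[tuple[str, str, str]],
    index: DualIndex,
    max_mismatches: int = 2,
    genomes: Sequence[str] = ("A", "B"),
) -> list[PairAlignment]:
    """Map (read_id, mate1, mate2) records against the consulted genomes."""
    out = []
    for rid, m1, m2 in records:
        hits1 = {g: index.map_read(m1, g, max_mismatches) for g in genomes}
        hits2 = {g: index.map_read(m2, g, max_mismatches) for g in genomes}
        out.append(PairAlignment(rid, hits1, hits2, len(m1)))
    return out


def classify_reads(
    records: Iterable[tuple[str, str, str]],
    index: DualIndex,
    mode: str = "hybrid",
    conspecific: str | None = None,
    max_mismatches: int = 2,
    fragment_window: tuple[int, int] = (150, 350),
) -> list[OriginCall]:
    """Full per-pair pipeline: align to both genomes, then classify."""
    genomes = ("A", "B") if mode == "hybrid" else (conspecific,)
    alignments = align_pairs(records, index, max_mismatches, genomes)
    return [
        classify_pair(pa, mode, conspecific, fragment_window) for pa in alignments
    ]


def _filter_alignment(pa: PairAlignment, max_mm: int) -> PairAlignment:
    return PairAlignment(
        pa.read_pair_id,
        {g: [h for h in hs if h.mismatches <= max_mm] for g, hs in pa.hits1.items()},
        {g: [h for h in hs if h.mismatches <= max_mm] for g, hs in pa.hits2.items()},
        pa.read_length,
    )


def mismatch_sweep(
    records: Sequence[tuple[str, str, str]],
    index: DualIndex,
    max_mm_values: Sequence[int],
    fragment_window: tuple[int, int] = (150, 350),
) -> pd.DataFrame:
    """Classify the same pairs under a sweep of mismatch budgets.

    Returns one row per budget with the fractions of pairs called
    A_specific, B_specific, common and discarded (fractions over ALL input
    pairs; the four sum to 1).  Alignments are computed once at the largest
    budget and re-thresholded, which is exact because a hit at budget t is
    a hit at every larger budget.
    """
    if len(max_mm_values) == 0:
        raise ValueError("max_mm_values must be non-empty")
    if any(v < 0 for v in max_mm_values):
        raise ValueError("mismatch budgets must be >= 0")
    alignments = align_pairs(records, index, max(max_mm_values))
    n = len(alignments)
    rows = []
    for t in max_mm_values:
        calls = [
            classify_pair(_filter_alignment(pa, t), "hybrid", None, fragment_window)
            for pa in alignments
        ]
        counts = {"A_specific": 0, "B_specific": 0, "common": 0, "discarded": 0}
        for c in calls:
            counts[c.call] += 1
        rows.append(
            {
                "max_mismatches": t,
                **{k: v / n if n else 0.0 for k, v in counts.items()},
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_pair_id": c.read_pair_id,
                "call": c.call,
                "reason": c.reason or "",
                "gene": c.gene or "",
                "mismatches": -1 if c.mismatches is None else c.mismatches,
            }
            for c in calls
        ]
    )
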