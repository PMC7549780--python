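"""Synthetic data generation for hybrid allele-specific expression studies.

Emulates the experimental design of a chicken x quail hybrid embryo
transcriptome study: two substitution-diverged parental transcriptomes with
1:1 orthology, a planted per-gene expression program over a
2-stage x 3-series x 2-sex x replicate design, negative-binomial counts, and
paired-end reads with sequencing error.  Every generator records complete
ground truth so downstream classification and recovery can be scored.

Series labels: ``Q`` (quail), ``G`` (chicken), ``H`` (hybrid).  Hybrid
expression is represented allele-wise as ``HQ`` (quail-derived allele) and
``HG`` (chicken-derived allele).  The stage contrast throughout is
blastoderm stage X vs stage XIII/XIV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STAGES = ("X", "XIII_XIV")
SERIES = ("Q", "G", "H")
SEXES = ("M", "F")
DIRECTIONS = ("up", "down", "unaltered")


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class ParentalReferencePair:
    """Two per-gene transcript sets related by substitution-only divergence.

    Orthology is 1:1 and total: gene ``i`` of genome A is the ortholog of
    gene ``i`` of genome B, and the two sequences have identical length
    (no indels), so transcript coordinates are shared between genomes.
    """

    gene_ids: list[str]
    seqs_a: list[str]
    seqs_b: list[str]
    divergence_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not (len(self.gene_ids) == len(self.seqs_a) == len(self.seqs_b)):
            raise ValueError("gene_ids, seqs_a and seqs_b must have equal length")
        for g, a, b in zip(self.gene_ids, self.seqs_a, self.seqs_b):
            if len(a) != len(b):
                raise ValueError(f"gene {g}: sequence lengths differ between genomes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs_a])

    def per_gene_divergence(self) -> np.ndarray:
        """Realized per-gene mismatch fraction between the two genomes."""
        out = np.empty(self.n_genes)
        for i, (a, b) in enumerate(zip(self.seqs_a, self.seqs_b)):
            xa = np.frombuffer(a.encode(), dtype=np.uint8)
            xb = np.frombuffer(b.encode(), dtype=np.uint8)
            out[i] = float((xa != xb).mean())
        return out

    def swapped(self) -> "ParentalReferencePair":
        """Return the pair with genome labels A and B exchanged."""
        return ParentalReferencePair(
            self.gene_ids, list(self.seqs_b), list(self.seqs_a),
            self.divergence_rate, self.seed,
        )


@dataclass
class ExpressionProgram:
    """Planted per-gene truth: baseline mean and stage log2FC per series.

    ``lfc_*`` are the true stage XIII/XIV vs stage X log2 fold changes for
    the quail (Q), chicken (G), hybrid quail-allele (HQ) and hybrid
    chicken-allele (HG) series.  ``true_pattern`` is D for misregulated
    genes (up in both parents, up in neither hybrid allele), A for genes up
    in both parents with concordant hybrid alleles, and "none" otherwise.
    """

    table: pd.DataFrame  # gene, baseline_mean, lfc_Q/G/HQ/HG, dir_*, true_pattern

    SERIES_COLS = ("Q", "G", "HQ", "HG")

    def __post_init__(self) -> None:
        required = {"gene", "baseline_mean", "true_pattern"} | {
            f"lfc_{s}" for s in self.SERIES_COLS
        } | {f"dir_{s}" for s in self.SERIES_COLS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"program table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def true_lfc(self, series: str) -> pd.Series:
        return self.table.set_index("gene")[f"lfc_{series}"]

    def pattern_counts(self) -> dict[str, int]:
        return self.table["true_pattern"].value_counts().to_dict()

    def pattern_genes(self, pattern: str) -> set[str]:
        t = self.table
        return set(t.loc[t["true_pattern"] == pattern, "gene"])


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library in the factorial design."""

    sample_id: str
    series: str  # Q, G or H
    stage: str  # X or XIII_XIV
    sex: str  # M or F
    replicate: int
    library_size_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.library_size_factor <= 0:
            raise ValueError("library_size_factor must be positive")


def default_design(
    n_replicates: int = 3,
    library_size_factors: Sequence[float] | None = None,
    seed: int | None = None,
    lsf_sd: float = 0.0,
) -> list[SampleDesign]:
    """Full factorial design: series x stage x sex x replicate.

    Library size factors default to 1; with ``lsf_sd`` > 0 they are drawn
    lognormally (seeded) to emulate unequal sequencing depth.
    """
    cells = [(se, st, sx) for se in SERIES for st in STAGES for sx in SEXES]
    n = len(cells) * n_replicates
    if library_size_factors is not None:
        lsf = list(library_size_factors)
        if len(lsf) != n:
            raise ValueError(f"need {n} library size factors, got {len(lsf)}")
    elif lsf_sd > 0:
        rng = np.random.default_rng(seed)
        lsf = list(np.exp(rng.normal(0.0, lsf_sd, size=n)))
    else:
        lsf = [1.0] * n
    out = []
    i = 0
    for se, st, sx in cells:
        for rep in range(1, n_replicates + 1):
            out.append(
                SampleDesign(f"{se}_{st}_{sx}_r{rep}", se, st, sx, rep, lsf[i])
            )
            i += 1
    ids = [d.sample_id for d in out]
    assert len(set(ids)) == len(ids)
    return out


def simulate_references(
    n_genes: int,
    gene_length: int | Sequence[int] = 1000,
    divergence_rate: float = 0.07,
    seed: int = 0,
    min_length: int = 350,
) -> ParentalReferencePair:
    """Simulate two substitution-diverged parental transcript sets.

    Genome A is uniform random DNA; genome B substitutes each site
    independently with probability ``divergence_rate``, drawing the
    replacement uniformly from the three alternative bases.  ``gene_length``
    may be a scalar or a per-gene sequence; all lengths must be at least
    ``min_length`` (the maximum fragment length used downstream).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= divergence_rate <= 0.75:
        raise ValueError(f"divergence_rate must be in [0, 0.75], got {divergence_rate}")
    if np.isscalar(gene_length):
        lengths = np.full(n_genes, int(gene_length))
    else:
        lengths = np.asarray(gene_length, dtype=int)
        if len(lengths) != n_genes:
            raise ValueError("gene_length sequence must have n_genes entries")
    for i, L in enumerate(lengths):
        if L < min_length:
            raise ValueError(
                f"gene g{i + 1:04d}: length {L} below minimum fragment length {min_length}"
            )
    rng = np.random.default_rng(seed)
    gene_ids, seqs_a, seqs_b = [], [], []
    for i, L in enumerate(lengths):
        a = rng.integers(0, 4, size=L)
        sub = rng.random(L) < divergence_rate
        # shift by 1..3 mod 4: uniform over the three alternative bases
        b = np.where(sub, (a + rng.integers(1, 4, size=L)) % 4, a)
        gene_ids.append(f"g{i + 1:04d}")
        seqs_a.append(_decode(BASES[a]))
        seqs_b.append(_decode(BASES[b]))
    return ParentalReferencePair(gene_ids, seqs_a, seqs_b, divergence_rate, seed)


def simulate_program(
    n_genes: int,
    direction_mix: dict[str, float] | None = None,
    misregulation_fraction: float = 0.5,
    effect_size_log2: float = 2.0,
    baseline_mean: float = 200.0,
    baseline_sd_log: float = 0.0,
    up_both_fraction: float = 0.1,
    parent_discordance: float = 0.35,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> ExpressionProgram:
    """Plant a per-gene expression program with known regulatory outcomes.

    An ``up_both_fraction`` of genes is upregulated between stages in both
    parental species — the eligible class.  Every other gene draws a shared
    parental direction from ``direction_mix`` (defaults: 10% up, 10% down,
    80% unaltered); a ``parent_discordance`` fraction of those redraws the
    chicken direction independently (never re-creating up-in-both), so the
    parental programs are only partially concordant, as between real
    species.  Hybrid alleles inherit their parent-of-origin's direction,
    except that among the up-in-both genes a ``misregulation_fraction`` is
    planted as pattern D: both hybrid allele log2FCs are set to zero (no
    upregulation of either allele).  The remaining up-in-both genes are
    pattern A.  Up/down effects are ``+/- effect_size_log2``.
    """
    if direction_mix is None:
        direction_mix = {"up": 0.1, "down": 0.1, "unaltered": 0.8}
    probs = np.array([direction_mix.get(d, 0.0) for d in DIRECTIONS])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"direction_mix proportions sum to {probs.sum()}, not 1")
    if not 0.0 <= misregulation_fraction <= 1.0:
        raise ValueError("misregulation_fraction must be in [0, 1]")
    if not 0.0 <= up_both_fraction <= 1.0:
        raise ValueError("up_both_fraction must be in [0, 1]")
    if effect_size_log2 < 1.0:
        raise ValueError("effect_size_log2 must be >= 1 (direction-call convention)")

    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids must have n_genes entries")

    up_both = rng.random(n_genes) < up_both_fraction
    dir_q = rng.choice(DIRECTIONS, size=n_genes, p=probs)
    dir_g = dir_q.copy()
    redraw = rng.random(n_genes) < parent_discordance
    dir_g[redraw] = rng.choice(DIRECTIONS, size=int(redraw.sum()), p=probs)
    # a redraw must not create an extra up-in-both gene
    accidental = (dir_q == "up") & (dir_g == "up") & ~up_both
    dir_g[accidental] = "unaltered"
    dir_q[up_both] = "up"
    dir_g[up_both] = "up"

    lfc_of = {"up": effect_size_log2, "down": -effect_size_log2, "unaltered": 0.0}
    lfc_q = np.array([lfc_of[d] for d in dir_q])
    lfc_g = np.array([lfc_of[d] for d in dir_g])

    # hybrid alleles inherit the parental program by default (pattern A side)
    dir_hq, dir_hg = dir_q.copy(), dir_g.copy()
    lfc_hq, lfc_hg = lfc_q.copy(), lfc_g.copy()

    misreg = up_both & (rng.random(n_genes) < misregulation_fraction)
    dir_hq[misreg] = "unaltered"
    dir_hg[misreg] = "unaltered"
    lfc_hq[misreg] = 0.0
    lfc_hg[misreg] = 0.0

    pattern = np.where(misreg, "D", np.where(up_both, "A", "none"))

    if baseline_sd_log > 0:
        baseline = baseline_mean * np.exp(
            rng.normal(-0.5 * baseline_sd_log**2, baseline_sd_log, size=n_genes)
        )
    else:
        baseline = np.full(n_genes, float(baseline_mean))

    table = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "baseline_mean": baseline,
            "lfc_Q": lfc_q,
            "lfc_G": lfc_g,
            "lfc_HQ": lfc_hq,
            "lfc_HG": lfc_hg,
            "dir_Q": dir_q,
            "dir_G": dir_g,
            "dir_HQ": dir_hq,
            "dir_HG": dir_hg,
            "true_pattern": pattern,
        }
    )
    return ExpressionProgram(table)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB draws with variance = mean + dispersion * mean^2."""
    r = 1.0 / np.maximum(dispersion, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    program: ExpressionProgram,
    design: Sequence[SampleDesign],
    dispersion: float | np.ndarray = 0.05,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Draw negative-binomial count matrices per series from the program.

    Returns a dict keyed by series tag Q, G, HQ, HG.  Parental samples
    produce one column per sample in their series matrix; each hybrid
    sample produces one column in BOTH allele matrices (HQ and HG) with
    per-allele mean equal to half the series mean, reflecting symmetric
    allele usage.  Expected count is
    ``library_size_factor * baseline * 2^(lfc if stage XIII/XIV else 0)``
    and variance = mean + dispersion * mean^2.
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    disp = np.asarray(dispersion, dtype=float)
    if np.any(disp <= 0):
        raise ValueError("dispersion must be > 0")
    if disp.ndim == 0:
        disp = np.full(len(program.genes), float(disp))
    rng = np.random.default_rng(seed)
    t = program.table
    baseline = t["baseline_mean"].to_numpy()
    genes = program.genes

    cols: dict[str, dict[str, np.ndarray]] = {s: {} for s in ("Q", "G", "HQ", "HG")}
    for d in sorted(design, key=lambda d: d.sample_id):
        alleles = [("HQ", 0.5), ("HG", 0.5)] if d.series == "H" else [(d.series, 1.0)]
        for tag, frac in alleles:
            lfc = t[f"lfc_{tag}"].to_numpy()
            mu = d.library_size_factor * frac * baseline * np.where(
                d.stage == "XIII_XIV", np.exp2(lfc), 1.0
            )
            cols[tag][d.sample_id] = _nb_draw(rng, mu, disp)

    out = {}
    for tag, data in cols.items():
        if data:
            out[tag] = pd.DataFrame(data, index=genes).astype(int)
    return out


def design_metadata(design: Sequence[SampleDesign]) -> pd.DataFrame:
    rows = [
        {
            "sample": d.sample_id,
            "series": d.series,
            "stage": d.stage,
            "sex": d.sex,
            "replicate": d.replicate,
            "library_size_factor": d.library_size_factor,
        }
        for d in design
    ]
    return pd.DataFrame(rows).set_index("sample")


def simulate_annotations(
    program: ExpressionProgram,
    n_terms: int = 20,
    genes_per_term: int = 30,
    planted_term: str = "T_misregulation",
    planted_enrichment: float = 0.8,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene→term annotations with one term planted on pattern-D genes.

    ``n_terms`` background terms draw member genes uniformly; the planted
    term draws a ``planted_enrichment`` fraction of its members from the
    true pattern-D genes (all of them if fewer), emulating a functionally
    coherent misregulated gene set.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(program.genes)
    out: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = min(genes_per_term, len(genes))
        out[f"T{i + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    d_genes = sorted(program.pattern_genes("D"))
    if d_genes:
        n_from_d = min(len(d_genes), int(round(planted_enrichment * genes_per_term)))
        members = set(rng.choice(d_genes, size=n_from_d, replace=False))
        pool = sorted(set(genes) - members)
        n_bg = min(genes_per_term - n_from_d, len(pool))
        members |= set(rng.choice(pool, size=n_bg, replace=False))
        out[planted_term] = members
    return out


@dataclass
class ReadTruth:
    """Per-read-pair ground truth emitted alongside simulated FASTQ."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: read_id, gene, species, position, fragment_length


def simulate_reads(
    refs: ParentalReferencePair,
    expression: dict[str, np.ndarray] | np.ndarray,
    n_read_pairs: int,
    read_length: int = 100,
    fragment_mean: float = 250.0,
    fragment_sd: float = 25.0,
    fragment_window: tuple[int, int] = (150, 350),
    error_rate: float = 0.001,
    seed: int = 0,
    sample_id: str = "s1",
) -> tuple[list[tuple[str, str, str]], ReadTruth]:
    """Simulate FR paired-end reads from one library.

    ``expression`` gives per-gene expression levels: either a single vector
    (parental sample: all fragments drawn from that one genome, keyed by
    which genome via ``{"A": vec}``) or a dict with keys ``"A"`` and/or
    ``"B"`` (hybrid sample: each allele's fragments drawn from its own
    genome).  Fragments per gene are multinomial with weights proportional
    to expression x length; start positions uniform; each base flipped to a
    random different base independently with probability ``error_rate``.

    Returns ``(records, truth)`` where records are
    ``(read_id, mate1_seq, mate2_seq)`` and the truth table records the
    source gene, genome and fragment start of every pair.
    """
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    if isinstance(expression, np.ndarray):
        expression = {"A": expression}
    lengths = refs.lengths()
    lo, hi = fragment_window
    if read_length > lo:
        raise ValueError("read_length must not exceed the minimum fragment length")
    short = lengths < hi
    if short.any():
        bad = refs.gene_ids[int(np.argmax(short))]
        raise ValueError(f"gene {bad} shorter than maximum fragment length {hi}")

    rng = np.random.default_rng(seed)
    seq_arrays = {
        "A": [np.frombuffer(s.encode(), dtype=np.uint8) for s in refs.seqs_a],
        "B": [np.frombuffer(s.encode(), dtype=np.uint8) for s in refs.seqs_b],
    }

    # allocate pairs over (species, gene) with weights expression x length
    keys, weights = [], []
    for sp in sorted(expression):
        expr = np.asarray(expression[sp], dtype=float)
        if len(expr) != refs.n_genes:
            raise ValueError("expression vector length must equal n_genes")
        w = expr * lengths
        for gi in np.nonzero(w > 0)[0]:
            keys.append((sp, int(gi)))
            weights.append(w[gi])
    if not keys:
        return [], ReadTruth(pd.DataFrame(
            columns=["read_id", "gene", "species", "position", "fragment_length"]))
    weights = np.asarray(weights)
    alloc = rng.multinomial(n_read_pairs, weights / weights.sum())

    records, truth_rows = [], []
    pair_no = 0
    for (sp, gi), cnt in zip(keys, alloc):
        if cnt == 0:
            continue
        ref = seq_arrays[sp][gi]
        L = len(ref)
        flens = np.clip(
            np.rint(rng.normal(fragment_mean, fragment_sd, size=cnt)).astype(int), lo, hi
        )
        flens = np.minimum(flens, L)
        starts = (rng.random(cnt) * (L - flens + 1)).astype(int)
        for fl, st in zip(flens, starts):
            frag = ref[st : st + fl]
            m1 = frag[:read_length].copy()
            m2 = frag[-read_length:].copy()
            for m in (m1, m2):
                if error_rate > 0:
                    errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                    if errs.size:
                        cur = m[errs]
                        # map base to one of its three alternatives
                        idx = np.searchsorted(BASES, cur)
                        m[errs] = BASES[(idx + rng.integers(1, 4, size=errs.size)) % 4]
            pair_no += 1
            rid = f"{sample_id}:{pair_no}"
            records.append((rid, _decode(m1), revcomp(_decode(m2))))
            truth_rows.append(
                {
                    "read_id": rid,
                    "gene": refs.gene_ids[gi],
                    "species": sp,
                    "position": int(st),
                    "fragment_length": int(fl),
                }
            )
    truth = ReadTruth(pd.DataFrame(truth_rows))
    return records, truth
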