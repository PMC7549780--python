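"""Seeded end-to-end orchestration of the hybrid ASE analysis.

``run_all`` executes simulate -> dual-genome map -> count -> low-count
filter -> stage-contrast DE (4 series x 2 sexes) -> concordance ->
pattern classification -> overrepresentation, writing TSV outputs and a
manifest (seed, parameters, per-stage row counts, output checksums).
Reruns with the same config are byte-identical.

``analyze_counts`` is the count-level core shared by the read-level
pipeline and by callers that already hold count matrices (e.g. full-scale
statistical studies where read simulation adds nothing).

A single global seed drives per-stage substreams derived from the stage
name, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, dualmap, enrich, io, patterns, quantify, simdata

SERIES_TO_GENOME = {"G": "A", "Q": "B"}  # genome A = chicken side, B = quail side
CONCORDANCE_PAIRS = (("Q", "G"), ("Q", "HQ"), ("G", "HG"))


@dataclass
class RunConfig:
    """All knobs of one run; defaults are the standard synthetic study."""

    mode: str = "synthetic"
    outdir: str = "hybridase_out"
    seed: int = 42
    # synthetic data
    n_genes: int = 60
    gene_length: int = 1000
    divergence_rate: float = 0.07
    direction_mix: dict = field(
        default_factory=lambda: {"up": 0.1, "down": 0.1, "unaltered": 0.8}
    )
    misregulation_fraction: float = 0.5
    effect_size_log2: float = 2.0
    baseline_mean: float = 200.0
    up_both_fraction: float = 0.1
    parent_discordance: float = 0.35
    n_replicates: int = 3
    dispersion: float = 0.05
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    fragment_min: int = 150
    fragment_max: int = 350
    error_rate: float = 0.001
    reads_per_sample: int | None = 2000  # None: match the NB count depth
    # mapper
    k: int = 31
    max_mismatches: int = 2
    # DE thresholds
    fdr_alpha: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    count_threshold: int = 1
    # real-mode paths
    ref_a: str | None = None
    ref_b: str | None = None
    design_table: str | None = None
    annotations: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ValueError("fold-change thresholds must be positive")

    @property
    def fragment_window(self) -> tuple[int, int]:
        return (self.fragment_min, self.fragment_max)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def analyze_counts(
    counts_by_tag: Mapping[str, pd.DataFrame],
    sample_meta: pd.DataFrame,
    count_threshold: int = 1,
) -> dict:
    """Filter, DE, concordance, and pattern analysis from count matrices.

    ``counts_by_tag`` maps series tag (Q, G, HQ, HG) to a genes x samples
    matrix; ``sample_meta`` is indexed by sample with stage and sex
    columns.  The low-count filter and the stage contrast run per
    (tag, sex); each sex's pattern universe is the intersection of its
    four retained-gene lists.
    """
    de: dict[tuple[str, str], pd.DataFrame] = {}
    retained: dict[tuple[str, str], list[str]] = {}
    for tag, matrix in counts_by_tag.items():
        meta = sample_meta.loc[matrix.columns]
        for sex in sorted(meta["sex"].unique()):
            cols = meta.index[meta["sex"] == sex]
            sub = quantify.filter_low_counts(matrix[cols], count_threshold)
            retained[(tag, sex)] = list(sub.index)
            de[(tag, sex)] = diffexpr.de_analysis(sub, meta.loc[cols, "stage"])

    sexes = sorted({sex for _, sex in de})
    universes, profiles, conc = {}, {}, {}
    for sex in sexes:
        uni = patterns.common_universe(
            *[retained[(tag, sex)] for tag in patterns.SERIES_ORDER]
        )
        universes[sex] = uni
        de_by_series = {tag: de[(tag, sex)] for tag in patterns.SERIES_ORDER}
        profiles[sex] = patterns.build_profiles(de_by_series, uni, sex)
        for x, y in CONCORDANCE_PAIRS:
            conc[(x, y, sex)] = patterns.concordance(
                de[(x, sex)], de[(y, sex)], uni, x, y
            )
    sets = patterns.misregulated_sets(profiles)
    return {
        "de": de,
        "retained": retained,
        "universes": universes,
        "profiles": profiles,
        "concordance": conc,
        "sets": sets,
    }


def _simulate_inputs(cfg: RunConfig):
    refs = simdata.simulate_references(
        cfg.n_genes,
        cfg.gene_length,
        cfg.divergence_rate,
        child_seed(cfg.seed, "references"),
        min_length=cfg.fragment_max,
    )
    program = simdata.simulate_program(
        cfg.n_genes,
        cfg.direction_mix,
        cfg.misregulation_fraction,
        cfg.effect_size_log2,
        cfg.baseline_mean,
        up_both_fraction=cfg.up_both_fraction,
        parent_discordance=cfg.parent_discordance,
        seed=child_seed(cfg.seed, "program"),
        gene_ids=refs.gene_ids,
    )
    design = simdata.default_design(cfg.n_replicates)
    counts = simdata.simulate_counts(
        program, design, cfg.dispersion, child_seed(cfg.seed, "counts")
    )
    return refs, program, design, counts


def _map_sample(cfg, refs, index, d, counts, lengths):
    """Simulate and classify one library; return per-tag count vectors."""
    if d.series == "H":
        expr = {
            "A": counts["HG"][d.sample_id].to_numpy() / lengths,
            "B": counts["HQ"][d.sample_id].to_numpy() / lengths,
        }
        depth = int(counts["HG"][d.sample_id].sum() + counts["HQ"][d.sample_id].sum())
        mode, conspecific = "hybrid", None
    else:
        genome = SERIES_TO_GENOME[d.series]
        expr = {genome: counts[d.series][d.sample_id].to_numpy() / lengths}
        depth = int(counts[d.series][d.sample_id].sum())
        mode, conspecific = "parental", genome
    n_pairs = cfg.reads_per_sample if cfg.reads_per_sample is not None else depth
    records, truth = simdata.simulate_reads(
        refs,
        expr,
        n_pairs,
        cfg.read_length,
        cfg.fragment_mean,
        cfg.fragment_sd,
        cfg.fragment_window,
        cfg.error_rate,
        seed=child_seed(cfg.seed, f"reads:{d.sample_id}"),
        sample_id=d.sample_id,
    )
    calls = dualmap.classify_reads(
        records, index, mode, conspecific, cfg.max_mismatches, cfg.fragment_window
    )
    vectors = quantify.count_pairs(calls, refs.gene_ids, mode)
    if mode == "parental":
        vectors = {d.series: vectors["counts"]}
    return vectors, calls, truth


def _load_real_inputs(cfg: RunConfig):
    for name in ("ref_a", "ref_b", "design_table"):
        path = getattr(cfg, name)
        if path is None or not os.path.exists(str(path)):
            raise FileNotFoundError(f"real mode requires {name}; missing path: {path}")
    refs = io.read_reference_pair(cfg.ref_a, cfg.ref_b)
    design_df = io.read_design_table(cfg.design_table)
    for col in ("fastq1", "fastq2"):
        if col not in design_df.columns:
            raise ValueError(f"real-mode design table needs a {col} column")
    return refs, design_df


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write outputs + manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    if config.mode == "synthetic":
        refs, program, design, true_counts = _simulate_inputs(config)
        design_meta = simdata.design_metadata(design)
        io.write_reference_pair(
            refs, str(outdir / "ref_A.fasta"), str(outdir / "ref_B.fasta")
        )
        io.write_tsv(program.table.set_index("gene"), str(outdir / "program_truth.tsv"))
        io.write_tsv(design_meta, str(outdir / "design.tsv"))
        samples = list(design)
    else:
        refs, design_df = _load_real_inputs(config)
        program, true_counts = None, None
        design_meta = design_df
        samples = [
            simdata.SampleDesign(str(s), r["series"], r["stage"], r["sex"],
                                 int(r["replicate"]))
            for s, r in design_df.iterrows()
        ]
    stage_counts["genes"] = refs.n_genes
    stage_counts["samples"] = len(samples)

    index = dualmap.DualIndex(refs, config.k)
    lengths = refs.lengths().astype(float)

    mapped: dict[str, dict[str, pd.Series]] = {t: {} for t in ("Q", "G", "HQ", "HG")}
    all_calls = []
    for d in sorted(samples, key=lambda d: d.sample_id):
        if config.mode == "synthetic":
            vectors, calls, _truth = _map_sample(
                config, refs, index, d, true_counts, lengths
            )
        else:
            row = design_meta.loc[d.sample_id]
            records = io.read_fastq_pairs(row["fastq1"], row["fastq2"])
            mode = "hybrid" if d.series == "H" else "parental"
            conspecific = SERIES_TO_GENOME.get(d.series)
            calls = dualmap.classify_reads(
                records, index, mode, conspecific,
                config.max_mismatches, config.fragment_window,
            )
            vectors = quantify.count_pairs(calls, refs.gene_ids, mode)
            if mode == "parental":
                vectors = {d.series: vectors["counts"]}
        for tag, vec in vectors.items():
            mapped[tag][d.sample_id] = vec
        df = dualmap.calls_to_frame(calls)
        df.insert(0, "sample", d.sample_id)
        all_calls.append(df)

    calls_df = pd.concat(all_calls, ignore_index=True)
    io.write_tsv(calls_df, str(outdir / "origin_calls.tsv"), index=False)
    stage_counts["read_pairs"] = len(calls_df)
    stage_counts["accepted_pairs"] = int(
        calls_df["call"].isin(["A_specific", "B_specific"]).sum()
    )

    counts_by_tag = {
        tag: pd.DataFrame(cols) for tag, cols in mapped.items() if cols
    }
    for tag, matrix in counts_by_tag.items():
        io.write_tsv(matrix, str(outdir / f"counts_{tag}.tsv"))

    result = analyze_counts(counts_by_tag, design_meta, config.count_threshold)
    for (tag, sex), de in result["de"].items():
        io.write_tsv(de, str(outdir / f"de_{tag}_{sex}.tsv"))
    conc_rows = []
    for (x, y, sex), c in result["concordance"].items():
        for dx in patterns.DIRECTIONS:
            for dy in patterns.DIRECTIONS:
                conc_rows.append(
                    {
                        "series_x": x, "series_y": y, "sex": sex,
                        "dir_x": dx, "dir_y": dy,
                        "n_genes": int(c.table.loc[dx, dy]),
                    }
                )
        conc_rows.append(
            {
                "series_x": x, "series_y": y, "sex": sex,
                "dir_x": "summary", "dir_y": f"r={c.pearson_r:.6f}",
                "n_genes": int(c.universe_size),
            }
        )
    io.write_tsv(pd.DataFrame(conc_rows), str(outdir / "concordance.tsv"), index=False)
    profiles = pd.concat(result["profiles"].values(), ignore_index=True)
    io.write_tsv(profiles, str(outdir / "pattern_profiles.tsv"), index=False)
    sets = result["sets"]
    set_rows = [
        {"set": name, "gene": g}
        for name in ("eligible_union", "patternD_union", "patternD_intersection")
        for g in sorted(sets[name])
    ]
    io.write_tsv(pd.DataFrame(set_rows, columns=["set", "gene"]),
                 str(outdir / "gene_sets.tsv"), index=False)
    stage_counts["eligible_union"] = len(sets["eligible_union"])
    stage_counts["patternD_union"] = len(sets["patternD_union"])

    # overrepresentation of the misregulated set against the analyzed universe
    population = sorted(set().union(*result["universes"].values()))
    study = sorted(set(sets["patternD_union"]) & set(population))
    if config.annotations:
        annotations = io.read_annotations(config.annotations)
    elif program is not None:
        annotations = simdata.simulate_annotations(
            program, seed=child_seed(config.seed, "annotations")
        )
    else:
        annotations = {}
    enrichment = []
    if annotations and study:
        enrichment = enrich.fisher_overrep(study, population, annotations)
        enr_df = pd.DataFrame([asdict(r) for r in enrichment])
        io.write_tsv(enr_df, str(outdir / "enrichment.tsv"), index=False)
    stage_counts["enriched_terms"] = sum(r.fdr < config.fdr_alpha for r in enrichment)

    manifest = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "stage_counts": stage_counts,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.suffix in (".tsv", ".fasta")
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    result.update(
        {
            "refs": refs,
            "program": program,
            "counts_by_tag": counts_by_tag,
            "calls": calls_df,
            "enrichment": enrichment,
            "manifest": manifest,
        }
    )
    return result
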