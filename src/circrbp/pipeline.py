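"""End-to-end stage orchestration over plain TSV/FASTA/BED artifacts.

Each stage reads the files an upstream stage (or an external tool) left in
the run directory and writes plain TSVs, so any stage can be re-run or fed
externally produced inputs.  ``run_all`` executes the dependency order
DE -> CLR -> regions -> motifs -> correlations -> subtypes ->
stratification -> survival and records a manifest (config snapshot, input
checksums, stage status, output paths, seed) as JSON.  Stage outputs are
written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import clr, correlate, correlation_direction_concordance, cpm, de_test, filter_rbps
from .io import (
    PipelineConfig,
    read_circ_bed,
    read_count_matrix,
    read_fasta,
    read_gene_list,
    read_pwm_library,
    read_results_table,
    write_results_table,
)
from .motifs import dual_role_intersection, motif_frequency_profile, region_motif_enrichment
from .regions import REGION_KINDS, RegionSet, extract_all_regions, write_regions_fasta
from .stratify import assign_subtypes, stratify
from .survival import survival_screen
from .synthetic import SynthParams, generate_dataset


class MissingInputError(FileNotFoundError):
    """An input file a stage depends on is absent."""


class StageError(RuntimeError):
    """A stage failed while computing."""


INPUT_FILES = {
    "genome": "genome.fa",
    "circs": "circs.bed",
    "circ_counts": "circ_counts.tsv",
    "gene_counts": "gene_counts.tsv",
    "samples": "samples.tsv",
    "rbp_list": "rbp_list.txt",
    "signatures": "signatures.tsv",
    "pwm_dir": "pwms",
}

STAGE_DEPS = {
    "de": ["circ_counts", "gene_counts", "samples", "rbp_list"],
    "clr": ["circ_counts", "gene_counts"],
    "regions": ["genome", "circs"],
    "motifs": ["regions.fa", "de_circ.tsv", "pwm_dir"],
    "correlate": ["de_circ.tsv", "de_rbp.tsv", "circ_counts", "gene_counts"],
    "subtypes": ["gene_counts", "signatures"],
    "stratify": ["gene_counts", "rbp_list", "subtypes.tsv"],
    "survive": ["gene_counts", "rbp_list", "samples", "de_rbp.tsv"],
}

STAGE_ORDER = ["de", "clr", "regions", "motifs", "correlate", "subtypes", "stratify", "survive"]


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename into place."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve(rundir: Path, name: str) -> Path:
    """Resolve a dependency name (logical input or stage output file)."""
    path = rundir / INPUT_FILES.get(name, name)
    if not path.exists():
        raise MissingInputError(f"required input {path} is missing")
    return path


def _read_regions_fasta(path: Path) -> dict[str, dict[str, RegionSet]]:
    regions: dict[str, dict[str, RegionSet]] = {kind: {} for kind in REGION_KINDS}
    circ_id = kind = None
    seq_parts: list[str] = []

    def flush():
        if circ_id is not None:
            regions[kind][circ_id] = RegionSet(circ_id, kind, "".join(seq_parts))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                fields = line[1:].split("|")
                circ_id, kind = fields[0], fields[1]
                seq_parts = []
            else:
                seq_parts.append(line)
    flush()
    return regions


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _tumor_control_groups(meta: pd.DataFrame) -> pd.Series:
    groups = meta.set_index("sample_id")["group"]
    # primary-tumor vs healthy-brain comparison; recurrent samples excluded
    return groups[groups.isin(["GBM_PRM", "HB"])]


def stage_de(rundir: Path, config: PipelineConfig) -> list[Path]:
    circ = read_count_matrix(_resolve(rundir, "circ_counts"), "circRNA")
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    meta = read_results_table(_resolve(rundir, "samples"))
    rbps = read_gene_list(_resolve(rundir, "rbp_list"))
    groups = _tumor_control_groups(meta)
    keep = [s for s in circ.sample_ids if s in groups.index]
    # group1 = control (HB sorts after GBM_PRM alphabetically; relabel so
    # log2fc is tumor vs control)
    glab = groups.loc[keep].map({"HB": "1_control", "GBM_PRM": "2_tumor"})
    de_circ = de_test(circ.counts[keep], glab, config)
    de_gene = de_test(gene.counts[keep], glab, config)
    de_rbp = filter_rbps(de_gene, rbps)
    outs = []
    for name, df in (("de_circ.tsv", de_circ), ("de_gene.tsv", de_gene), ("de_rbp.tsv", de_rbp)):
        path = rundir / name
        _atomic_write(path, lambda p, df=df: write_results_table(df, p))
        outs.append(path)
    return outs


def stage_clr(rundir: Path, config: PipelineConfig) -> list[Path]:
    circ = read_count_matrix(_resolve(rundir, "circ_counts"), "circRNA")
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    pooled_circ = circ.counts.sum(axis=1)
    pooled_lin = gene.counts.sum(axis=1)
    pair_map = {c: f"LIN_{c}" for c in circ.feature_ids if f"LIN_{c}" in gene.counts.index}
    if not pair_map:
        raise StageError("clr: no LIN_<circ_id> host-gene counterparts in the gene matrix")
    table = clr(pooled_circ, pooled_lin, pair_map)
    path = rundir / "clr.tsv"
    _atomic_write(path, lambda p: write_results_table(table, p))
    return [path]


def stage_regions(rundir: Path, config: PipelineConfig) -> list[Path]:
    genome = read_fasta(_resolve(rundir, "genome"))
    circs = read_circ_bed(_resolve(rundir, "circs"))
    regions = extract_all_regions(circs, genome, config.flank_len, config.boundary_len)
    path = rundir / "regions.fa"
    _atomic_write(path, lambda p: write_regions_fasta(regions, p))
    return [path]


def stage_motifs(rundir: Path, config: PipelineConfig) -> list[Path]:
    regions = _read_regions_fasta(_resolve(rundir, "regions.fa"))
    de_circ = read_results_table(_resolve(rundir, "de_circ.tsv"))
    pwms = read_pwm_library(_resolve(rundir, "pwm_dir"))
    de_status = dict(zip(de_circ["feature_id"], de_circ["status"]))
    results = region_motif_enrichment(
        regions, de_status, pwms, k=config.k, motif_fdr=config.motif_fdr
    )
    outs = []
    for (cls_name, direction), res in results.items():
        for stem, df in (("kmer_enrichment", res["kmer_table"]), ("motif_enrichment", res["motif_results"])):
            path = rundir / f"{stem}_{cls_name}_{direction}.tsv"
            if stem == "kmer_enrichment":
                df = df[df["count_fg"] + df["count_bg"] > 0]
            _atomic_write(path, lambda p, df=df: write_results_table(df, p))
            outs.append(path)
    body_down = results.get(("body", "down"))
    flank_down = results.get(("flank", "down"))
    if body_down is not None and flank_down is not None:
        venn = dual_role_intersection(body_down["motif_results"], flank_down["motif_results"])
        path = rundir / "dual_role.json"
        _atomic_write(path, lambda p: p.write_text(json.dumps(venn, indent=2)))
        outs.append(path)
    profiles = motif_frequency_profile(pwms, regions)
    path = rundir / "motif_profiles.tsv"
    _atomic_write(path, lambda p: write_results_table(profiles, p))
    outs.append(path)
    return outs


def stage_correlate(rundir: Path, config: PipelineConfig, max_rbps: int = 30, max_circs: int = 200) -> list[Path]:
    de_circ = read_results_table(_resolve(rundir, "de_circ.tsv"))
    de_rbp = read_results_table(_resolve(rundir, "de_rbp.tsv"))
    circ = read_count_matrix(_resolve(rundir, "circ_counts"), "circRNA")
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    de_circ_ids = de_circ.loc[de_circ["status"] != "null", "feature_id"].tolist()[:max_circs]
    rbp_ids = de_rbp.sort_values("fdr")["feature_id"].tolist()[:max_rbps]
    if not de_circ_ids or not rbp_ids:
        raise StageError("correlate: no DE circRNAs or no DE RBPs to correlate")
    circ_log = cpm(circ, log=True).loc[de_circ_ids]
    gene_log = cpm(gene, log=True)
    rbp_log = gene_log.loc[[r for r in rbp_ids if r in gene_log.index]]
    corr_circ = correlate(rbp_log, circ_log)
    lin_ids = [f"LIN_{c}" for c in de_circ_ids if f"LIN_{c}" in gene_log.index]
    outs = []
    path = rundir / "correlations.tsv"
    _atomic_write(path, lambda p: write_results_table(corr_circ, p))
    outs.append(path)
    if lin_ids:
        lin_log = gene_log.loc[lin_ids].rename(index=lambda s: s.removeprefix("LIN_"))
        corr_mrna = correlate(rbp_log, lin_log)
        conc = correlation_direction_concordance(corr_circ, corr_mrna, alpha=config.corr_alpha)
        path = rundir / "correlation_concordance.tsv"
        _atomic_write(path, lambda p: write_results_table(conc, p))
        outs.append(path)
    return outs


def stage_subtypes(rundir: Path, config: PipelineConfig) -> list[Path]:
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    sig = read_results_table(_resolve(rundir, "signatures"))
    meta = read_results_table(_resolve(rundir, "samples"))
    tumor = meta.loc[meta["group"].str.startswith("GBM"), "sample_id"].tolist()
    signature_sets = {s: g["gene"].tolist() for s, g in sig.groupby("subtype")}
    log_expr = cpm(gene.counts[tumor], log=True)
    assign = assign_subtypes(log_expr, signature_sets)
    path = rundir / "subtypes.tsv"
    _atomic_write(path, lambda p: write_results_table(assign, p))
    return [path]


def stage_stratify(rundir: Path, config: PipelineConfig) -> list[Path]:
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    rbps = read_gene_list(_resolve(rundir, "rbp_list"))
    subtypes = read_results_table(_resolve(rundir, "subtypes.tsv"))
    tumor = subtypes["sample_id"].tolist()
    rbp_expr = cpm(gene.counts[tumor], log=True).loc[[r for r in rbps if r in gene.counts.index]]
    result = stratify(
        rbp_expr,
        subtypes.set_index("sample_id")["subtype"],
        k_range=config.k_range,
        seed=config.seed,
        chi2_alpha=config.chi2_alpha,
        anova_alpha=config.anova_alpha,
    )
    clusters = pd.DataFrame({"sample_id": result.sample_ids, "cluster": result.labels})
    clusters["chosen_k"] = result.chosen_k
    outs = []
    path = rundir / "stratification_clusters.tsv"
    _atomic_write(path, lambda p: write_results_table(clusters, p))
    outs.append(path)
    path = rundir / "discriminant_rbps.tsv"
    _atomic_write(path, lambda p: write_results_table(result.discriminant, p))
    outs.append(path)
    return outs


def stage_survive(rundir: Path, config: PipelineConfig) -> list[Path]:
    gene = read_count_matrix(_resolve(rundir, "gene_counts"), "gene")
    meta = read_results_table(_resolve(rundir, "samples"))
    de_rbp = read_results_table(_resolve(rundir, "de_rbp.tsv"))
    rbps = read_gene_list(_resolve(rundir, "rbp_list"))
    screened = de_rbp.loc[de_rbp["status"] != "null", "feature_id"].tolist() or rbps
    surv = meta.dropna(subset=["survival_time", "event"])
    expr = cpm(gene, log=True)
    screen = survival_screen(screened, expr, surv, alpha=0.05)
    path = rundir / "survival_screen.tsv"
    _atomic_write(path, lambda p: write_results_table(screen, p))
    return [path]


STAGE_FUNCS = {
    "de": stage_de,
    "clr": stage_clr,
    "regions": stage_regions,
    "motifs": stage_motifs,
    "correlate": stage_correlate,
    "subtypes": stage_subtypes,
    "stratify": stage_stratify,
    "survive": stage_survive,
}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_stage(stage_name: str, rundir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Run one stage after validating its upstream inputs exist."""
    if stage_name not in STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; valid stages: {', '.join(STAGE_ORDER)}")
    rundir = Path(rundir)
    config = config or PipelineConfig()
    for dep in STAGE_DEPS[stage_name]:
        _resolve(rundir, dep)
    t0 = time.time()
    try:
        outputs = STAGE_FUNCS[stage_name](rundir, config)
    except (MissingInputError, ValueError) as exc:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise StageError(f"stage {stage_name!r} failed: {exc}") from exc
    return {
        "stage": stage_name,
        "status": "ok",
        "outputs": [str(p) for p in outputs],
        "seconds": round(time.time() - t0, 3),
    }


def run_all(config: PipelineConfig, rundir: str | Path, stages: list[str] | None = None) -> dict:
    """Run all stages in dependency order; returns (and writes) the manifest."""
    rundir = Path(rundir)
    stages = stages or STAGE_ORDER
    input_checksums = {}
    for name, fname in INPUT_FILES.items():
        path = rundir / fname
        if path.is_file():
            input_checksums[name] = _sha256(path)
    manifest = {
        "tool": "circrbp",
        "version": __version__,
        "seed": config.seed,
        "config": {**dataclasses.asdict(config), "k_range": list(config.k_range)},
        "input_checksums": input_checksums,
        "stages": [],
    }
    for stage in stages:
        entry = run_stage(stage, rundir, config)
        entry["output_checksums"] = {Path(p).name: _sha256(Path(p)) for p in entry["outputs"]}
        manifest["stages"].append(entry)
    _atomic_write(rundir / "manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
    return manifest


def demo_params(seed: int = 42) -> SynthParams:
    """Small synthetic demo sized so generate + run_all completes in minutes."""
    return SynthParams(
        chrom_len=800_000,
        n_circ=120,
        circ_len_min=200,
        circ_len_max=1200,
        n_samples=12,
        n_rbp=40,
        n_driver_rbps=10,
        seed=seed,
    )


def run_demo(outdir: str | Path, seed: int = 42) -> dict:
    """One-command synthetic smoke run: generate a dataset, then run_all."""
    params = demo_params(seed)
    generate_dataset(params, outdir)
    config = PipelineConfig(seed=seed, flank_len=params.flank_len, boundary_len=params.boundary_len)
    return run_all(config, outdir)
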