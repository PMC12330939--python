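"""Synthetic dataset generator with recorded ground truth.

Every downstream stage gets a recovery test from data built here: a
uniform-background genome carrying non-overlapping exonic circRNAs on both
strands; hexamer motifs over-written into chosen region classes at a
foreground rate in motif-direction-matched DE circRNAs and a background
rate elsewhere (U-rich hexamers mark downregulated circRNAs, G/C-rich
hexamers upregulated ones, mirroring the asymmetry the analysis is meant
to recover); negative-binomial counts with designed fold changes, 3-fold
library-size variation and host-gene linear counterparts; subtype- and
cluster-structured RBP/gene signatures; and exponential survival times
whose hazard tracks a designated driver RBP's expression quartiles.

All randomness flows from ``SynthParams.seed`` through per-stage
``SeedSequence`` children, so a full dataset is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BASES,
    CircRecord,
    CountMatrix,
    GenomeStore,
    PWMRecord,
    SampleMeta,
    reverse_complement,
    write_circ_bed,
    write_count_matrix,
    write_fasta,
    write_pwm_library,
    write_results_table,
    write_sample_meta,
)
from .survival import quartile_groups

_STAGE_OFFSETS = {"genome": 0, "circs": 1, "motifs": 2, "counts": 3, "survival": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGE_OFFSETS))
    return np.random.default_rng(children[_STAGE_OFFSETS[stage]])


@dataclass
class SynthParams:
    """Study-condition knobs for the synthetic dataset.

    Defaults describe a desk-scale cohort: 1000 circRNAs of 200-2000 bp on
    a 6 Mb chromosome, a fifth downregulated and a twentieth upregulated
    (echoing the strong down-skew of circRNA deregulation in tumors),
    U-rich/G+C-rich planted hexamers at 6 vs 0.5 copies per kb, NB counts
    with dispersion 0.1 and base mean 100, 20 samples per group, four
    molecular subtypes, three planted expression clusters driven by 15
    RBPs, and a survival hazard ratio of 3 for driver-high samples.
    """

    n_chrom: int = 1
    chrom_len: int = 6_000_000
    n_circ: int = 1000
    circ_len_min: int = 200
    circ_len_max: int = 2000
    frac_up: float = 0.05
    frac_down: float = 0.20
    planted_down_motif: str = "TTTTTT"
    planted_up_motif: str = "GGCGGC"
    insert_rate_fg: float = 6.0  # expected copies per kb in matched DE regions
    insert_rate_bg: float = 0.5  # expected copies per kb elsewhere
    plant_regions: tuple[str, ...] = ("body",)
    nb_dispersion: float = 0.1
    base_mean: float = 100.0
    fc_up: float = 4.0
    fc_down: float = 0.25
    n_samples: int = 20  # per group (tumor, control)
    host_circ_corr: float = 0.0  # 0 = independent host-gene counts
    n_rbp: int = 60
    n_driver_rbps: int = 15
    n_clusters: int = 3
    cluster_shift: float = 2.0  # log2 mean shift applied by driver RBPs
    n_subtypes: int = 4
    n_signature_genes: int = 10  # per subtype
    subtype_shift: float = 2.0  # log2 shift of own-signature genes
    hazard_ratio: float = 3.0
    median_survival_days: float = 445.0  # baseline group median
    horizon_days: float = 1825.0  # administrative censoring
    flank_len: int = 1000
    boundary_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1 and self.frac_up + self.frac_down <= 1):
            raise ValueError("fractions must be in [0,1] with frac_up + frac_down <= 1")
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ValueError("fold changes must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    de_status: dict[str, str] = field(default_factory=dict)  # circ_id -> up/down/null
    motif_insertions: list[dict] = field(default_factory=list)
    size_factors: dict[str, float] = field(default_factory=dict)
    cluster_label: dict[str, int] = field(default_factory=dict)  # tumor samples
    subtype_label: dict[str, str] = field(default_factory=dict)
    hazard_group: dict[str, str] = field(default_factory=dict)  # low/medium/high
    driver_rbps: list[str] = field(default_factory=list)
    survival_driver: str = ""


SUBTYPES = ("classical", "mesenchymal", "neural", "proneural")


# ---------------------------------------------------------------------------
# genome and annotations
# ---------------------------------------------------------------------------

def generate_genome(params: SynthParams, rng: np.random.Generator | None = None) -> GenomeStore:
    """I.i.d. uniform A/C/G/T background, one string per chromosome."""
    if params.chrom_len < 2 * (params.flank_len + params.boundary_len):
        raise ValueError(
            f"chrom_len {params.chrom_len} too small for flank_len {params.flank_len} "
            f"and boundary_len {params.boundary_len}"
        )
    rng = rng or _stage_rng(params.seed, "genome")
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    sequences = {}
    for i in range(params.n_chrom):
        draw = rng.integers(0, 4, size=params.chrom_len)
        sequences[f"chr{i + 1}"] = bytes(lut[draw]).decode("ascii")
    return GenomeStore(sequences)


def generate_circ_annotations(
    genome: GenomeStore, params: SynthParams, rng: np.random.Generator | None = None
) -> list[CircRecord]:
    """Non-overlapping single-exon circRNAs with >= flank_len spacing.

    Lengths are uniform in [circ_len_min, circ_len_max]; strands ~50/50;
    leftover chromosome space is spread randomly over the inter-circRNA
    gaps so placements differ between seeds but spacing is guaranteed.
    """
    rng = rng or _stage_rng(params.seed, "circs")
    chroms = list(genome.sequences)
    per_chrom = np.array_split(np.arange(params.n_circ), len(chroms))
    records: list[CircRecord] = []
    for chrom, idx in zip(chroms, per_chrom):
        n = len(idx)
        if n == 0:
            continue
        clen = genome.lengths[chrom]
        lengths = rng.integers(params.circ_len_min, params.circ_len_max + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * params.flank_len
        leftover = clen - needed
        if leftover < 0:
            achievable = int((clen - params.flank_len) // (params.circ_len_max + params.flank_len))
            raise ValueError(
                f"cannot place {n} circRNAs on {chrom} (len {clen}); about {achievable} achievable"
            )
        extra = rng.multinomial(leftover, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for j, i in enumerate(idx):
            pos += params.flank_len + int(extra[j])
            start = pos
            end = start + int(lengths[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(CircRecord(f"circ{i:05d}", chrom, start, end, strand))
    return records


def assign_de_status(circs: list[CircRecord], params: SynthParams,
                     rng: np.random.Generator | None = None) -> dict[str, str]:
    """Deterministically sized up/down/null assignment, order shuffled by seed."""
    rng = rng or _stage_rng(params.seed, "circs")
    n = len(circs)
    n_up = int(round(params.frac_up * n))
    n_down = int(round(params.frac_down * n))
    status = np.array(["up"] * n_up + ["down"] * n_down + ["null"] * (n - n_up - n_down))
    rng.shuffle(status)
    return {c.circ_id: s for c, s in zip(circs, status)}


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def _region_interval(circ: CircRecord, kind: str, flank_len: int, boundary_len: int) -> tuple[int, int]:
    """Genomic interval of a region class (transcript-orientation aware)."""
    plus = circ.strand == "+"
    if kind == "body":
        return circ.start, circ.end
    if kind == "flank5":
        return (circ.start - flank_len, circ.start) if plus else (circ.end, circ.end + flank_len)
    if kind == "flank3":
        return (circ.end, circ.end + flank_len) if plus else (circ.start - flank_len, circ.start)
    if kind == "boundary5":
        return (circ.start - boundary_len, circ.start + boundary_len) if plus else (
            circ.end - boundary_len, circ.end + boundary_len)
    if kind == "boundary3":
        return (circ.end - boundary_len, circ.end + boundary_len) if plus else (
            circ.start - boundary_len, circ.start + boundary_len)
    raise ValueError(f"unknown region kind {kind!r}")


def plant_motifs(
    genome: GenomeStore,
    circs: list[CircRecord],
    truth: SyntheticTruth,
    params: SynthParams,
    rng: np.random.Generator | None = None,
) -> GenomeStore:
    """Overwrite planted hexamers into region classes, recording every site.

    For each motif (down-motif targets down-DE circRNAs, up-motif up-DE),
    each circRNA region in ``params.plant_regions`` receives
    Poisson(rate * len / 1000) non-overlapping copies, with the foreground
    rate when the circRNA's DE status matches the motif's direction and
    the background rate otherwise.  Minus-strand regions receive the
    reverse complement so the transcript-oriented sequence carries the
    motif.  Copies are written by overwrite so no coordinate shifts.
    """
    rng = rng or _stage_rng(params.seed, "motifs")
    for motif in (params.planted_down_motif, params.planted_up_motif):
        if params.insert_rate_fg * len(motif) / 1000.0 > 0.05:
            raise ValueError(
                f"insert_rate_fg={params.insert_rate_fg}/kb with motif length {len(motif)} "
                "implies > 5% expected sequence overwrite; lower the rate"
            )
    seqs = {name: bytearray(seq.encode("ascii")) for name, seq in genome.sequences.items()}
    motif_for = {"down": params.planted_down_motif, "up": params.planted_up_motif}
    # placements must never overwrite each other — across motifs, region
    # kinds and neighbouring circRNAs (flank windows may coincide)
    blocked: dict[str, set[int]] = {name: set() for name in seqs}
    for circ in circs:
        status = truth.de_status[circ.circ_id]
        occupied = blocked[circ.chrom]
        for direction, motif in motif_for.items():
            for kind in params.plant_regions:
                lo, hi = _region_interval(circ, kind, params.flank_len, params.boundary_len)
                lo = max(lo, 0)
                hi = min(hi, genome.lengths[circ.chrom])
                region_len = hi - lo
                if region_len < len(motif):
                    continue
                rate = params.insert_rate_fg if status == direction else params.insert_rate_bg
                n_copies = rng.poisson(rate * region_len / 1000.0)
                if n_copies == 0:
                    continue
                placed: list[int] = []
                attempts = 0
                span = len(motif)
                while len(placed) < n_copies and attempts < 50 * n_copies + 100:
                    attempts += 1
                    pos = int(rng.integers(lo, hi - span + 1))
                    cover = range(pos, pos + span)
                    if not any(b in occupied for b in cover):
                        placed.append(pos)
                        occupied.update(cover)
                written = motif if circ.strand == "+" else reverse_complement(motif)
                for pos in sorted(placed):
                    seqs[circ.chrom][pos : pos + len(motif)] = written.encode("ascii")
                    truth.motif_insertions.append(
                        {
                            "chrom": circ.chrom,
                            "pos": pos,
                            "motif": motif,
                            "genomic_seq": written,
                            "region_kind": kind,
                            "circ_id": circ.circ_id,
                            "direction": direction,
                            "foreground": status == direction,
                        }
                    )
    return GenomeStore({name: ba.decode("ascii") for name, ba in seqs.items()})


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / max(dispersion, 1e-8)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: SyntheticTruth,
    params: SynthParams,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, CountMatrix, list[SampleMeta]]:
    """NB count matrices (circRNA + gene) and sample metadata.

    Tumor samples carry the designed fold changes on up/down circRNAs,
    subtype shifts on signature genes and cluster shifts on driver RBPs;
    the gene matrix includes one linear host counterpart per circRNA (so
    CLR is computable) plus RBP and signature genes.  Library sizes vary
    3-fold via per-sample size factors recorded in the truth.
    """
    rng = rng or _stage_rng(params.seed, "counts")
    n = params.n_samples
    tumor_ids = [f"GBM_{i + 1:02d}" for i in range(n)]
    control_ids = [f"HB_{i + 1:02d}" for i in range(n)]
    samples = tumor_ids + control_ids

    # 3-fold library-size variation, log-uniform
    sf = np.exp(rng.uniform(-0.5 * np.log(3), 0.5 * np.log(3), size=2 * n))
    truth.size_factors = dict(zip(samples, sf.tolist()))

    # tumor structure: subtypes and planted clusters, balanced then shuffled
    subs = np.array([SUBTYPES[i % params.n_subtypes] for i in range(n)])
    rng.shuffle(subs)
    clus = np.array([i % params.n_clusters for i in range(n)])
    rng.shuffle(clus)
    truth.subtype_label = dict(zip(tumor_ids, subs.tolist()))
    truth.cluster_label = dict(zip(tumor_ids, clus.tolist()))

    is_tumor = np.array([1] * n + [0] * n, dtype=bool)

    # --- circRNA counts -----------------------------------------------------
    circ_ids = list(truth.de_status)
    fc_map = {"up": params.fc_up, "down": params.fc_down, "null": 1.0}
    circ_fc = np.array([fc_map[truth.de_status[c]] for c in circ_ids])
    mean = params.base_mean * np.where(is_tumor[None, :], circ_fc[:, None], 1.0) * sf[None, :]
    circ_counts = _nb_draw(rng, mean, params.nb_dispersion)
    circ_cm = CountMatrix(pd.DataFrame(circ_counts, index=circ_ids, columns=samples), feature_kind="circRNA")

    # --- gene counts: host genes + RBPs + subtype signatures ----------------
    gene_rows = []
    gene_means = []
    host_base = np.exp(rng.normal(np.log(params.base_mean), 0.5, size=len(circ_ids)))
    for i, c in enumerate(circ_ids):
        gene_rows.append(f"LIN_{c}")
        log2fc = params.host_circ_corr * np.log2(circ_fc[i])
        gene_means.append(host_base[i] * np.where(is_tumor, 2.0**log2fc, 1.0))

    rbp_names = [f"RBP{i + 1:03d}" for i in range(params.n_rbp)]
    truth.driver_rbps = rbp_names[: params.n_driver_rbps]
    # the survival driver is kept clear of the cluster drivers so its
    # expression quartiles are not confounded with cluster structure
    truth.survival_driver = (
        rbp_names[params.n_driver_rbps] if params.n_driver_rbps < params.n_rbp else rbp_names[-1]
    )
    rbp_base = np.exp(rng.normal(np.log(params.base_mean), 0.5, size=params.n_rbp))
    # each driver must actually separate clusters: redraw constant patterns
    driver_pattern = rng.choice([-1.0, 1.0], size=(params.n_driver_rbps, params.n_clusters))
    if params.n_clusters > 1:
        for r in range(params.n_driver_rbps):
            while np.all(driver_pattern[r] == driver_pattern[r, 0]):
                driver_pattern[r] = rng.choice([-1.0, 1.0], size=params.n_clusters)
    for r, name in enumerate(rbp_names):
        mu = np.full(2 * n, rbp_base[r])
        if r < params.n_driver_rbps:
            shift = driver_pattern[r, clus]  # per tumor sample
            mu = mu.copy()
            mu[:n] *= 2.0 ** (params.cluster_shift * shift)
        gene_rows.append(name)
        gene_means.append(mu)

    sig_base = np.exp(rng.normal(np.log(params.base_mean), 0.5,
                                 size=params.n_subtypes * params.n_signature_genes))
    gi = 0
    for s_idx in range(params.n_subtypes):
        subtype = SUBTYPES[s_idx % len(SUBTYPES)]
        own = subs == subtype
        for j in range(params.n_signature_genes):
            mu = np.full(2 * n, sig_base[gi])
            mu[:n][own] *= 2.0**params.subtype_shift
            gene_rows.append(f"SIG_{subtype}_{j + 1:02d}")
            gene_means.append(mu)
            gi += 1

    gene_mean = np.vstack(gene_means) * sf[None, :]
    gene_counts = _nb_draw(rng, gene_mean, params.nb_dispersion)
    gene_cm = CountMatrix(pd.DataFrame(gene_counts, index=gene_rows, columns=samples), feature_kind="gene")

    # hazard groups from the designated survival driver's tumor expression
    driver_expr = gene_cm.counts.loc[truth.survival_driver, tumor_ids].astype(float) / sf[:n]
    grouping = quartile_groups(driver_expr)
    truth.hazard_group = dict(zip(grouping["sample_id"], grouping["group"]))

    metas = [
        SampleMeta(s, "GBM_PRM", subtype=truth.subtype_label[s]) for s in tumor_ids
    ] + [SampleMeta(s, "HB") for s in control_ids]
    return circ_cm, gene_cm, metas


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    truth: SyntheticTruth,
    params: SynthParams,
    metas: list[SampleMeta],
    rng: np.random.Generator | None = None,
) -> list[SampleMeta]:
    """Exponential survival with the hazard scaled up in driver-high samples.

    Baseline hazard = ln2 / median_survival_days; the "high" hazard group
    gets hazard * hazard_ratio.  Administrative censoring at the horizon
    (event = 0, time = horizon).
    """
    rng = rng or _stage_rng(params.seed, "survival")
    if not truth.hazard_group:
        raise ValueError("hazard groups not assigned; run simulate_counts first")
    base_h = np.log(2) / params.median_survival_days
    out = []
    for m in metas:
        if m.sample_id not in truth.hazard_group:
            out.append(m)
            continue
        h = base_h * (params.hazard_ratio if truth.hazard_group[m.sample_id] == "high" else 1.0)
        t = rng.exponential(1.0 / h)
        if t >= params.horizon_days:
            st, ev = params.horizon_days, 0
        else:
            st, ev = t, 1
        out.append(dataclasses.replace(m, survival_time=float(st), event=ev))
    return out


# ---------------------------------------------------------------------------
# PWM library for planted motifs
# ---------------------------------------------------------------------------

def pwm_from_kmer(kmer: str, name: str, concentration: float = 0.97, source: str = "CISBP_RNA") -> PWMRecord:
    """A PWM sharply concentrated on one k-mer (off-target bases share the rest)."""
    m = np.full((len(kmer), 4), (1 - concentration) / 3)
    for i, ch in enumerate(kmer):
        m[i, BASES.index(ch)] = concentration
    return PWMRecord(name, m, source=source)


def default_pwm_library(params: SynthParams) -> list[PWMRecord]:
    """Planted-motif PWMs plus disjoint controls (never planted)."""
    return [
        pwm_from_kmer(params.planted_down_motif, "RBP_URICH"),
        pwm_from_kmer(params.planted_up_motif, "RBP_GCRICH", source="RBNS"),
        pwm_from_kmer("ACACAC", "RBP_CTRL1"),
        pwm_from_kmer("CGATAG", "RBP_CTRL2", source="RBNS"),
    ]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(params: SynthParams, outdir: str | Path) -> tuple[dict[str, Path], SyntheticTruth]:
    """Generate and write the full dataset; returns file paths and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = SyntheticTruth()

    genome = generate_genome(params)
    circs = generate_circ_annotations(genome, params)
    truth.de_status = assign_de_status(circs, params)
    genome = plant_motifs(genome, circs, truth, params)
    circ_cm, gene_cm, metas = simulate_counts(truth, params)
    metas = simulate_survival(truth, params, metas)
    pwms = default_pwm_library(params)

    paths = {
        "genome": outdir / "genome.fa",
        "circs": outdir / "circs.bed",
        "circ_counts": outdir / "circ_counts.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "samples": outdir / "samples.tsv",
        "rbp_list": outdir / "rbp_list.txt",
        "signatures": outdir / "signatures.tsv",
        "pwm_dir": outdir / "pwms",
        "truth_de": outdir / "truth_de.tsv",
        "truth_motifs": outdir / "truth_motifs.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "truth_sizefactors": outdir / "truth_sizefactors.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_circ_bed(circs, paths["circs"])
    write_count_matrix(circ_cm, paths["circ_counts"])
    write_count_matrix(gene_cm, paths["gene_counts"])
    write_sample_meta(metas, paths["samples"])
    with open(paths["rbp_list"], "w") as fh:
        for name in [g for g in gene_cm.feature_ids if g.startswith("RBP")]:
            fh.write(name + "\n")
    write_results_table(
        [
            {"gene": g, "subtype": g.split("_")[1]}
            for g in gene_cm.feature_ids
            if g.startswith("SIG_")
        ],
        paths["signatures"],
    )
    write_pwm_library(pwms, paths["pwm_dir"])

    write_results_table(
        [{"circ_id": c, "de_status": s} for c, s in truth.de_status.items()], paths["truth_de"]
    )
    write_results_table(truth.motif_insertions, paths["truth_motifs"],
                        columns=["chrom", "pos", "motif", "genomic_seq", "region_kind",
                                 "circ_id", "direction", "foreground"])
    write_results_table(
        [
            {
                "sample_id": s,
                "cluster": truth.cluster_label.get(s, -1),
                "subtype": truth.subtype_label.get(s, ""),
                "hazard_group": truth.hazard_group.get(s, ""),
            }
            for s in circ_cm.sample_ids
        ],
        paths["truth_clusters"],
    )
    write_results_table(
        [{"sample_id": s, "size_factor": f} for s, f in truth.size_factors.items()],
        paths["truth_sizefactors"],
    )
    return paths, truth
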