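"""Seeded synthetic fixtures: expression matrices with a planted
condition-specific TF and correlated target genes, and promoter genomes
with a motif planted at an elevated rate in target-gene promoters.

The generator emulates the statistical structure the pipeline assumes:
log2 intensities with i.i.d. Gaussian noise around per-gene baselines, a
TF shifted upward in the treatment arrays of exactly one condition, target
genes built as rho * (standardized TF profile) + sqrt(1-rho^2) * noise so
their expected Pearson correlation with the TF equals rho, and promoters
of i.i.d. background composition with an exact 8-mer overwritten at a
uniform position with group/background-specific probabilities.  It does
not model probe effects, intensity-dependent variance, or phylogenetic
sequence structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .expression import Condition, ConditionDesign, ExpressionMatrix
from .promoters import TSSRecord, reverse_complement

import pandas as pd

ALPHABET = "ACGT"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_tfs: int = 40
    n_conditions: int = 8
    n_datasets: int = 1
    replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    cstf_effect: float = 3.0  # log2 shift of the planted TF in its condition
    target_fraction: float = 0.03
    target_correlation: float = 0.95
    noise_sd: float = 0.25
    promoter_length: int = 1000
    gc_content: float = 0.5
    planted_motif: str = "GAATATTC"  # HSE-like full palindrome
    plant_rate_group: float = 0.8
    plant_rate_background: float = 0.05
    spacer_length: int = 20

    def __post_init__(self) -> None:
        for name in ("plant_rate_group", "plant_rate_background", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 < self.target_correlation <= 1.0:
            raise ValueError("target_correlation must be in (-1, 1]")
        if self.promoter_length < 8:
            raise ValueError("promoter_length must be >= 8")
        if len(self.planted_motif) != 8 or not set(self.planted_motif) <= set(ALPHABET):
            raise ValueError("planted_motif must be an ACGT 8-mer")


@dataclass
class GroundTruth:
    planted_tf_id: str
    planted_condition: str
    true_target_ids: list[str]
    planted_motif: str
    planted_positions: dict[str, int] = field(default_factory=dict)
    gene_strands: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic sub-streams so adding genes to one component
    # does not perturb sampling in another
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    """(all gene ids, TF gene ids).  TFs come first: TF0001..; then G0001.."""
    tfs = [f"TF{i:04d}" for i in range(1, cfg.n_tfs + 1)]
    others = [f"G{i:05d}" for i in range(1, cfg.n_genes - cfg.n_tfs + 1)]
    return tfs + others, tfs


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ConditionDesign, GroundTruth]:
    """Expression matrix + design with one planted condition-specific TF.

    The planted TF (the first TF id) is shifted by cstf_effect in the
    treatment samples of the first condition of the first dataset.  Target
    genes follow the TF profile with expected correlation
    target_correlation over the dataset's samples, inheriting its
    condition-specific induction.
    """
    rng = _rng(cfg, 0)
    genes, tfs = gene_ids(cfg)
    n_total = len(genes)

    conditions: list[Condition] = []
    datasets: dict[str, list[str]] = {}
    sample_ids: list[str] = []
    for d in range(1, cfg.n_datasets + 1):
        ds_id = f"DS{d}"
        ds_samples: list[str] = []
        for c in range(1, cfg.n_conditions + 1):
            cid = f"{ds_id}_cond{c:02d}"
            treat = [f"{cid}_t{r}" for r in range(1, cfg.replicates + 1)]
            ctrl = [f"{cid}_c{r}" for r in range(1, cfg.replicates + 1)]
            conditions.append(Condition(cid, treat, ctrl, ds_id))
            ds_samples.extend(treat + ctrl)
        datasets[ds_id] = ds_samples
        sample_ids.extend(ds_samples)

    planted_tf = tfs[0]
    planted_condition = conditions[0].condition_id
    n_targets = round(cfg.target_fraction * cfg.n_genes)
    non_tf = genes[cfg.n_tfs :]
    targets = sorted(rng.choice(non_tf, size=n_targets, replace=False).tolist())

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_total)
    values = baselines[:, None] + rng.normal(0.0, cfg.noise_sd, (n_total, len(sample_ids)))

    # planted TF: induced in treatment samples of its condition
    tf_idx = genes.index(planted_tf)
    treat_cols = [sample_ids.index(s) for s in conditions[0].treatment_sample_ids]
    values[tf_idx, treat_cols] += cfg.cstf_effect

    # targets track the TF profile at the configured correlation
    rho = cfg.target_correlation
    ds_cols = [sample_ids.index(s) for s in datasets[conditions[0].dataset_id]]
    tf_profile = values[tf_idx, ds_cols]
    sigma_t = tf_profile.std(ddof=0)
    centered = tf_profile - tf_profile.mean()
    for g in targets:
        gi = genes.index(g)
        eps = rng.normal(0.0, 1.0, len(ds_cols))
        values[gi, ds_cols] = (
            baselines[gi]
            + rho * centered
            + np.sqrt(1.0 - rho**2) * sigma_t * eps
        )

    m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    design = ConditionDesign(conditions=conditions, datasets=datasets)
    truth = GroundTruth(
        planted_tf_id=planted_tf,
        planted_condition=planted_condition,
        true_target_ids=targets,
        planted_motif=cfg.planted_motif,
    )
    return m, design, truth


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(ALPHABET[i] for i in idx)


def simulate_promoters(
    cfg: SimulationConfig,
    all_gene_ids: list[str],
    true_target_ids: list[str],
    truth: GroundTruth | None = None,
) -> tuple[dict[str, str], list[TSSRecord], GroundTruth]:
    """Genome + TSS table with the motif planted by overwrite.

    Every gene gets a single promoter of promoter_length bases of i.i.d.
    composition at the configured GC content; the planted 8-mer overwrites
    a uniform-random window with probability plant_rate_group for target
    genes and plant_rate_background otherwise.  Genes alternate between +
    and - strands so extraction is exercised on both.
    """
    rng = _rng(cfg, 1)
    L = cfg.promoter_length
    motif = cfg.planted_motif
    target_set = set(true_target_ids)
    if truth is None:
        truth = GroundTruth("", "", sorted(target_set), motif)

    chunks: list[str] = []
    tss_records: list[TSSRecord] = []
    pos = 0  # 0-based length written so far
    for i, gene in enumerate(all_gene_ids):
        promoter = list(_random_bases(rng, L, cfg.gc_content))
        rate = cfg.plant_rate_group if gene in target_set else cfg.plant_rate_background
        if rng.random() < rate:
            at = int(rng.integers(0, L - 8 + 1))
            promoter[at : at + 8] = motif
            truth.planted_positions[gene] = at
        promoter_seq = "".join(promoter)
        spacer = _random_bases(rng, cfg.spacer_length, cfg.gc_content)
        strand = "+" if i % 2 == 0 else "-"
        truth.gene_strands[gene] = strand
        if strand == "+":
            # [pos+1 .. pos+L] promoter, TSS at pos+L+1 (first spacer base)
            chunks.append(promoter_seq)
            chunks.append(spacer)
            tss = pos + L + 1
        else:
            # TSS at pos+1; [pos+2 .. pos+L+1] is the reverse complement
            chunks.append(spacer[:1])
            chunks.append(reverse_complement(promoter_seq))
            chunks.append(spacer[1:])
            tss = pos + 1
        tss_records.append(TSSRecord(f"{gene}.1", gene, "chr1", tss, strand))
        pos += L + cfg.spacer_length
    genome = {"chr1": "".join(chunks)}
    return genome, tss_records, truth


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Emit every input file the pipeline consumes, plus ground_truth.json."""
    from .expression import write_design, write_expression
    from .promoters import write_tss_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, design, truth = simulate_expression(cfg)
    genes, tfs = gene_ids(cfg)
    genome, tss_records, truth = simulate_promoters(cfg, genes, truth.true_target_ids, truth)
    write_expression(m, outdir / "expression.tsv")
    write_design(design, outdir / "design.yaml")
    (outdir / "tf_list.txt").write_text("\n".join(tfs) + "\n")
    write_genome_fasta(genome, outdir / "genome.fa")
    write_tss_table(tss_records, outdir / "tss.tsv")
    truth.save(outdir / "ground_truth.json")
    return truth
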