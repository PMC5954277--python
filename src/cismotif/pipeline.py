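"""End-to-end orchestration: normalize -> CsTF calling -> co-expression ->
promoter construction -> background indexing -> enrichment -> motif assembly.

Every stage writes its outputs as flat TSV/JSON with fixed column order and
6-significant-digit floats, so reruns on identical inputs are byte-stable
and stages can be resumed from serialized intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .assembly import (
    build_pssm,
    classify_palindrome,
    map_and_merge,
    rank_core_kmers,
    select_step1_motifs,
    tss_distance_profile,
    write_meme_motif,
    write_regions_tsv,
)
from .coexpression import CoexpressionGroup, build_group, select_degs
from .cstf import call_cstfs
from .enrichment import build_background, enrich_group, write_enrichment_tsv, BackgroundIndex
from .expression import (
    ValidationError,
    quantile_normalize,
    read_design,
    read_expression,
)
from .promoters import (
    GenomeLookup,
    PromoterSet,
    build_promoter_set,
    read_tss_table,
    write_promoters,
)

log = logging.getLogger("cismotif")


@dataclass
class PipelineConfig:
    expression_path: str = ""
    design_path: str = ""
    tf_list_path: str = ""
    genome_path: str = ""
    tss_path: str = ""
    outdir: str = "cismotif_out"
    # thresholds (defaults are the published cut-offs)
    alpha_detf: float = 0.01
    min_lfc: float = 1.0
    min_z: float = 2.0
    alpha_deg: float = 0.01
    min_abs_lfc: float = math.log2(1.5)
    min_pcc: float = 0.8
    alpha_enrich: float = 0.001
    k_min: int = 4
    k_max: int = 8
    enrich_k: int = 8
    top_cores: int = 10
    promoter_length: int = 1000
    min_group_size: int = 10
    merge_gap: int = 0
    # switches
    apply_quantile_normalization: bool = False
    equal_var: bool = False
    two_sided_fc: bool = False
    both_strands: bool = False
    include_self: bool = False
    require_both_cores: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_detf", "alpha_deg", "alpha_enrich"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not -1.0 <= self.min_pcc <= 1.0:
            raise ValidationError(f"min_pcc must be in [-1, 1], got {self.min_pcc}")
        if not (1 <= self.k_min <= self.k_max):
            raise ValidationError(f"invalid k range ({self.k_min}, {self.k_max})")
        if not (self.k_min <= self.enrich_k <= self.k_max):
            raise ValidationError("enrich_k must lie within the k range")
        if self.promoter_length < self.enrich_k:
            raise ValidationError("promoter_length must be >= enrich_k")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the machine-readable run summary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading expression matrix and design")
    m = read_expression(cfg.expression_path)
    design = read_design(cfg.design_path)
    design.validate_against(m)
    if cfg.apply_quantile_normalization:
        m = quantile_normalize(m)
    tf_ids = [
        line.strip()
        for line in Path(cfg.tf_list_path).read_text().splitlines()
        if line.strip()
    ]

    # --- stage: CsTF calling -------------------------------------------------
    log.info("calling condition-specific TFs")
    detfs, zscores, cstfs = call_cstfs(
        m,
        design,
        tf_ids,
        alpha=cfg.alpha_detf,
        min_log2fc=cfg.min_lfc,
        z_threshold=cfg.min_z,
        equal_var=cfg.equal_var,
        two_sided_fc=cfg.two_sided_fc,
    )
    cstf_keys = {(c.tf_id, c.condition_id) for c in cstfs}
    detf_keys = {(d.tf_id, d.condition_id): d for d in detfs}
    with open(out / "cstf.tsv", "w") as fh:
        fh.write("tf_id\tcondition_id\tp_value\tlog2_fc\tz\tis_detf\tis_cstf\n")
        for (tf, cond), zrec in sorted(zscores.items()):
            d = detf_keys.get((tf, cond))
            z_str = _fmt(zrec.z) if zrec.z is not None else "NA"
            p_str = _fmt(d.p_value) if d else "NA"
            fc_str = _fmt(d.log2_fc) if d else _fmt(zrec.x)
            fh.write(
                f"{tf}\t{cond}\t{p_str}\t{fc_str}\t{z_str}\t"
                f"{int(d is not None)}\t{int((tf, cond) in cstf_keys)}\n"
            )

    # --- stage: promoters ----------------------------------------------------
    log.info("building promoter set")
    genome = GenomeLookup(cfg.genome_path)
    tss = read_tss_table(cfg.tss_path)
    ps = build_promoter_set(tss, genome, cfg.promoter_length, cfg.merge_gap)
    write_promoters(ps, out / "promoters.fa", out / "promoters.bed")

    # --- stage: background ---------------------------------------------------
    log.info("indexing k-mer background (k=%d..%d)", cfg.k_min, cfg.k_max)
    bg = build_background(ps, cfg.k_min, cfg.k_max, cfg.both_strands)
    bg.save(out / "background.json")

    # --- stage: co-expression + enrichment + assembly per CsTF ---------------
    summary_groups = []
    deg_cache: dict[str, list[str]] = {}
    for c in sorted(cstfs, key=lambda r: (r.tf_id, r.condition_id)):
        if c.condition_id not in deg_cache:
            deg_cache[c.condition_id] = select_degs(
                m, design, c.condition_id, cfg.alpha_deg, cfg.min_abs_lfc, cfg.equal_var
            )
        degs = deg_cache[c.condition_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group = build_group(
                c, degs, m, design, cfg.min_pcc, cfg.min_group_size, cfg.include_self
            )
        tag = f"{c.tf_id}_{c.condition_id}"
        with open(out / f"group_{tag}.tsv", "w") as fh:
            fh.write("cstf_id\tcondition_id\tgene_id\tpcc\n")
            for g in group.member_gene_ids:
                fh.write(f"{c.tf_id}\t{c.condition_id}\t{g}\t{_fmt(group.pcc[g])}\n")
        entry = {
            "cstf_id": c.tf_id,
            "condition_id": c.condition_id,
            "n_degs": len(degs),
            "group_size": group.size,
            "discarded": group.discarded,
            "n_enriched": 0,
            "consensus": None,
        }
        if not group.discarded:
            entry.update(_enrich_and_assemble(group, ps, bg, cfg, out, tag))
        summary_groups.append(entry)

    summary = {
        "n_tfs": len(tf_ids),
        "n_conditions": len(design.conditions),
        "n_detfs": len(detfs),
        "n_cstfs": len(cstfs),
        "n_promoters": len(ps),
        "n_promoter_genes": len(ps.gene_ids),
        "groups": summary_groups,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


def _enrich_and_assemble(
    group: CoexpressionGroup,
    ps: PromoterSet,
    bg: BackgroundIndex,
    cfg: PipelineConfig,
    out: Path,
    tag: str,
) -> dict:
    log.info("enrichment for %s (group size %d)", tag, group.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = enrich_group(
            group.member_gene_ids, ps, bg, cfg.alpha_enrich, cfg.enrich_k
        )
    write_enrichment_tsv(results, out / f"enrichment_{tag}.tsv")
    enriched = sorted(r.motif for r in results if r.enriched)
    entry: dict = {"n_enriched": len(enriched), "consensus": None}
    if not enriched:
        return entry

    r3 = rank_core_kmers(enriched, 3, cfg.top_cores)
    r4 = rank_core_kmers(enriched, 4, cfg.top_cores)
    with open(out / f"cores_{tag}.tsv", "w") as fh:
        fh.write("core_length\tcore\tcount\n")
        for rk in (r3, r4):
            for core, n in rk.entries:
                fh.write(f"{rk.core_length}\t{core}\t{n}\n")
    selected = select_step1_motifs(enriched, r3, r4, cfg.require_both_cores)

    group_set = set(group.member_gene_ids)
    group_ps = PromoterSet([r for r in ps.records if r.gene_id in group_set])
    regions = map_and_merge(selected, group_ps)
    write_regions_tsv(regions, out / f"regions_{tag}.tsv")

    with open(out / f"palindromes_{tag}.tsv", "w") as fh:
        fh.write("motif\tclassification\n")
        for mtf in enriched:
            fh.write(f"{mtf}\t{classify_palindrome(mtf)}\n")

    hist = tss_distance_profile(regions, group_ps, 100, cfg.promoter_length)
    with open(out / f"tss_profile_{tag}.tsv", "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, n in enumerate(hist):
            fh.write(f"{i * 100}\t{(i + 1) * 100}\t{n}\n")

    if regions:
        anchor = r3.cores[0] if r3.cores else None
        pssm = build_pssm(regions, anchor_core=anchor)
        write_meme_motif(pssm, tag, out / f"pssm_{tag}.meme")
        entry["consensus"] = pssm.consensus
    return entry
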