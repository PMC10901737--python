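"""End-to-end orchestration: screen (slice -> call -> annotate -> filter ->
triage) and scan (inverted repeat pairs per transcript), driven by one JSON
configuration with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .alignment_io import SpeciesPartition, read_maf
from .effect_triage import (
    DamagingScores,
    classify_consequence,
    is_damaging,
    read_scores_tsv,
    select_transcript,
    transcripts_from_gff3,
    triage,
)
from .lineage_screen import (
    VariantCallConfig,
    read_gene_bed,
    screen_genes,
    write_variants,
)
from .stempair_scan import (
    PairScanConfig,
    candidates_to_frame,
    find_inverted_pairs,
    rank_candidates,
    read_repeats_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    maf: Optional[str] = None
    genes: Optional[str] = None  # BED6
    gff: Optional[str] = None
    fasta: Optional[str] = None
    repeats: Optional[str] = None  # BED6
    scores: Optional[str] = None  # TSV keyed chrom:pos:allele
    outdir: str = "tailscan_out"
    ingroup: Optional[list[str]] = None
    outgroups: Optional[list[str]] = None
    reference: Optional[str] = None
    flank_bp: int = 10_000
    snv_rule: str = "any-differs"
    ins_rule: str = "any-absent"
    sift_cut: float = 0.05
    polyphen_cut: float = 0.446
    max_inner_distance: int = 10_000
    min_identity_fraction: float = 0.6
    lam: float = 2_000.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def partition(self) -> SpeciesPartition:
        kwargs = {}
        if self.ingroup:
            kwargs["ingroup"] = tuple(self.ingroup)
            kwargs["reference"] = self.reference or self.ingroup[0]
        elif self.reference:
            kwargs["reference"] = self.reference
        if self.outgroups:
            kwargs["outgroups"] = tuple(self.outgroups)
        return SpeciesPartition(**kwargs)

    def call_config(self) -> VariantCallConfig:
        return VariantCallConfig(
            snv_outgroup_rule=self.snv_rule,
            ins_outgroup_rule=self.ins_rule,
            flank_bp=self.flank_bp,
        )

    def scan_config(self) -> PairScanConfig:
        return PairScanConfig(
            max_inner_distance=self.max_inner_distance,
            min_identity_fraction=self.min_identity_fraction,
            lam=self.lam,
        )

    def manifest(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
        return {"config": cfg, "config_sha256": digest, "tailscan_version": __version__}


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ValueError(f"pipeline config is missing the {what} input")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def _open_fasta(path: Path):
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def run_screen(config: PipelineConfig) -> dict[str, Path]:
    """Variant screen over gene regions, with optional consequence
    annotation, damaging-score filtering and triage when a transcript
    annotation (and genome) are supplied."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maf_path = _require(config.maf, "MAF alignment")
    genes_path = _require(config.genes, "gene table")

    with open(maf_path) as fh:
        blocks = read_maf(fh)
    genes = read_gene_bed(genes_path)
    partition = config.partition()
    table, summary = screen_genes(blocks, genes, partition, config.call_config())
    logger.info("screen: %d blocks, %d genes -> %d variant records",
                len(blocks), len(genes), len(table))

    outputs: dict[str, Path] = {}
    variants_path = outdir / "variants.tsv"
    write_variants(table, str(variants_path))
    outputs["variants"] = variants_path

    summary_payload = summary.as_dict()

    if config.gff and config.fasta:
        gff_path = _require(config.gff, "transcript annotation")
        fasta_path = _require(config.fasta, "genome FASTA")
        genome = _open_fasta(fasta_path)
        by_gene = transcripts_from_gff3(str(gff_path))
        scores = read_scores_tsv(config.scores) if config.scores else {}

        # re-call variants as objects for annotation
        cfg = config.call_config()
        from .lineage_screen import call_indels, call_snvs

        consequences = []
        for gene_id, interval in genes:
            if gene_id not in by_gene:
                continue
            selected = select_transcript(by_gene[gene_id])
            others = [t for t in by_gene[gene_id] if t is not selected]
            region = interval.expanded(cfg.flank_bp)
            from .alignment_io import slice_block

            for block in blocks:
                sub = slice_block(block, region, partition.reference)
                if sub.width == 0:
                    continue
                for v in call_snvs(sub, partition, cfg, gene_id=gene_id) + call_indels(
                    sub, partition, cfg, gene_id=gene_id
                ):
                    call = classify_consequence(v, selected, genome, cfg.flank_bp)
                    key = (
                        f"{v.ref_interval.chrom}:{v.ref_interval.start + 1}:"
                        f"{v.ingroup_allele or '-'}"
                    )
                    sc = scores.get(key, DamagingScores())
                    damaging = is_damaging(
                        call.consequence, sc, config.sift_cut, config.polyphen_cut
                    )
                    on_others = [
                        classify_consequence(v, t, genome, cfg.flank_bp) for t in others
                    ]
                    decision = triage(call, None, on_others) if damaging else None
                    consequences.append(
                        {
                            "chrom": v.ref_interval.chrom,
                            "pos": v.ref_interval.start + 1,
                            "kind": v.kind,
                            "gene_id": gene_id,
                            "transcript_id": call.transcript_id,
                            "consequence": call.consequence,
                            "protein_change": (
                                f"{call.protein_change[1]}{call.protein_change[0]}"
                                f"{call.protein_change[2]}"
                                if call.protein_change
                                else ""
                            ),
                            "sift": "" if sc.sift is None else sc.sift,
                            "polyphen": "" if sc.polyphen is None else sc.polyphen,
                            "damaging": damaging,
                            "triage": decision.category if decision else "",
                            "triage_evidence": decision.evidence if decision else "",
                        }
                    )
        cons_df = pd.DataFrame.from_records(consequences)
        cons_path = outdir / "consequences.tsv"
        cons_df.to_csv(cons_path, sep="\t", index=False)
        outputs["consequences"] = cons_path
        n_called = len(cons_df)
        n_damaging = int(cons_df["damaging"].sum()) if n_called else 0
        summary_payload["n_annotated"] = n_called
        summary_payload["n_damaging"] = n_damaging
        logger.info("annotate: %d calls, %d damaging", n_called, n_damaging)

    summary_path = outdir / "screen_summary.json"
    summary_path.write_text(json.dumps(summary_payload, indent=1))
    outputs["summary"] = summary_path
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(config.manifest(), indent=1))
    outputs["manifest"] = manifest_path
    return outputs


def run_scan(config: PipelineConfig) -> dict[str, Path]:
    """Inverted repeat-pair scan over every transcript in the annotation."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff_path = _require(config.gff, "transcript annotation")
    fasta_path = _require(config.fasta, "genome FASTA")
    repeats_path = _require(config.repeats, "repeat BED")

    genome = _open_fasta(fasta_path)
    repeats = read_repeats_bed(repeats_path)
    by_gene = transcripts_from_gff3(str(gff_path))
    scan_cfg = config.scan_config()

    frames = []
    for gene_id in sorted(by_gene):
        for t in by_gene[gene_id]:
            cands = rank_candidates(
                find_inverted_pairs(
                    t,
                    [r for r in repeats if r.interval.chrom == t.chrom],
                    genome,
                    scan_cfg,
                ),
                scan_cfg,
            )
            if cands:
                frames.append(candidates_to_frame(cands, t.transcript_id))
            logger.info("scan: %s -> %d candidates", t.transcript_id, len(cands))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else candidates_to_frame([])
    )
    out_path = Path(outdir) / "pair_candidates.tsv"
    table.to_csv(out_path, sep="\t", index=False)
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(config.manifest(), indent=1))
    return {"candidates": out_path, "manifest": manifest_path}
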