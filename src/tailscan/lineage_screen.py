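"""Call hominoid-specific SNVs, insertions, and deletions from alignment blocks.

The calling rules operate column-wise on an 8-species alignment split into a
six-species tailless ingroup and two tailed outgroups:

* SNV — every ingroup species carries the same base and that base differs
  from at least one outgroup base (``any-differs``; a stricter
  ``both-differ`` rule is available).
* insertion — every ingroup species carries sequence while at least one
  outgroup is gapped (``any-absent``; ``both-absent`` available). Maximal
  runs of such columns with an identical per-outgroup absence pattern merge
  into a single insertion.
* deletion — the whole ingroup is gapped while both outgroups carry
  sequence; maximal runs merge into one deletion anchored between the two
  flanking reference bases (a width-0 interval, since the deleted sequence
  has no reference coordinates).

Sites where the two outgroups disagree with each other are still called but
flagged ``ambiguous_outgroup``: they may be outgroup-specific changes rather
than ingroup-specific ones. Columns containing N in any decisive species are
never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

import pandas as pd

from .alignment_io import (
    GAP,
    NO_CALL,
    AlignmentBlock,
    SpeciesPartition,
    ref_positions,
    slice_block,
)
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"

# per-outgroup support states
DIFFERS = "differs"
MATCHES = "matches"
ABSENT = "absent"
MISSING = "missing"


@dataclass(frozen=True)
class VariantCallConfig:
    """Presence/absence rules and screen geometry.

    ``snv_outgroup_rule``: ``any-differs`` calls an SNV when the shared
    ingroup base differs from at least one outgroup; ``both-differ`` requires
    both. ``ins_outgroup_rule`` analogously for gap-based absence. Deletions
    always require both outgroups present. ``flank_bp`` is the distance by
    which gene intervals are widened on both sides before calling.
    """

    snv_outgroup_rule: str = "any-differs"
    ins_outgroup_rule: str = "any-absent"
    del_outgroup_rule: str = "both-present"
    require_complete_ingroup: bool = True
    min_indel_length: int = 1
    flank_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.snv_outgroup_rule not in ("any-differs", "both-differ"):
            raise ValueError(f"bad snv rule {self.snv_outgroup_rule!r}")
        if self.ins_outgroup_rule not in ("any-absent", "both-absent"):
            raise ValueError(f"bad insertion rule {self.ins_outgroup_rule!r}")
        if self.del_outgroup_rule != "both-present":
            raise ValueError("deletion rule is fixed to both-present")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.min_indel_length < 1:
            raise ValueError("min_indel_length must be >= 1")


@dataclass(frozen=True)
class ColumnVerdict:
    kind: str  # "none" | "snv" | "ins_site" | "del_site"
    ingroup_allele: str = ""
    outgroup_alleles: tuple[str, ...] = ()
    outgroup_support: tuple[str, ...] = ()
    ambiguous: bool = False


NONE_VERDICT = ColumnVerdict("none")


@dataclass(frozen=True)
class LineageVariant:
    """A called ingroup-specific variant on reference coordinates."""

    kind: str
    ref_interval: GenomicInterval
    ingroup_allele: str
    outgroup_alleles: tuple[str, ...]
    outgroup_support: tuple[str, ...]
    ambiguous_outgroup: bool
    gene_id: Optional[str] = None
    block_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == SNV and len(self.ingroup_allele) != 1:
            raise ValueError("SNV ingroup allele must be a single base")
        if self.kind == DELETION and self.ingroup_allele != "":
            raise ValueError("deletion ingroup allele must be empty")
        if self.kind == INSERTION and self.ref_interval.width != len(
            self.ingroup_allele
        ):
            raise ValueError("insertion interval width must match segment length")
        if self.ambiguous_outgroup != (len(set(self.outgroup_support)) > 1):
            raise ValueError("ambiguous flag inconsistent with outgroup support")


@dataclass
class ScreenSummary:
    n_snv: int
    n_insertion: int
    n_deletion: int
    per_gene: pd.DataFrame  # columns: gene_id, n_snv, n_insertion, n_deletion

    def as_dict(self) -> dict:
        return {
            "n_snv": self.n_snv,
            "n_insertion": self.n_insertion,
            "n_deletion": self.n_deletion,
            "per_gene": self.per_gene.to_dict(orient="records"),
        }


def _state(ch: Optional[str]) -> str:
    if ch is None or ch == NO_CALL:
        return MISSING
    if ch == GAP:
        return "gap"
    return "base"


def classify_column(
    column: dict[str, str],
    partition: SpeciesPartition,
    config: VariantCallConfig = VariantCallConfig(),
) -> ColumnVerdict:
    """Apply the presence/absence rules to one alignment column.

    ``column`` maps species id -> character over ``{A,C,G,T,N,-}``; species
    absent from the block should simply be absent from the map. N counts as
    missing, and any missing decisive species yields the ``none`` verdict.
    """
    ing = [column.get(s) for s in partition.ingroup]
    outs = [column.get(s) for s in partition.outgroups]
    ing_states = [_state(c) for c in ing]
    out_states = [_state(c) for c in outs]

    if MISSING in out_states:
        return NONE_VERDICT
    if config.require_complete_ingroup and MISSING in ing_states:
        return NONE_VERDICT

    present_ing = [c for c, st in zip(ing, ing_states) if st != MISSING]
    if not present_ing:
        return NONE_VERDICT

    out_chars = tuple(c for c in outs)  # all present at this point

    if all(st == "base" for st in ing_states) and all(
        c == present_ing[0] for c in present_ing
    ):
        base = present_ing[0]
        support = tuple(
            ABSENT if c == GAP else (MATCHES if c == base else DIFFERS)
            for c in out_chars
        )
        n_absent = support.count(ABSENT)
        ins_fires = (
            n_absent >= 1
            if config.ins_outgroup_rule == "any-absent"
            else n_absent == len(support)
        )
        if ins_fires:
            return ColumnVerdict(
                "ins_site",
                ingroup_allele=base,
                outgroup_alleles=out_chars,
                outgroup_support=support,
                ambiguous=len(set(support)) > 1,
            )
        if all(st == "base" for st in out_states):
            n_diff = support.count(DIFFERS)
            snv_fires = (
                n_diff >= 1
                if config.snv_outgroup_rule == "any-differs"
                else n_diff == len(support)
            )
            if snv_fires:
                return ColumnVerdict(
                    "snv",
                    ingroup_allele=base,
                    outgroup_alleles=out_chars,
                    outgroup_support=support,
                    ambiguous=len(set(support)) > 1,
                )
        return NONE_VERDICT

    if all(st == "gap" for st in ing_states) and all(
        st == "base" for st in out_states
    ):
        # outgroup retains sequence the ingroup lost
        support = tuple(DIFFERS for _ in out_chars)
        return ColumnVerdict(
            "del_site",
            ingroup_allele="",
            outgroup_alleles=out_chars,
            outgroup_support=support,
            ambiguous=False,
        )
    return NONE_VERDICT


def _block_id(block: AlignmentBlock, reference: str) -> str:
    row = block.row(reference)
    return f"{row.src}:{row.source_start}"


def call_snvs(
    block: AlignmentBlock,
    partition: SpeciesPartition,
    config: VariantCallConfig = VariantCallConfig(),
    gene_id: Optional[str] = None,
) -> list[LineageVariant]:
    """One SNV per qualifying column that has a non-gap reference position."""
    ref_row = block.row(partition.reference)
    coords = ref_positions(block, partition.reference)
    bid = _block_id(block, partition.reference)
    out = []
    for i in range(block.width):
        if coords[i] is None:
            continue
        v = classify_column(block.column(i), partition, config)
        if v.kind != "snv":
            continue
        out.append(
            LineageVariant(
                kind=SNV,
                ref_interval=GenomicInterval(ref_row.chrom, coords[i], coords[i] + 1),
                ingroup_allele=v.ingroup_allele,
                outgroup_alleles=v.outgroup_alleles,
                outgroup_support=v.outgroup_support,
                ambiguous_outgroup=v.ambiguous,
                gene_id=gene_id,
                block_id=bid,
            )
        )
    return out


def call_indels(
    block: AlignmentBlock,
    partition: SpeciesPartition,
    config: VariantCallConfig = VariantCallConfig(),
    gene_id: Optional[str] = None,
) -> list[LineageVariant]:
    """Merge maximal runs of insertion/deletion columns into variants.

    Insertion runs merge only while the per-outgroup absence pattern is
    identical; a single interrupting column breaks the run. Deletion runs are
    anchored at the reference coordinate immediately following the run (a
    width-0 interval between the flanking reference bases).
    """
    ref_row = block.row(partition.reference)
    coords = ref_positions(block, partition.reference)
    chrom = ref_row.chrom
    bid = _block_id(block, partition.reference)
    verdicts = [classify_column(block.column(i), partition, config) for i in range(block.width)]

    out: list[LineageVariant] = []
    i = 0
    while i < block.width:
        v = verdicts[i]
        if v.kind == "ins_site" and coords[i] is not None:
            j = i
            while (
                j + 1 < block.width
                and verdicts[j + 1].kind == "ins_site"
                and verdicts[j + 1].outgroup_support == v.outgroup_support
                and coords[j + 1] is not None
            ):
                j += 1
            run = range(i, j + 1)
            if len(run) >= config.min_indel_length:
                segment = "".join(verdicts[k].ingroup_allele for k in run)
                og = tuple(
                    "".join(verdicts[k].outgroup_alleles[o] for k in run)
                    for o in range(len(partition.outgroups))
                )
                out.append(
                    LineageVariant(
                        kind=INSERTION,
                        ref_interval=GenomicInterval(
                            chrom, coords[i], coords[j] + 1
                        ),
                        ingroup_allele=segment,
                        outgroup_alleles=og,
                        outgroup_support=v.outgroup_support,
                        ambiguous_outgroup=v.ambiguous,
                        gene_id=gene_id,
                        block_id=bid,
                    )
                )
            i = j + 1
        elif v.kind == "del_site":
            j = i
            while j + 1 < block.width and verdicts[j + 1].kind == "del_site":
                j += 1
            run = range(i, j + 1)
            if len(run) >= config.min_indel_length:
                anchor = next(
                    (coords[k] for k in range(j + 1, block.width) if coords[k] is not None),
                    None,
                )
                if anchor is None:
                    prev = next(
                        (coords[k] for k in range(i - 1, -1, -1) if coords[k] is not None),
                        None,
                    )
                    anchor = ref_row.source_start if prev is None else prev + 1
                og = tuple(
                    "".join(verdicts[k].outgroup_alleles[o] for k in run)
                    for o in range(len(partition.outgroups))
                )
                out.append(
                    LineageVariant(
                        kind=DELETION,
                        ref_interval=GenomicInterval(chrom, anchor, anchor),
                        ingroup_allele="",
                        outgroup_alleles=og,
                        outgroup_support=v.outgroup_support,
                        ambiguous_outgroup=v.ambiguous,
                        gene_id=gene_id,
                        block_id=bid,
                    )
                )
            i = j + 1
        else:
            i += 1
    return out


def _variant_key(v: LineageVariant) -> tuple:
    return (
        v.kind,
        v.ref_interval.chrom,
        v.ref_interval.start,
        v.ref_interval.end,
        v.ingroup_allele,
        v.outgroup_alleles,
    )


def variants_to_frame(variants: Sequence[LineageVariant]) -> pd.DataFrame:
    records = [
        {
            "chrom": v.ref_interval.chrom,
            "start": v.ref_interval.start,
            "end": v.ref_interval.end,
            "kind": v.kind,
            "ingroup_allele": v.ingroup_allele,
            "outgroup_alleles": ",".join(v.outgroup_alleles),
            "outgroup_support": ",".join(v.outgroup_support),
            "ambiguous_outgroup": v.ambiguous_outgroup,
            "gene_id": v.gene_id or "",
            "block_id": v.block_id or "",
        }
        for v in variants
    ]
    cols = [
        "chrom", "start", "end", "kind", "ingroup_allele", "outgroup_alleles",
        "outgroup_support", "ambiguous_outgroup", "gene_id", "block_id",
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def screen_genes(
    blocks: Sequence[AlignmentBlock],
    genes: Sequence[tuple[str, GenomicInterval]],
    partition: SpeciesPartition = SpeciesPartition(),
    config: VariantCallConfig = VariantCallConfig(),
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Screen each gene region (widened by ``flank_bp``) across all blocks.

    Returns a variant table labelled per gene, and a summary whose global
    counts de-duplicate variants shared between overlapping gene regions.
    """
    all_variants: list[LineageVariant] = []
    per_gene_rows = []
    for gene_id, interval in genes:
        region = interval.expanded(config.flank_bp)
        gene_variants: list[LineageVariant] = []
        for block in blocks:
            if not block.has(partition.reference):
                raise KeyError(f"reference {partition.reference!r} absent from block")
            sub = slice_block(block, region, partition.reference)
            if sub.width == 0:
                continue
            gene_variants.extend(call_snvs(sub, partition, config, gene_id=gene_id))
            gene_variants.extend(call_indels(sub, partition, config, gene_id=gene_id))
        if not gene_variants:
            logger.warning("gene %s: no variants (or no overlapping blocks)", gene_id)
        per_gene_rows.append(
            {
                "gene_id": gene_id,
                "n_snv": sum(v.kind == SNV for v in gene_variants),
                "n_insertion": sum(v.kind == INSERTION for v in gene_variants),
                "n_deletion": sum(v.kind == DELETION for v in gene_variants),
            }
        )
        all_variants.extend(gene_variants)

    # global counts: a variant found under two overlapping gene regions
    # counts once
    seen: set[tuple] = set()
    unique: list[LineageVariant] = []
    for v in all_variants:
        k = _variant_key(v)
        if k not in seen:
            seen.add(k)
            unique.append(v)
    summary = ScreenSummary(
        n_snv=sum(v.kind == SNV for v in unique),
        n_insertion=sum(v.kind == INSERTION for v in unique),
        n_deletion=sum(v.kind == DELETION for v in unique),
        per_gene=pd.DataFrame.from_records(
            per_gene_rows, columns=["gene_id", "n_snv", "n_insertion", "n_deletion"]
        ),
    )
    table = variants_to_frame(all_variants)
    return table, summary


# --- variant table I/O -----------------------------------------------------

TSV_COLUMNS = ["CHROM", "POS", "KIND", "INGROUP_ALLELE", "OUTGROUP_ALLELES", "FLAGS", "GENE"]


def write_variants(
    table: pd.DataFrame, stream: Union[TextIO, str], format: str = "tsv"
) -> None:
    """Write a variant table as TSV (POS 1-based, sorted) or BED."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        df = table.sort_values(["chrom", "start", "end", "kind"], kind="mergesort")
        if format == "tsv":
            out = pd.DataFrame(
                {
                    "CHROM": df["chrom"],
                    "POS": df["start"] + 1,
                    "KIND": df["kind"],
                    "INGROUP_ALLELE": df["ingroup_allele"].replace("", "."),
                    "OUTGROUP_ALLELES": df["outgroup_alleles"],
                    "FLAGS": df["ambiguous_outgroup"].map(
                        lambda a: "ambiguous_outgroup" if a else "."
                    ),
                    "GENE": df["gene_id"].replace("", "."),
                }
            )
            out.to_csv(stream, sep="\t", index=False)
        elif format == "bed":
            bed = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df["kind"] + ":" + df["ingroup_allele"].replace("", "-"),
                    "score": 0,
                    "strand": "+",
                }
            )
            bed.to_csv(stream, sep="\t", index=False, header=False)
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            stream.close()


def read_variants(stream: Union[TextIO, str]) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_variants` (tsv format)."""
    df = pd.read_csv(stream, sep="\t", dtype={"CHROM": str})
    df["INGROUP_ALLELE"] = df["INGROUP_ALLELE"].fillna(".").replace(".", "")
    df["GENE"] = df["GENE"].fillna(".").replace(".", "")
    starts = df["POS"] - 1
    widths = df.apply(
        lambda r: 0
        if r["KIND"] == DELETION
        else (1 if r["KIND"] == SNV else len(r["INGROUP_ALLELE"])),
        axis=1,
    ) if len(df) else pd.Series([], dtype=int)
    return pd.DataFrame(
        {
            "chrom": df["CHROM"],
            "start": starts,
            "end": starts + widths,
            "kind": df["KIND"],
            "ingroup_allele": df["INGROUP_ALLELE"],
            "outgroup_alleles": df["OUTGROUP_ALLELES"],
            "ambiguous_outgroup": df["FLAGS"] == "ambiguous_outgroup",
            "gene_id": df["GENE"],
        }
    )


def read_gene_bed(stream: Union[TextIO, str]) -> list[tuple[str, GenomicInterval]]:
    """Gene intervals from BED6 (name column = gene id)."""
    try:
        df = pd.read_csv(
            stream,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str},
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        (r.name, GenomicInterval(r.chrom, int(r.start), int(r.end),
                                 r.strand if r.strand in ("+", "-") else "+"))
        for r in df.itertuples(index=False)
    ]
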