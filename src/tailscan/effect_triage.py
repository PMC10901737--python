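"""Coding-consequence classification and candidate triage.

Variants from the lineage screen are interpreted against one selected
transcript per gene ("the longest transcript with the most exons"): exon
count first, spliced length second, transcript id as a deterministic
tie-break. Consequences are computed inversely to ordinary variant calling:
the ingroup (hominoid reference) allele is the reference and the outgroup
allele is the alternate, because no ancestral genome is available.

SNVs surviving the consequence step are filtered on externally supplied
SIFT (< 0.05, deleterious) and PolyPhen (> 0.446, damaging) scores;
protein-altering indels pass unconditionally. Remaining candidates are
triaged into the three recurring false-positive categories (outgroup-specific
change, consequence only on a minor transcript, amino acid shared with a
tailed species) or kept as true candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .intervals import GenomicInterval
from .lineage_screen import INSERTION, SNV, LineageVariant

SPLICE_WINDOW = 2  # intronic bp adjacent to an exon boundary

CONSEQUENCE_CLASSES = (
    "flank_upstream",
    "flank_downstream",
    "intronic",
    "splice_region",
    "utr",
    "synonymous",
    "missense",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
    "stop_gained",
    "stop_lost",
)

PROTEIN_ALTERING = {
    "missense",
    "stop_gained",
    "stop_lost",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
}

_SNV_CLASSES = {"synonymous", "missense", "stop_gained", "stop_lost"}


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence slice from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end].upper()
    return str(seq[start:end]).upper()  # pyfaidx FastaRecord supports slicing


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are stored in ascending genomic order; transcript
    (5'->3') order is derived from ``strand``. Exon ordinals used throughout
    are 1-based in transcript order.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda c: c.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS outside exons")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.width for c in self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_in_transcript_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[GenomicInterval]:
        """Introns in ascending genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def exon_cds_length(self, ordinal: int) -> int:
        """CDS bases inside the exon with the given 1-based transcript ordinal."""
        exon = self.exons_in_transcript_order()[ordinal - 1]
        return sum(
            min(exon.end, c.end) - max(exon.start, c.start)
            for c in self.cds
            if c.overlaps(exon)
        )

    def cds_sequence(self, genome) -> str:
        parts = [_fetch(genome, self.chrom, c.start, c.end) for c in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_index_of(self, genomic_pos: int) -> Optional[int]:
        """0-based position within the (stranded) CDS, or None if non-coding."""
        offset = 0
        fwd = None
        for c in self.cds:
            if c.start <= genomic_pos < c.end:
                fwd = offset + (genomic_pos - c.start)
                break
            offset += c.width
        if fwd is None:
            return None
        return fwd if self.strand == "+" else self.cds_length - 1 - fwd


def select_transcript(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick the transcript with the most exons, then the longest spliced
    length, then the lexicographically smallest id."""
    if not transcripts:
        raise ValueError("no transcripts to select from")
    return max(
        transcripts,
        key=lambda t: (t.exon_count, t.spliced_length, _NegStr(t.transcript_id)),
    )


class _NegStr(str):
    """Reverses string ordering so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class ConsequenceCall:
    variant: Optional[LineageVariant]
    consequence: str
    protein_change: Optional[tuple[int, str, str]] = None  # (1-based aa pos, ref, alt)
    transcript_id: Optional[str] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if (self.protein_change is not None) != (self.consequence in _SNV_CLASSES):
            raise ValueError("protein_change must accompany coding SNV classes only")


@dataclass(frozen=True)
class DamagingScores:
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in (("sift", self.sift), ("polyphen", self.polyphen)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score must lie in [0, 1], got {v}")


def translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _effective_interval(variant: LineageVariant) -> GenomicInterval:
    iv = variant.ref_interval
    if iv.width == 0:  # deletion anchor: the junction point before base iv.start
        return GenomicInterval(iv.chrom, iv.start, iv.start + 1)
    return iv


def _alt_base(variant: LineageVariant) -> Optional[str]:
    """Outgroup base used as the alternate allele for an SNV."""
    for b in variant.outgroup_alleles:
        if b in "ACGT" and b != variant.ingroup_allele:
            return b
    return None


def classify_consequence(
    variant: LineageVariant,
    transcript: TranscriptModel,
    genome=None,
    flank_bp: int = 10_000,
) -> ConsequenceCall:
    """Positional + coding consequence of one variant on one transcript.

    Splice-region takes precedence over any coding class; CDS SNVs are
    translated strand-aware with the standard genetic code; CDS indels are
    in-frame iff their CDS-overlapping length is divisible by 3.
    """
    if variant.ref_interval.chrom != transcript.chrom:
        raise ValueError("variant and transcript on different chromosomes")
    iv = _effective_interval(variant)
    span = transcript.span
    tid = transcript.transcript_id

    if iv.end <= span.start or iv.start >= span.end:
        before = iv.end <= span.start
        upstream = before if transcript.strand == "+" else not before
        return ConsequenceCall(
            variant,
            "flank_upstream" if upstream else "flank_downstream",
            transcript_id=tid,
        )

    for intron in transcript.introns():
        donor = GenomicInterval(iv.chrom, intron.start, min(intron.start + SPLICE_WINDOW, intron.end))
        acceptor = GenomicInterval(iv.chrom, max(intron.end - SPLICE_WINDOW, intron.start), intron.end)
        if iv.overlaps(donor) or iv.overlaps(acceptor):
            return ConsequenceCall(variant, "splice_region", transcript_id=tid)

    cds_overlap = sum(
        min(iv.end, c.end) - max(iv.start, c.start)
        for c in transcript.cds
        if c.overlaps(iv)
    )
    exon_overlap = any(e.overlaps(iv) for e in transcript.exons)

    if variant.kind == SNV:
        if cds_overlap > 0:
            idx = transcript.cds_index_of(variant.ref_interval.start)
            assert idx is not None
            cds_seq = transcript.cds_sequence(genome)
            codon_i = idx // 3
            codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
            if len(codon) < 3:
                return ConsequenceCall(
                    variant, "utr", transcript_id=tid, note="partial terminal codon"
                )
            alt = _alt_base(variant)
            if alt is None:
                return ConsequenceCall(
                    variant,
                    "synonymous",
                    protein_change=(codon_i + 1, translate_codon(codon), translate_codon(codon)),
                    transcript_id=tid,
                    note="no comparable outgroup base",
                )
            if transcript.strand == "-":
                alt = alt.translate(_COMPLEMENT)
            alt_codon = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
            ref_aa = translate_codon(codon)
            alt_aa = translate_codon(alt_codon)
            if ref_aa == alt_aa:
                cls = "synonymous"
            elif alt_aa == "*":
                cls = "stop_gained"
            elif ref_aa == "*":
                cls = "stop_lost"
            else:
                cls = "missense"
            return ConsequenceCall(
                variant, cls, protein_change=(codon_i + 1, ref_aa, alt_aa), transcript_id=tid
            )
        if exon_overlap:
            return ConsequenceCall(variant, "utr", transcript_id=tid)
        return ConsequenceCall(variant, "intronic", transcript_id=tid)

    # indels: the length that hits coding sequence decides the frame
    if variant.kind == INSERTION:
        length = cds_overlap
    else:  # deletion: the lost segment has no reference coordinates
        anchor_in_cds = any(
            c.start < iv.end and iv.start < c.end for c in transcript.cds
        )
        length = len(variant.outgroup_alleles[0]) if anchor_in_cds else 0
    if length > 0:
        if length % 3 == 0:
            cls = "inframe_insertion" if variant.kind == INSERTION else "inframe_deletion"
        else:
            cls = "frameshift"
        return ConsequenceCall(variant, cls, transcript_id=tid)
    if exon_overlap:
        return ConsequenceCall(variant, "utr", transcript_id=tid)
    return ConsequenceCall(variant, "intronic", transcript_id=tid)


def is_damaging(
    consequence: str,
    scores: DamagingScores,
    sift_cut: float = 0.05,
    polyphen_cut: float = 0.446,
) -> bool:
    """Retention rule: scored SNVs pass on SIFT/PolyPhen thresholds (strict
    inequalities); protein-altering indels pass regardless of scores."""
    if consequence in ("inframe_insertion", "inframe_deletion", "frameshift"):
        return True
    if consequence in _SNV_CLASSES:
        if scores.sift is not None and scores.sift < sift_cut:
            return True
        if scores.polyphen is not None and scores.polyphen > polyphen_cut:
            return True
    return False


def filter_damaging(
    calls: Sequence[tuple[ConsequenceCall, DamagingScores]],
    sift_cut: float = 0.05,
    polyphen_cut: float = 0.446,
) -> list[tuple[ConsequenceCall, DamagingScores]]:
    return [
        (c, s)
        for c, s in calls
        if is_damaging(c.consequence, s, sift_cut, polyphen_cut)
    ]


TRIAGE_CATEGORIES = (
    "candidate",
    "outgroup_specific",
    "minor_transcript",
    "shared_aa_in_tailed_species",
)


@dataclass(frozen=True)
class ResiduePanel:
    """Residues at the candidate site across species.

    ``outgroups`` maps the two outgroup species to their residue;
    ``tailed`` maps any other tailed species (e.g. mouse) to theirs.
    """

    ingroup: str
    outgroups: Mapping[str, str]
    tailed: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class TriageDecision:
    category: str
    evidence: str

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.category!r}")


def triage(
    call: ConsequenceCall,
    panel: Optional[ResiduePanel] = None,
    on_other_transcripts: Sequence[ConsequenceCall] = (),
) -> TriageDecision:
    """Assign exactly one triage category; rules fire in the listed order.

    1. outgroup_specific — the outgroups disagree and one matches the
       ingroup residue, so the change is on the outgroup branch.
    2. minor_transcript — the protein-level consequence exists only on a
       transcript other than the selected one.
    3. shared_aa_in_tailed_species — at least one tailed species carries the
       ingroup residue, so the residue cannot explain taillessness.
    Otherwise the call remains a candidate.
    """
    if panel is not None and len(panel.outgroups) >= 2:
        outs = list(panel.outgroups.values())
        if len(set(outs)) > 1 and panel.ingroup in outs:
            return TriageDecision(
                "outgroup_specific",
                f"outgroups {outs} disagree; one matches ingroup {panel.ingroup!r}",
            )
    if call.consequence not in PROTEIN_ALTERING and any(
        other.consequence in PROTEIN_ALTERING for other in on_other_transcripts
    ):
        hit = next(
            o for o in on_other_transcripts if o.consequence in PROTEIN_ALTERING
        )
        return TriageDecision(
            "minor_transcript",
            f"protein-altering only on {hit.transcript_id} ({hit.consequence})",
        )
    if panel is not None:
        shared = [sp for sp, res in panel.tailed.items() if res == panel.ingroup]
        if shared:
            return TriageDecision(
                "shared_aa_in_tailed_species",
                f"ingroup residue {panel.ingroup!r} also in tailed {shared}",
            )
    if panel is None:
        return TriageDecision("candidate", "untested")
    return TriageDecision("candidate", "no false-positive rule fired")


# --- transcript and score I/O ------------------------------------------------


def transcripts_from_gff3(path: str) -> dict[str, list[TranscriptModel]]:
    """Load transcript models from GFF3, grouped by gene id."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, list[TranscriptModel]] = {}
    for t in list(db.features_of_type("mRNA")) + list(db.features_of_type("transcript")):
        exons = [
            GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
            for c in db.children(t, featuretype="exon", order_by="start")
        ]
        cds = [
            GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
            for c in db.children(t, featuretype="CDS", order_by="start")
        ]
        gene_id = t.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            parents = list(db.parents(t, featuretype="gene"))
            gene_id = parents[0].id if parents else t.id
        model = TranscriptModel(
            gene_id=gene_id,
            transcript_id=t.id,
            chrom=t.seqid,
            strand=t.strand,
            exons=exons,
            cds=cds,
        )
        out.setdefault(gene_id, []).append(model)
    return out


def read_scores_tsv(path) -> dict[str, DamagingScores]:
    """Score annotations keyed ``CHROM:POS:ALLELE`` (POS 1-based).

    Expected columns: chrom, pos, allele, sift, polyphen (empty = absent).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    out = {}
    for r in df.itertuples(index=False):
        sift = None if pd.isna(r.sift) else float(r.sift)
        polyphen = None if pd.isna(r.polyphen) else float(r.polyphen)
        out[f"{r.chrom}:{int(r.pos)}:{r.allele}"] = DamagingScores(sift, polyphen)
    return out
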