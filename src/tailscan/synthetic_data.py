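"""Seeded generators for every input the analysis consumes.

Each generator emulates the statistical structure the corresponding stage
assumes and returns a ground-truth manifest alongside the data, so every
stage can be tested for exact recovery without any external download:

* :func:`simulate_alignment` — an 8-species alignment block (six-species
  ingroup plus two outgroups) carrying planted ingroup-specific SNVs,
  insertions and deletions over a sampled ancestral sequence, optionally
  with background divergence on the outgroup branches only (the ingroup is
  kept monomorphic so planted features remain the only ingroup-shared
  signal).
* :func:`simulate_locus` — a multi-exon gene with planted inverted intronic
  repeat pairs: the downstream member is written as the reverse complement
  of the upstream member with a requested number of substitutions, at a
  requested inner distance.
* :func:`simulate_cross` — offspring of a Mendelian cross drawn from the
  Punnett proportions with per-genotype penetrance and phenotype-category
  mix.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
per call; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .alignment_io import AlignedRow, AlignmentBlock, SpeciesPartition
from .cross_stats import CATEGORIES, CrossDesign, PhenotypeTable, expected_offspring
from .effect_triage import TranscriptModel
from .intervals import GenomicInterval
from .stempair_scan import RepeatFeature, reverse_complement

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _different_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


# --- alignment simulation ----------------------------------------------------

#: which outgroups carry the divergent state of a planted variant
OUTGROUP_PATTERNS = ("both", "first", "second")


@dataclass(frozen=True)
class PlantedVariant:
    kind: str  # "snv" | "insertion" | "deletion"
    position: int  # reference coordinate (anchor for deletions)
    length: int = 1
    outgroup_pattern: str = "both"

    def __post_init__(self) -> None:
        if self.kind not in ("snv", "insertion", "deletion"):
            raise ValueError(f"unknown planted kind {self.kind!r}")
        if self.outgroup_pattern not in OUTGROUP_PATTERNS:
            raise ValueError(f"unknown outgroup pattern {self.outgroup_pattern!r}")
        if self.length < 1:
            raise ValueError("planted length must be >= 1")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference footprint (half-open); deletions occupy only the anchor."""
        if self.kind == "snv":
            return (self.position, self.position + 1)
        if self.kind == "insertion":
            return (self.position, self.position + self.length)
        return (self.position, self.position)


@dataclass
class AlignmentSimSpec:
    partition: SpeciesPartition = field(default_factory=SpeciesPartition)
    region_length: int = 10_000
    planted: tuple[PlantedVariant, ...] = ()
    background_divergence: float = 0.0
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_divergence < 1.0:
            raise ValueError("background divergence must lie in [0, 1)")
        spans = []
        for v in self.planted:
            lo, hi = v.ref_span
            if lo < 0 or hi > self.region_length or v.position > self.region_length:
                raise ValueError(f"planted variant outside region: {v}")
            # pad by 1 so neighbouring indel runs can never merge
            spans.append((lo - 1, max(hi, lo + 1) + 1, v))
        spans.sort()
        for (a0, a1, va), (b0, b1, vb) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"planted variants overlap: {va} vs {vb}")


def simulate_alignment(
    spec: AlignmentSimSpec,
) -> tuple[list[AlignmentBlock], pd.DataFrame]:
    """One alignment block with planted ingroup-specific variants.

    The truth table has columns kind, chrom, start, end, length,
    outgroup_pattern on reference coordinates (matching the screen's output
    conventions: SNV width 1, insertion width = length, deletion a width-0
    anchor).
    """
    rng = np.random.default_rng(spec.seed)
    part = spec.partition
    species = list(part.ingroup) + list(part.outgroups)
    anc = _random_seq(rng, spec.region_length)
    out_idx = {"first": (0,), "second": (1,), "both": (0, 1)}

    # column list: (ref_coord or None, {species: char})
    columns: list[tuple[Optional[int], dict[str, str]]] = []
    by_pos: dict[int, list[PlantedVariant]] = {}
    for v in spec.planted:
        by_pos.setdefault(v.position, []).append(v)

    planted_cols: set[int] = set()  # column indices owned by planted variants
    for p in range(spec.region_length + 1):
        for v in by_pos.get(p, ()):
            if v.kind == "deletion":
                seg = _random_seq(rng, v.length)
                for k in range(v.length):
                    col = {s: "-" for s in part.ingroup}
                    for o in part.outgroups:
                        col[o] = seg[k]
                    planted_cols.add(len(columns))
                    columns.append((None, col))
        if p == spec.region_length:
            break
        col = {s: anc[p] for s in species}
        for v in by_pos.get(p, ()):
            if v.kind == "snv":
                alt = _different_base(rng, anc[p])
                for oi in out_idx[v.outgroup_pattern]:
                    col[part.outgroups[oi]] = alt
                planted_cols.add(len(columns))
        columns.append((p, col))

    # second pass: insertions blank the outgroup rows over their run
    coord_to_col = {c: i for i, (c, _) in enumerate(columns) if c is not None}
    for v in spec.planted:
        if v.kind != "insertion":
            continue
        for p in range(v.position, v.position + v.length):
            ci = coord_to_col[p]
            planted_cols.add(ci)
            for oi in out_idx[v.outgroup_pattern]:
                columns[ci][1][part.outgroups[oi]] = "-"

    if spec.background_divergence > 0:
        d = spec.background_divergence
        for ci, (coord, col) in enumerate(columns):
            if ci in planted_cols:
                continue
            for o in part.outgroups:
                if col[o] in "ACGT" and rng.random() < d:
                    col[o] = _different_base(rng, col[o])

    rows = []
    for s in species:
        text = "".join(col[s] for _, col in columns)
        size = len(text) - text.count("-")
        rows.append(
            AlignedRow(
                src=f"{s}.{spec.chrom}",
                source_start=0,
                size=size,
                strand="+",
                source_length=size,
                text=text,
            )
        )
    block = AlignmentBlock(tuple(rows), score=0.0)

    truth = pd.DataFrame.from_records(
        [
            {
                "kind": v.kind,
                "chrom": spec.chrom,
                "start": v.ref_span[0],
                "end": v.ref_span[1],
                "length": v.length,
                "outgroup_pattern": v.outgroup_pattern,
            }
            for v in sorted(spec.planted, key=lambda v: (v.position, v.kind))
        ],
        columns=["kind", "chrom", "start", "end", "length", "outgroup_pattern"],
    )
    return [block], truth


def plant_random_variants(
    region_length: int,
    n_snv: int,
    n_insertion: int,
    n_deletion: int,
    seed: int,
    indel_lengths: tuple[int, int] = (1, 8),
    partition: Optional[SpeciesPartition] = None,
    background_divergence: float = 0.0,
) -> AlignmentSimSpec:
    """Place non-overlapping planted variants uniformly at random.

    Variants keep >=2 bp of clearance so independently planted indel runs
    can never merge into a single call.
    """
    rng = np.random.default_rng(seed)
    taken: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        return all(hi + 2 <= a or b + 2 <= lo for a, b in taken)

    planted: list[PlantedVariant] = []
    jobs = (
        [("snv", 1)] * n_snv
        + [("insertion", None)] * n_insertion
        + [("deletion", None)] * n_deletion
    )
    lo_len, hi_len = indel_lengths
    for kind, ln in jobs:
        length = ln if ln else int(rng.integers(lo_len, hi_len + 1))
        for _ in range(10_000):
            pos = int(rng.integers(1, region_length - length - 1))
            span = (pos, pos + (length if kind == "insertion" else 1))
            if kind == "deletion":
                span = (pos, pos + 1)
            if free(*span):
                taken.append(span)
                planted.append(PlantedVariant(kind, pos, length))
                break
        else:
            raise RuntimeError("could not place planted variants; region too dense")
    kw = {} if partition is None else {"partition": partition}
    return AlignmentSimSpec(
        region_length=region_length,
        planted=tuple(planted),
        background_divergence=background_divergence,
        seed=seed,
        **kw,
    )


# --- locus simulation --------------------------------------------------------


@dataclass(frozen=True)
class PlantedPair:
    """An inverted repeat pair to plant around one or more exons.

    Host introns are 1-based transcript-order ordinals (intron i follows
    exon i); the pair traps exons ``intron_up+1 .. intron_down``.
    """

    intron_up: int
    intron_down: int
    repeat_length: int = 297
    substitutions: int = 0
    inner_distance: int = 1_448

    def __post_init__(self) -> None:
        if self.intron_up >= self.intron_down:
            raise ValueError("upstream intron ordinal must precede downstream")
        if not 0 <= self.substitutions <= self.repeat_length:
            raise ValueError("substitutions must lie in [0, repeat length]")


@dataclass
class LocusSimSpec:
    # TBXT-like default: five coding exons, the middle one 117 bp so the
    # single-exon skip is frame-preserving and the two-exon skip is not
    exon_sizes: tuple[int, ...] = (150, 120, 117, 91, 150)
    intron_sizes: tuple[int, ...] = (1_500, 1_200, 1_200, 1_500)
    pairs: tuple[PlantedPair, ...] = (PlantedPair(2, 3),)
    gene_id: str = "geneSim"
    chrom: str = "chrSim"
    strand: str = "+"
    pad: int = 200  # bp of intergenic sequence on each side
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_sizes) != len(self.exon_sizes) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        for p in self.pairs:
            if p.intron_down > len(self.intron_sizes):
                raise ValueError(f"pair {p} references a missing intron")


@dataclass
class SimulatedLocus:
    genome: dict[str, str]
    transcript: TranscriptModel
    repeats: list[RepeatFeature]
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA / GFF3 / BED6 / truth JSON under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        t = self.transcript
        fasta = outdir / "locus.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gff = outdir / "locus.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            span = t.span
            attrs = f"ID={t.gene_id}"
            fh.write(
                f"{t.chrom}\ttailscan\tgene\t{span.start + 1}\t{span.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{t.chrom}\ttailscan\tmRNA\t{span.start + 1}\t{span.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id};gene_id={t.gene_id}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\ttailscan\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f"Parent={t.transcript_id}\n"
                )
            for c in t.cds:
                fh.write(
                    f"{t.chrom}\ttailscan\tCDS\t{c.start + 1}\t{c.end}\t.\t{t.strand}\t0\t"
                    f"Parent={t.transcript_id}\n"
                )
        bed = outdir / "repeats.bed"
        with open(bed, "w") as fh:
            for r in self.repeats:
                iv = r.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.family}\t0\t{iv.strand}\n"
                )
        truth = outdir / "locus_truth.json"
        truth.write_text(json.dumps(self.truth.to_dict(orient="records"), indent=1))
        return {"fasta": fasta, "gff3": gff, "bed": bed, "truth": truth}


def simulate_locus(spec: LocusSimSpec) -> SimulatedLocus:
    """Generate a gene locus with planted inverted repeat pairs.

    The downstream repeat's genomic sequence is the reverse complement of
    the upstream repeat's with ``substitutions`` positions changed, so the
    gapless stem identity is forced to ``repeat_length - substitutions``.
    Placement is deterministic: the downstream member sits as close to its
    intron start as the requested inner distance allows. A pair that cannot
    fit raises ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)

    # build exon/intron coordinates
    exons: list[GenomicInterval] = []
    pos = spec.pad
    introns: list[GenomicInterval] = []
    for i, ex in enumerate(spec.exon_sizes):
        exons.append(GenomicInterval(spec.chrom, pos, pos + ex, spec.strand))
        pos += ex
        if i < len(spec.intron_sizes):
            introns.append(
                GenomicInterval(spec.chrom, pos, pos + spec.intron_sizes[i], spec.strand)
            )
            pos += spec.intron_sizes[i]
    total = pos + spec.pad
    seq = list(_random_seq(rng, total))

    repeats: list[RepeatFeature] = []
    truth_rows = []
    placed: list[tuple[int, int]] = []
    for k, pair in enumerate(spec.pairs, start=1):
        up_intron = introns[pair.intron_up - 1]
        dn_intron = introns[pair.intron_down - 1]
        L, D = pair.repeat_length, pair.inner_distance
        between = dn_intron.start - up_intron.end  # exons + introns in between
        rem = D - between
        if rem < 0:
            raise ValueError(f"pair {k}: inner distance {D} shorter than the "
                             f"intervening {between} bp of exons/introns")
        # a = tail of upstream intron after r1, b = head of downstream intron
        b = max(0, rem - (up_intron.width - L))
        a = rem - b
        if a < 0 or a + L > up_intron.width or b + L > dn_intron.width:
            raise ValueError(f"pair {k}: repeats do not fit their host introns")
        up_start = up_intron.end - a - L
        dn_start = dn_intron.start + b
        for s, e in ((up_start, up_start + L), (dn_start, dn_start + L)):
            if any(s < pe and ps < e for ps, pe in placed):
                raise ValueError(f"pair {k}: planted repeats overlap a previous pair")
            placed.append((s, e))

        up_seq = _random_seq(rng, L)
        dn_seq = list(reverse_complement(up_seq))
        subs = rng.choice(L, size=pair.substitutions, replace=False)
        for si in subs:
            dn_seq[si] = _different_base(rng, dn_seq[si])
        seq[up_start : up_start + L] = up_seq
        seq[dn_start : dn_start + L] = "".join(dn_seq)

        up = RepeatFeature(
            GenomicInterval(spec.chrom, up_start, up_start + L, "+"),
            family=f"SIMREP{k}",
        )
        dn = RepeatFeature(
            GenomicInterval(spec.chrom, dn_start, dn_start + L, "-"),
            family=f"SIMREP{k}",
        )
        repeats.extend([up, dn])
        truth_rows.append(
            {
                "pair": k,
                "up_start": up_start,
                "up_end": up_start + L,
                "dn_start": dn_start,
                "dn_end": dn_start + L,
                "inner_distance": dn_start - (up_start + L),
                "repeat_length": L,
                "substitutions": pair.substitutions,
                "expected_identity": L - pair.substitutions,
                "trapped_exons": list(range(pair.intron_up + 1, pair.intron_down + 1)),
            }
        )

    transcript = TranscriptModel(
        gene_id=spec.gene_id,
        transcript_id=f"{spec.gene_id}.t1",
        chrom=spec.chrom,
        strand=spec.strand,
        exons=exons,
        cds=list(exons),  # fully coding exons; lengths control the frame
    )
    truth = pd.DataFrame.from_records(
        truth_rows,
        columns=[
            "pair", "up_start", "up_end", "dn_start", "dn_end", "inner_distance",
            "repeat_length", "substitutions", "expected_identity", "trapped_exons",
        ],
    )
    return SimulatedLocus(
        genome={spec.chrom: "".join(seq)},
        transcript=transcript,
        repeats=repeats,
        truth=truth,
    )


# --- cross simulation --------------------------------------------------------


@dataclass
class CrossSimSpec:
    design: CrossDesign
    n: int
    penetrance: Mapping[str, float]
    category_mix: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("offspring count must be > 0")
        for g, p in self.penetrance.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance for {g} must lie in [0, 1]")
        for g, mix in self.category_mix.items():
            if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"category mix for {g} must be 3 fractions summing to 1")


def simulate_cross(spec: CrossSimSpec) -> PhenotypeTable:
    """Draw offspring genotypes and phenotypes; affected mice are split over
    no/short/kinked tail by the per-genotype category mix (default all
    no-tail), the rest are long-tailed."""
    rng = np.random.default_rng(spec.seed)
    props = expected_offspring(spec.design)
    genotypes = sorted(props)
    counts = rng.multinomial(spec.n, [props[g] for g in genotypes])
    rows = []
    for g, n_g in zip(genotypes, counts):
        pen = spec.penetrance.get(g, 0.0)
        affected = rng.binomial(n_g, pen) if n_g else 0
        mix = spec.category_mix.get(g, (1.0, 0.0, 0.0))
        split = rng.multinomial(affected, mix) if affected else np.zeros(3, dtype=int)
        rows.append(
            {
                "genotype": g,
                "no_tail": int(split[0]),
                "short_tail": int(split[1]),
                "kinked_tail": int(split[2]),
                "long_tail": int(n_g - affected),
            }
        )
    df = pd.DataFrame.from_records(rows, columns=["genotype", *CATEGORIES])
    return PhenotypeTable(df.set_index("genotype"))
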