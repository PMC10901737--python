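"""Exon-flanking inverted repeat-pair scanning.

Two intronic repeats annotated on opposite strands can base-pair in the
pre-mRNA into a stem whose loop traps the exons lying between them,
conjoining the outer splice sites and promoting exon skipping. The scan
enumerates all such pairs across a transcript's introns, scores each stem by
the sequence identity of the upstream repeat against the reverse complement
of the downstream repeat, measures the inner (gap) distance between the
repeats, and predicts whether skipping the trapped exons preserves the
reading frame.

The ranking score, identity_fraction * exp(-inner_distance / lambda), is a
configurable heuristic: a nascent transcript can fold a short-range stem
during the window in which a long-range one cannot yet exist, so proximal
high-identity pairs are favoured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .effect_triage import TranscriptModel, _fetch
from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat (e.g. RepeatMasker BED6 record)."""

    interval: GenomicInterval
    family: str
    sequence: Optional[str] = None  # forward-strand genomic sequence, if preloaded

    def __post_init__(self) -> None:
        if self.interval.width < 1:
            raise ValueError("repeat interval must have width >= 1")
        if not self.family:
            raise ValueError("repeat family must be non-empty")

    def seq(self, genome=None) -> str:
        if self.sequence is not None:
            return self.sequence
        if genome is None:
            raise ValueError(f"no sequence source for repeat {self.family}")
        return _fetch(genome, self.interval.chrom, self.interval.start, self.interval.end)


@dataclass(frozen=True)
class AlignScores:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass(frozen=True)
class PairScanConfig:
    max_inner_distance: int = 10_000
    min_identity_fraction: float = 0.6
    scores: AlignScores = field(default_factory=AlignScores)
    lam: float = 2_000.0  # distance decay scale, bp

    def __post_init__(self) -> None:
        if self.max_inner_distance <= 0:
            raise ValueError("max_inner_distance must be > 0")
        if not 0.0 <= self.min_identity_fraction <= 1.0:
            raise ValueError("min_identity_fraction must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass(frozen=True)
class InvertedPairCandidate:
    upstream_repeat: RepeatFeature
    downstream_repeat: RepeatFeature
    trapped_exons: tuple[int, ...]  # 1-based transcript-order ordinals
    inner_distance: int
    identity_matches: int
    identity_denominator: int
    frame_preserving: bool
    trapped_noncoding: bool
    score: float

    def __post_init__(self) -> None:
        if not self.trapped_exons:
            raise ValueError("a candidate must trap at least one exon")
        if not 0 <= self.identity_matches <= self.identity_denominator:
            raise ValueError("identity counts out of range")
        if self.inner_distance < 0:
            raise ValueError("inner distance must be >= 0")

    @property
    def identity_fraction(self) -> float:
        return self.identity_matches / self.identity_denominator


def inner_distance(r1: RepeatFeature, r2: RepeatFeature) -> int:
    """Inner gap between an upstream and a downstream repeat: r2.start - r1.end.

    Zero for abutting repeats; overlapping or out-of-order repeats are an
    error.
    """
    d = r2.interval.start - r1.interval.end
    if d < 0:
        raise ValueError(
            f"repeats overlap or are out of order: "
            f"{r1.interval.start}-{r1.interval.end} vs {r2.interval.start}-{r2.interval.end}"
        )
    return d


def pair_identity(
    seq_a: str,
    seq_b: str,
    scores: AlignScores = AlignScores(),
    gapless: bool = False,
) -> tuple[int, int]:
    """Stem identity of two repeats.

    Globally aligns ``seq_a`` against the reverse complement of ``seq_b``
    (Needleman-Wunsch with the configured match/mismatch/gap scores) and
    returns ``(identity_matches, identity_denominator)`` where the match
    count is the maximum number of identical aligned positions achievable by
    any optimal-score alignment, and the denominator is the length of the
    shorter sequence.

    With ``gapless=True`` the sequences must have equal length and the
    identity is the plain position-wise match count against the reverse
    complement — the convention under which a stem with s substituted
    positions scores exactly ``length - s``.
    """
    if not seq_a or not seq_b:
        raise ValueError("pair_identity requires non-empty sequences")
    a = seq_a.upper()
    b = reverse_complement(seq_b.upper())
    if gapless:
        if len(a) != len(b):
            raise ValueError("gapless identity requires equal-length sequences")
        return sum(x == y for x, y in zip(a, b)), len(a)
    m, n = len(a), len(b)
    denom = min(m, n)

    # lexicographic (score, identities) DP packed into one integer:
    # value = score * K + identities, 0 <= identities < K
    K = denom + 1
    gap_step = scores.gap * K
    prev = [j * gap_step for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * gap_step] + [0] * n
        ai = a[i - 1]
        prev_row = prev
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                diag = prev_row[j - 1] + scores.match * K + 1
            else:
                diag = prev_row[j - 1] + scores.mismatch * K
            up = prev_row[j] + gap_step
            left = cur[j - 1] + gap_step
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur[j] = best
        prev = cur
    matches = prev[n] % K
    return matches, denom


def frame_effect(
    trapped_exons: Sequence[int], transcript: TranscriptModel
) -> tuple[str, bool]:
    """Reading-frame consequence of skipping the trapped exons.

    Returns ``(verdict, trapped_noncoding)``: ``in_frame`` iff the summed
    CDS length of the trapped exons is divisible by 3. Exons carrying no CDS
    contribute 0; if the total is 0 the skip removes no coding sequence and
    is in-frame by construction, flagged via the second element.
    """
    total = sum(transcript.exon_cds_length(o) for o in trapped_exons)
    if total == 0:
        return "in_frame", True
    return ("in_frame" if total % 3 == 0 else "frameshift"), False


def _host_intron(
    repeat: RepeatFeature, introns_tx_order: Sequence[GenomicInterval]
) -> Optional[int]:
    """1-based transcript-order ordinal of the intron containing the repeat."""
    for i, intron in enumerate(introns_tx_order, start=1):
        if intron.contains(repeat.interval):
            return i
    return None


def find_inverted_pairs(
    transcript: TranscriptModel,
    repeats: Sequence[RepeatFeature],
    genome=None,
    config: PairScanConfig = PairScanConfig(),
) -> list[InvertedPairCandidate]:
    """All exon-flanking opposite-strand repeat pairs passing the filters.

    A pair (r1 in intron i, r2 in intron j, i < j in transcript order) traps
    exons i+1 .. j. Pairs across non-adjacent introns are allowed, so more
    than one exon may be trapped. Repeats not fully contained in an intron
    are ignored. Transcripts with fewer than 3 exons yield no candidates.
    """
    if transcript.exon_count < 3:
        return []
    introns_genomic = transcript.introns()
    introns_tx = (
        introns_genomic if transcript.strand == "+" else list(reversed(introns_genomic))
    )
    hosted: list[tuple[int, RepeatFeature]] = []
    for r in repeats:
        if r.interval.chrom != transcript.chrom:
            raise ValueError("repeat and transcript on different chromosomes")
        i = _host_intron(r, introns_tx)
        if i is not None:
            hosted.append((i, r))

    out: list[InvertedPairCandidate] = []
    for i, r1 in hosted:
        for j, r2 in hosted:
            if j <= i:  # need r1's intron strictly 5' of r2's
                continue
            if r1.interval.strand == r2.interval.strand:
                continue
            first, second = (
                (r1, r2)
                if r1.interval.start <= r2.interval.start
                else (r2, r1)
            )
            d = inner_distance(first, second)
            if d > config.max_inner_distance:
                continue
            matches, denom = pair_identity(
                first.seq(genome), second.seq(genome), config.scores
            )
            if matches / denom < config.min_identity_fraction:
                continue
            trapped = tuple(range(i + 1, j + 1))
            verdict, noncoding = frame_effect(trapped, transcript)
            out.append(
                InvertedPairCandidate(
                    upstream_repeat=r1,
                    downstream_repeat=r2,
                    trapped_exons=trapped,
                    inner_distance=d,
                    identity_matches=matches,
                    identity_denominator=denom,
                    frame_preserving=verdict == "in_frame",
                    trapped_noncoding=noncoding,
                    score=candidate_score(matches / denom, d, config.lam),
                )
            )
    return out


def candidate_score(identity_fraction: float, distance: int, lam: float) -> float:
    return identity_fraction * math.exp(-distance / lam)


def rank_candidates(
    candidates: Sequence[InvertedPairCandidate],
    config: PairScanConfig = PairScanConfig(),
) -> list[InvertedPairCandidate]:
    """Descending score; ties by smaller inner distance, then genomic position."""
    return sorted(
        candidates,
        key=lambda c: (
            -c.score,
            c.inner_distance,
            c.upstream_repeat.interval.start,
            c.downstream_repeat.interval.start,
        ),
    )


def candidates_to_frame(
    candidates: Sequence[InvertedPairCandidate], transcript_id: str = ""
) -> pd.DataFrame:
    cols = [
        "transcript_id", "up_chrom", "up_start", "up_end", "up_family", "up_strand",
        "dn_start", "dn_end", "dn_family", "dn_strand", "trapped_exons",
        "inner_distance", "identity_matches", "identity_denominator",
        "identity_fraction", "frame", "score",
    ]
    records = [
        {
            "transcript_id": transcript_id,
            "up_chrom": c.upstream_repeat.interval.chrom,
            "up_start": c.upstream_repeat.interval.start,
            "up_end": c.upstream_repeat.interval.end,
            "up_family": c.upstream_repeat.family,
            "up_strand": c.upstream_repeat.interval.strand,
            "dn_start": c.downstream_repeat.interval.start,
            "dn_end": c.downstream_repeat.interval.end,
            "dn_family": c.downstream_repeat.family,
            "dn_strand": c.downstream_repeat.interval.strand,
            "trapped_exons": ",".join(map(str, c.trapped_exons)),
            "inner_distance": c.inner_distance,
            "identity_matches": c.identity_matches,
            "identity_denominator": c.identity_denominator,
            "identity_fraction": round(c.identity_fraction, 6),
            "frame": "in_frame" if c.frame_preserving else "frameshift",
            "score": round(c.score, 6),
        }
        for c in candidates
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def read_repeats_bed(path) -> list[RepeatFeature]:
    """RepeatMasker-style BED6: name = repeat family, strand column used."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        RepeatFeature(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
            family=r.name,
        )
        for r in df.itertuples(index=False)
    ]
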