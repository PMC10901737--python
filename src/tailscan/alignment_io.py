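"""Multi-species alignment blocks: MAF I/O, slicing, and ingroup consensus.

A MAF file is a series of blocks; each block holds one gapped row per
assembly with that row's source coordinates (start, non-gap size, strand,
source length). Rows are stored exactly as they appear in the file —
negative-strand rows are already reverse-complemented by the aligner — and
all derived coordinates are reported on the reference assembly's forward
strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO, Union

from .intervals import GenomicInterval

GAP = "-"
NO_CALL = "N"

#: The six tailless ape assemblies used as the default ingroup.
HOMINOIDS = ("hg38", "gorGor5", "panTro5", "panPan2", "ponAbe2", "nomLeu3")
#: Default tailed outgroups: pig-tailed macaque and marmoset.
OUTGROUPS = ("macNem1", "calJac3")


class MafFormatError(ValueError):
    """Raised on malformed MAF input or invariant-violating blocks."""


@dataclass(frozen=True)
class AlignedRow:
    """One gapped row of an alignment block.

    ``src`` is the MAF source name (``assembly.chrom``); the assembly prefix
    is the species identifier. ``source_start`` counts forward-strand bases
    for ``+`` rows and reverse-strand offsets for ``-`` rows, as in MAF.
    """

    src: str
    source_start: int
    size: int
    strand: str
    source_length: int
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise MafFormatError("row text must be non-empty")
        non_gap = len(self.text) - self.text.count(GAP)
        if non_gap != self.size:
            raise MafFormatError(
                f"row {self.src}: size {self.size} != non-gap count {non_gap}"
            )
        if self.strand not in ("+", "-"):
            raise MafFormatError(f"row {self.src}: bad strand {self.strand!r}")

    @property
    def species_id(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]


@dataclass(frozen=True)
class AlignmentBlock:
    """An ordered set of equal-width aligned rows, at most one per species."""

    rows: tuple[AlignedRow, ...]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise MafFormatError(f"row widths disagree: {sorted(widths)}")
        seen: set[str] = set()
        for r in self.rows:
            if r.species_id in seen:
                raise MafFormatError(f"duplicate species in block: {r.species_id}")
            seen.add(r.species_id)

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(r.species_id for r in self.rows)

    def row(self, species_id: str) -> AlignedRow:
        for r in self.rows:
            if r.species_id == species_id:
                return r
        raise KeyError(f"species {species_id!r} not in block")

    def has(self, species_id: str) -> bool:
        return any(r.species_id == species_id for r in self.rows)

    def column(self, index: int) -> dict[str, str]:
        """Map species -> character at the given alignment column."""
        return {r.species_id: r.text[index] for r in self.rows}


@dataclass(frozen=True)
class SpeciesPartition:
    """Ingroup/outgroup split with a designated reference assembly."""

    ingroup: tuple[str, ...] = HOMINOIDS
    outgroups: tuple[str, ...] = OUTGROUPS
    reference: str = HOMINOIDS[0]

    def __post_init__(self) -> None:
        if set(self.ingroup) & set(self.outgroups):
            raise ValueError("ingroup and outgroups must be disjoint")
        if self.reference not in self.ingroup:
            raise ValueError("reference must be an ingroup member")
        if len(self.outgroups) < 1:
            raise ValueError("at least one outgroup is required")


def read_maf(stream: Union[TextIO, str]) -> list[AlignmentBlock]:
    """Parse MAF text (UCSC dialect) into alignment blocks.

    Raises :class:`MafFormatError` naming the offending line number on
    malformed input.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    blocks: list[AlignmentBlock] = []
    rows: list[AlignedRow] = []
    score: Optional[float] = None
    in_block = False

    def flush(lineno: int) -> None:
        nonlocal rows, score, in_block
        if in_block:
            try:
                blocks.append(AlignmentBlock(tuple(rows), score=score))
            except MafFormatError as exc:
                raise MafFormatError(f"block ending at line {lineno}: {exc}") from exc
        rows, score, in_block = [], None, False

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            continue
        fields = line.split()
        tag = fields[0]
        if tag == "a":
            flush(lineno)
            in_block = True
            for f in fields[1:]:
                if f.startswith("score="):
                    try:
                        score = float(f[len("score=") :])
                    except ValueError as exc:
                        raise MafFormatError(
                            f"line {lineno}: bad score field {f!r}"
                        ) from exc
        elif tag == "s":
            if not in_block:
                raise MafFormatError(f"line {lineno}: 's' line outside a block")
            if len(fields) != 7:
                raise MafFormatError(
                    f"line {lineno}: expected 7 fields on 's' line, got {len(fields)}"
                )
            try:
                row = AlignedRow(
                    src=fields[1],
                    source_start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    source_length=int(fields[5]),
                    text=fields[6].upper(),
                )
            except (ValueError, MafFormatError) as exc:
                raise MafFormatError(f"line {lineno}: {exc}") from exc
            rows.append(row)
        elif tag in ("i", "e", "q", "track"):
            continue  # annotation lines carry no alignment content
        else:
            raise MafFormatError(f"line {lineno}: unrecognized line type {tag!r}")
    flush(lineno + 1)
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], stream: TextIO) -> None:
    """Write blocks as MAF; output round-trips through :func:`read_maf`."""
    stream.write("##maf version=1\n")
    for block in blocks:
        if block.width == 0:
            raise MafFormatError("refusing to write an empty block")
        score = block.score if block.score is not None else 0.0
        stream.write(f"a score={score:.6f}\n")
        src_w = max(len(r.src) for r in block.rows)
        start_w = max(len(str(r.source_start)) for r in block.rows)
        size_w = max(len(str(r.size)) for r in block.rows)
        len_w = max(len(str(r.source_length)) for r in block.rows)
        for r in block.rows:
            stream.write(
                f"s {r.src:<{src_w}} {r.source_start:>{start_w}} "
                f"{r.size:>{size_w}} {r.strand} {r.source_length:>{len_w}} {r.text}\n"
            )
        stream.write("\n")


def maf_to_string(blocks: Iterable[AlignmentBlock]) -> str:
    buf = io.StringIO()
    write_maf(blocks, buf)
    return buf.getvalue()


def ref_positions(
    block: AlignmentBlock, reference: str
) -> list[Optional[int]]:
    """Per-column reference coordinate, or ``None`` where the reference is gapped.

    Non-gap columns map to ``source_start + (number of prior non-gap
    characters)`` in the reference row.
    """
    row = block.row(reference)  # KeyError if absent
    out: list[Optional[int]] = []
    pos = row.source_start
    for ch in row.text:
        if ch == GAP:
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out


def slice_block(
    block: AlignmentBlock, interval: GenomicInterval, reference: str
) -> AlignmentBlock:
    """Extract the sub-block over reference coordinates ``[start, end)``.

    Columns where the reference row is gapped are kept only when they lie
    between two retained reference positions. Every row's ``source_start``
    and ``size`` are recomputed. A disjoint interval yields an empty block
    (zero rows).
    """
    ref_row = block.row(reference)
    if interval.chrom not in (ref_row.chrom, ref_row.src):
        return AlignmentBlock(())
    coords = ref_positions(block, reference)
    hit = [
        i
        for i, c in enumerate(coords)
        if c is not None and interval.start <= c < interval.end
    ]
    if not hit:
        return AlignmentBlock(())
    lo, hi = hit[0], hit[-1]  # interior reference gaps are retained
    keep = range(lo, hi + 1)
    new_rows = []
    for r in block.rows:
        prior = sum(1 for ch in r.text[:lo] if ch != GAP)
        text = "".join(r.text[i] for i in keep)
        size = len(text) - text.count(GAP)
        if size == 0:
            continue  # row has no sequence in the slice
        new_rows.append(
            replace(r, source_start=r.source_start + prior, size=size, text=text)
        )
    return AlignmentBlock(tuple(new_rows), score=block.score)


def hominoid_consensus(
    block: AlignmentBlock,
    partition: SpeciesPartition,
    mode: str = "unanimity",
) -> str:
    """Per-column ingroup consensus across the block.

    In the default unanimity mode a column yields the shared character
    (a base, or ``-`` when the whole ingroup is gapped) only when every
    ingroup species is present in the block and all agree; any absence,
    N, or disagreement yields the no-call symbol ``N``. A majority mode
    (plurality among present ingroup rows, ties -> N) is available but is
    not used by the variant-calling rules.
    """
    if mode not in ("unanimity", "majority"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    present = [s for s in partition.ingroup if block.has(s)]
    complete = len(present) == len(partition.ingroup)
    texts = [block.row(s).text for s in present]
    out = []
    for i in range(block.width):
        chars = [t[i] for t in texts]
        if mode == "unanimity":
            if complete and chars and all(c == chars[0] for c in chars) and chars[0] != NO_CALL:
                out.append(chars[0])
            else:
                out.append(NO_CALL)
        else:
            counts: dict[str, int] = {}
            for c in chars:
                if c != NO_CALL:
                    counts[c] = counts.get(c, 0) + 1
            if not counts:
                out.append(NO_CALL)
            else:
                best = max(counts.values())
                top = [c for c, n in counts.items() if n == best]
                out.append(top[0] if len(top) == 1 else NO_CALL)
    return "".join(out)
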