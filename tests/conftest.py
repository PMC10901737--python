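import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tailscan.alignment_io import AlignedRow, AlignmentBlock, SpeciesPartition
from tailscan.effect_triage import TranscriptModel
from tailscan.intervals import GenomicInterval

# compact 8-species panel mirroring the default partition
SPECIES = list(SpeciesPartition().ingroup) + list(SpeciesPartition().outgroups)


def make_block(texts: dict[str, str], start: int = 0, chrom: str = "chr1") -> AlignmentBlock:
    """Build a block from per-species gapped strings (equal width)."""
    rows = []
    for sp, text in texts.items():
        size = len(text) - text.count("-")
        rows.append(
            AlignedRow(
                src=f"{sp}.{chrom}",
                source_start=start,
                size=size,
                strand="+",
                source_length=start + size + 100,
                text=text,
            )
        )
    return AlignmentBlock(tuple(rows))


def uniform_block(seq: str, species=SPECIES, start: int = 0) -> AlignmentBlock:
    return make_block({sp: seq for sp in species}, start=start)


@pytest.fixture
def partition() -> SpeciesPartition:
    return SpeciesPartition()


@pytest.fixture
def toy_locus():
    """Deterministic 3-exon plus-strand gene with a fully coding 90-bp CDS.

    Layout: 50 bp pad | exon1 30 | intron1 120 | exon2 30 | intron2 120 |
    exon3 30 | pad. The first codon of exon2 is forced to AAA so the
    documented Lys->Arg example has a home.
    """
    rng = np.random.default_rng(42)
    length = 50 + 30 + 120 + 30 + 120 + 30 + 50
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    exon_ivs = [
        GenomicInterval("chrT", 50, 80),
        GenomicInterval("chrT", 200, 230),
        GenomicInterval("chrT", 350, 380),
    ]
    seq[200:203] = "AAA"
    genome = {"chrT": "".join(seq)}
    transcript = TranscriptModel(
        gene_id="toy",
        transcript_id="toy.t1",
        chrom="chrT",
        strand="+",
        exons=exon_ivs,
        cds=list(exon_ivs),
    )
    return genome, transcript
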