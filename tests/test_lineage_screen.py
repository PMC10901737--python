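import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailscan.alignment_io import SpeciesPartition
from tailscan.intervals import GenomicInterval
from tailscan.lineage_screen import (
    DELETION,
    INSERTION,
    SNV,
    VariantCallConfig,
    call_indels,
    call_snvs,
    classify_column,
    read_variants,
    screen_genes,
    variants_to_frame,
    write_variants,
)
from tailscan.synthetic_data import (
    AlignmentSimSpec,
    PlantedVariant,
    plant_random_variants,
    simulate_alignment,
)

from conftest import SPECIES, make_block, uniform_block

PART = SpeciesPartition()
CFG = VariantCallConfig()
ING = PART.ingroup
OUT = PART.outgroups


def col(ingroup_char, out1, out2):
    c = {sp: ingroup_char for sp in ING}
    c[OUT[0]], c[OUT[1]] = out1, out2
    return c


def oracle_verdict(column, partition, config):
    """Independent restatement of the calling rules for cross-checking."""
    def norm(c):
        return "X" if c is None or c == "N" else c

    ing = [norm(column.get(s)) for s in partition.ingroup]
    out = [norm(column.get(s)) for s in partition.outgroups]
    if "X" in out:
        return "none"
    if config.require_complete_ingroup and "X" in ing:
        return "none"
    states = set(ing)
    if states <= set("ACGT") and len(states) == 1:
        b = ing[0]
        gapped = [o == "-" for o in out]
        need_ins = any if config.ins_outgroup_rule == "any-absent" else all
        if need_ins(gapped):
            return "ins_site"
        if all(o in "ACGT" for o in out):
            diffs = [o != b for o in out]
            need_snv = any if config.snv_outgroup_rule == "any-differs" else all
            if need_snv(diffs):
                return "snv"
        return "none"
    if states == {"-"} and all(o in "ACGT" for o in out):
        return "del_site"
    return "none"


class TestClassifyColumn:
    def test_fully_conserved_column(self):
        assert classify_column(col("A", "A", "A"), PART, CFG).kind == "none"

    def test_shared_ingroup_base_differing_in_both_outgroups(self):
        v = classify_column(col("A", "G", "G"), PART, CFG)
        assert v.kind == "snv" and v.ingroup_allele == "A"
        assert not v.ambiguous

    def test_single_differing_outgroup_is_called_but_ambiguous(self):
        v = classify_column(col("A", "A", "G"), PART, CFG)
        assert v.kind == "snv" and v.ambiguous

    def test_single_differing_outgroup_fails_both_differ_rule(self):
        cfg = VariantCallConfig(snv_outgroup_rule="both-differ")
        assert classify_column(col("A", "A", "G"), PART, cfg).kind == "none"

    def test_ingroup_gap_with_both_outgroups_present_is_deletion_site(self):
        v = classify_column(col("-", "C", "C"), PART, CFG)
        assert v.kind == "del_site"

    def test_ingroup_bases_with_one_outgroup_gap_is_insertion_site(self):
        v = classify_column(col("A", "-", "A"), PART, CFG)
        assert v.kind == "ins_site" and v.ambiguous
        cfg = VariantCallConfig(ins_outgroup_rule="both-absent")
        assert classify_column(col("A", "-", "A"), PART, cfg).kind == "none"

    def test_n_in_decisive_species_blocks_calls(self):
        assert classify_column(col("A", "N", "G"), PART, CFG).kind == "none"
        c = col("A", "G", "G")
        c[ING[2]] = "N"
        assert classify_column(c, PART, CFG).kind == "none"

    def test_split_ingroup_is_never_called(self):
        c = col("A", "G", "G")
        c[ING[1]] = "C"
        assert classify_column(c, PART, CFG).kind == "none"

    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_ambiguity_flag_tracks_outgroup_support(self, data):
        chars = "ACGT-N"
        c = {sp: data.draw(st.sampled_from(chars)) for sp in SPECIES}
        v = classify_column(c, PART, CFG)
        if v.kind != "none":
            assert v.ambiguous == (len(set(v.outgroup_support)) > 1)


def test_classify_column_matches_oracle_on_random_columns():
    rng = np.random.default_rng(1234)
    chars = np.array(list("ACGT-N"))
    weights = [0.28, 0.28, 0.2, 0.12, 0.08, 0.04]
    configs = [
        VariantCallConfig(),
        VariantCallConfig(snv_outgroup_rule="both-differ", ins_outgroup_rule="both-absent"),
        VariantCallConfig(require_complete_ingroup=False),
    ]
    verdict_map = {"snv": "snv", "ins_site": "ins_site", "del_site": "del_site", "none": "none"}
    for _ in range(4000):
        # bias towards near-uniform ingroup columns so non-none verdicts occur
        base = rng.choice(chars, p=weights)
        c = {}
        for sp in SPECIES:
            c[sp] = base if rng.random() < 0.8 else rng.choice(chars, p=weights)
        cfg = configs[rng.integers(len(configs))]
        got = classify_column(c, PART, cfg)
        assert verdict_map[got.kind] == oracle_verdict(c, PART, cfg)


class TestCallSnvs:
    def test_conserved_block_has_no_calls(self):
        assert call_snvs(uniform_block("ACGTACGT"), PART, CFG) == []

    def test_planted_divergent_column(self):
        texts = {sp: "ACGTACGT" for sp in SPECIES}
        for o in OUT:
            texts[o] = "ACGAACGT"  # column 3 differs
        b = make_block(texts, start=100)
        calls = call_snvs(b, PART, CFG)
        assert len(calls) == 1
        v = calls[0]
        assert v.ref_interval.start == 103 and v.ingroup_allele == "T"
        assert v.outgroup_alleles == ("A", "A") and not v.ambiguous_outgroup

    def test_reference_gap_columns_never_yield_snvs(self):
        texts = {sp: "A-G" for sp in SPECIES}
        texts[OUT[0]] = "ATG"
        texts[OUT[1]] = "ATG"
        # middle column: ingroup gapped -> deletion territory, not SNV
        assert call_snvs(make_block(texts), PART, CFG) == []

    def test_matches_per_column_oracle_on_random_block(self):
        rng = np.random.default_rng(7)
        width = 500
        texts = {}
        anc = rng.choice(list("ACGT"), size=width)
        for sp in SPECIES:
            muts = rng.random(width) < (0.15 if sp in OUT else 0.02)
            chars = ["ACGT-N"[rng.integers(6)] if m else a for a, m in zip(anc, muts)]
            texts[sp] = "".join(chars)
        # keep the reference ungapped so every column has a coordinate
        texts["hg38"] = "".join(anc)
        b = make_block(texts)
        got = {(v.ref_interval.start, v.ingroup_allele) for v in call_snvs(b, PART, CFG)}
        expect = set()
        for i in range(width):
            c = b.column(i)
            if oracle_verdict(c, PART, CFG) == "snv":
                expect.add((i, c["hg38"]))
        assert got == expect


class TestCallIndels:
    def test_insertion_run_merges(self):
        texts = {sp: "GACGTG" for sp in SPECIES}
        for o in OUT:
            texts[o] = "G---TG"
        calls = call_indels(make_block(texts, start=10), PART, CFG)
        assert len(calls) == 1
        v = calls[0]
        assert v.kind == INSERTION
        assert (v.ref_interval.start, v.ref_interval.end) == (11, 14)
        assert v.ingroup_allele == "ACG"
        assert v.outgroup_alleles == ("---", "---")

    def test_deletion_run_merges_with_zero_width_anchor(self):
        texts = {sp: "G--T" for sp in SPECIES}
        for o in OUT:
            texts[o] = "GCAT"
        calls = call_indels(make_block(texts, start=10), PART, CFG)
        assert len(calls) == 1
        v = calls[0]
        assert v.kind == DELETION
        assert v.ref_interval.start == v.ref_interval.end == 11
        assert v.ingroup_allele == ""
        assert v.outgroup_alleles == ("CA", "CA")

    def test_outgroup_pattern_change_breaks_insertion_runs(self):
        texts = {sp: "AACCA" for sp in SPECIES}
        texts[OUT[0]] = "A--CA"
        texts[OUT[1]] = "A-C-A"  # absence pattern flips mid-run
        calls = call_indels(make_block(texts), PART, CFG)
        kinds = [(v.ref_interval.start, v.ref_interval.end) for v in calls]
        assert len(calls) >= 2 and kinds == sorted(kinds)
        patterns = {v.outgroup_support for v in calls}
        assert len(patterns) == len(calls)

    def test_min_indel_length_drops_short_runs(self):
        texts = {sp: "GACGTG" for sp in SPECIES}
        for o in OUT:
            texts[o] = "G---TG"
        cfg = VariantCallConfig(min_indel_length=4)
        assert call_indels(make_block(texts), PART, cfg) == []

    def test_matches_run_length_oracle_on_random_gap_patterns(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            width = 60
            anc = rng.choice(list("ACGT"), size=width)
            texts = {sp: "".join(anc) for sp in ING}
            for o in OUT:
                gaps = rng.random(width) < 0.25
                texts[o] = "".join("-" if g else a for a, g in zip(anc, gaps))
            b = make_block(texts)
            got = [
                (v.kind, v.ref_interval.start, v.ref_interval.end, v.outgroup_support)
                for v in call_indels(b, PART, CFG)
            ]
            # oracle: group consecutive ins_site verdicts by support pattern
            expect = []
            verdicts = [classify_column(b.column(i), PART, CFG) for i in range(width)]
            keyed = [
                (v.kind, v.outgroup_support) if v.kind == "ins_site" else None
                for v in verdicts
            ]
            i = 0
            for key, grp in itertools.groupby(range(width), key=lambda i: keyed[i]):
                idx = list(grp)
                if key is not None:
                    expect.append((INSERTION, idx[0], idx[-1] + 1, key[1]))
            assert got == expect

    def test_calls_invariant_under_block_subdivision(self):
        spec = plant_random_variants(2000, 8, 4, 4, seed=11)
        blocks, _ = simulate_alignment(spec)
        whole = blocks[0]
        from tailscan.alignment_io import slice_block

        mid = 1000
        # avoid splitting through a planted footprint
        while any(lo <= mid <= hi for lo, hi in
                  ((v.ref_span[0] - 1, v.ref_span[1] + 1) for v in spec.planted)):
            mid += 1
        left = slice_block(whole, GenomicInterval(ref_chrom(whole), 0, mid), "hg38")
        right = slice_block(whole, GenomicInterval(ref_chrom(whole), mid, 2000), "hg38")

        def key(v):
            return (v.kind, v.ref_interval.start, v.ref_interval.end, v.ingroup_allele)

        combined = sorted(
            key(v)
            for part in (left, right)
            for v in call_snvs(part, PART, CFG) + call_indels(part, PART, CFG)
        )
        full = sorted(
            key(v) for v in call_snvs(whole, PART, CFG) + call_indels(whole, PART, CFG)
        )
        assert combined == full


def ref_chrom(block):
    return block.row("hg38").chrom


class TestScreenGenes:
    def test_zero_variation_region(self):
        b = uniform_block("ACGT" * 50)
        genes = [("g", GenomicInterval("chr1", 50, 100))]
        _, summary = screen_genes([b], genes, PART, VariantCallConfig(flank_bp=10))
        assert (summary.n_snv, summary.n_insertion, summary.n_deletion) == (0, 0, 0)

    def test_planted_counts_recovered(self):
        planted = tuple(
            [PlantedVariant("snv", p) for p in (100, 300, 500, 700, 900)]
            + [PlantedVariant("insertion", 1200, 4), PlantedVariant("insertion", 1500, 2)]
            + [PlantedVariant("deletion", 1800, 3)]
        )
        spec = AlignmentSimSpec(region_length=2500, planted=planted, seed=2)
        blocks, _ = simulate_alignment(spec)
        genes = [("g", GenomicInterval("chrSim", 0, 2500))]
        _, summary = screen_genes(blocks, genes, PART, VariantCallConfig(flank_bp=0))
        assert (summary.n_snv, summary.n_insertion, summary.n_deletion) == (5, 2, 1)

    def test_overlapping_gene_regions_deduplicate_globally(self):
        spec = AlignmentSimSpec(
            region_length=1000, planted=(PlantedVariant("snv", 500),), seed=3
        )
        blocks, _ = simulate_alignment(spec)
        genes = [
            ("a", GenomicInterval("chrSim", 400, 600)),
            ("b", GenomicInterval("chrSim", 450, 650)),
        ]
        table, summary = screen_genes(blocks, genes, PART, VariantCallConfig(flank_bp=50))
        assert summary.n_snv == 1  # counted once globally
        assert set(table["gene_id"]) == {"a", "b"}  # once per gene
        assert summary.per_gene["n_snv"].tolist() == [1, 1]


class TestVariantTableIO:
    def test_empty_table_writes_header_only(self):
        buf = io.StringIO()
        write_variants(variants_to_frame([]), buf)
        assert buf.getvalue().strip().split("\t")[0] == "CHROM"

    def test_pos_is_one_based(self):
        spec = AlignmentSimSpec(
            region_length=200, planted=(PlantedVariant("snv", 99),), seed=4
        )
        blocks, _ = simulate_alignment(spec)
        calls = call_snvs(blocks[0], PART, CFG)
        buf = io.StringIO()
        write_variants(variants_to_frame(calls), buf)
        df = pd.read_csv(io.StringIO(buf.getvalue()), sep="\t")
        assert df["POS"].tolist() == [100]

    def test_round_trip(self):
        spec = plant_random_variants(3000, 10, 5, 5, seed=5)
        blocks, _ = simulate_alignment(spec)
        calls = call_snvs(blocks[0], PART, CFG) + call_indels(blocks[0], PART, CFG)
        table = variants_to_frame(calls)
        buf = io.StringIO()
        write_variants(table, buf)
        back = read_variants(io.StringIO(buf.getvalue()))
        orig = (
            table[["chrom", "start", "end", "kind", "ingroup_allele"]]
            .sort_values(["start", "kind"])
            .reset_index(drop=True)
        )
        got = (
            back[["chrom", "start", "end", "kind", "ingroup_allele"]]
            .sort_values(["start", "kind"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, orig)
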