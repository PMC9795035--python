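"""In-silico digestion: oracle equivalence, partition property, lookups."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbidnet import (
    EnzymeSpec,
    HINDIII,
    SimulationConfig,
    build_fragment_index,
    digest_sequence,
    generate_genome,
    locate_fragment,
)
from comorbidnet.genome_digest import FragmentIndex, read_fragment_bed, write_fragment_bed


def naive_digest(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, int]]:
    """Independent character-scan oracle for fragment boundaries."""
    site = enzyme.recognition_site
    seq = sequence.upper()
    cuts = []
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            cut = i + enzyme.cut_offset
            if 0 < cut < len(seq):
                cuts.append(cut)
    bounds = [0] + sorted(set(cuts)) + [len(seq)]
    return list(zip(bounds, bounds[1:]))


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("GGAAGCTTGG", [(0, 3), (3, 10)]),
        ("AAAA", [(0, 4)]),
        ("AAGCTTAAGCTT", [(0, 1), (1, 7), (7, 12)]),
        ("ggaagcttgg", [(0, 3), (3, 10)]),  # soft-masked lowercase still matches
        ("AANCTT", [(0, 6)]),  # N never matches the site
    ],
)
def test_digest_examples(sequence, expected):
    assert digest_sequence(sequence, HINDIII) == expected


def test_digest_rejects_empty_sequence():
    with pytest.raises(ValueError):
        digest_sequence("", HINDIII)


def test_enzyme_spec_validation():
    with pytest.raises(ValueError):
        EnzymeSpec("AAGCTT", cut_offset=7)
    with pytest.raises(ValueError):
        EnzymeSpec("AXGCTT")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACGTN", min_size=1, max_size=2000),
    inject=st.lists(st.integers(min_value=0, max_value=1999), max_size=5),
    cut_offset=st.integers(min_value=0, max_value=6),
)
def test_digest_matches_naive_scan_and_partitions(seq, inject, cut_offset):
    # inject recognition sites so matches are not vanishingly rare
    arr = list(seq)
    for pos in inject:
        if pos + 6 <= len(arr):
            arr[pos : pos + 6] = "AAGCTT"
    seq = "".join(arr)
    enzyme = EnzymeSpec("AAGCTT", cut_offset)
    frags = digest_sequence(seq, enzyme)
    assert frags == naive_digest(seq, enzyme)
    # partition: half-open intervals tile [0, len) with no gaps or overlaps
    assert frags[0][0] == 0 and frags[-1][1] == len(seq)
    for (s1, e1), (s2, e2) in zip(frags, frags[1:]):
        assert e1 == s2 and s1 < e1
    assert frags[-1][0] < frags[-1][1]


def test_build_index_counts_and_invalid_input():
    index = build_fragment_index({"chr1": "A" * 10, "chr2": "C" * 10})
    assert index.n_fragments() == 2
    index = build_fragment_index({"chr1": "GGAAGCTTGG"})
    assert index.n_fragments("chr1") == 2
    with pytest.raises(ValueError):
        FragmentIndex({"chr1": []})  # a chromosome must carry fragments
    with pytest.raises(ValueError):
        FragmentIndex({"chr1": [(0, 3), (4, 10)]})  # gap breaks the tiling


def test_fragment_count_equals_site_count_oracle(default_dataset):
    """On a synthetic genome, fragments = site occurrences + chromosomes."""
    total_sites = sum(
        len(re.findall("(?=AAGCTT)", seq)) for seq in default_dataset.genome.values()
    )
    assert default_dataset.index.n_fragments() == total_sites + len(default_dataset.genome)
    assert default_dataset.index.total_span() == sum(
        len(s) for s in default_dataset.genome.values()
    )


def test_locate_fragment_boundaries():
    index = build_fragment_index({"chr1": "GGAAGCTTGG"})  # fragments (0,3),(3,10)
    assert locate_fragment(index, "chr1", 3) == 1  # half-open boundary
    assert locate_fragment(index, "chr1", 2) == 0
    with pytest.raises(IndexError):
        locate_fragment(index, "chr1", 10)
    with pytest.raises(KeyError):
        locate_fragment(index, "chrX", 0)


def test_locate_is_consistent_with_fragment_intervals(default_dataset):
    index = default_dataset.index
    rng = np.random.default_rng(0)
    for chrom in index.chroms:
        for pos in rng.integers(0, index.chrom_length(chrom), size=50):
            frag = index.fragment(chrom, index.locate(chrom, int(pos)))
            assert frag.start <= pos < frag.end


def test_bed_round_trip(tmp_path):
    index = build_fragment_index({"chr1": "GGAAGCTTGG", "chr2": "AAAA"})
    path = tmp_path / "frags.bed"
    write_fragment_bed(index, path)
    loaded = read_fragment_bed(path)
    assert [
        (f.chrom, f.start, f.end, f.frag_id) for f in loaded
    ] == [(f.chrom, f.start, f.end, f.frag_id) for f in index]


def test_fasta_digest_matches_in_memory(tmp_path):
    from comorbidnet.synthetic import write_fasta

    genome, _ = generate_genome(SimulationConfig(rng_seed=1, chrom_length_bp=50_000, n_genes=4))
    fasta = tmp_path / "g.fa"
    write_fasta(genome, fasta)
    from_file = build_fragment_index(fasta)
    in_memory = build_fragment_index(genome)
    assert from_file.n_fragments() == in_memory.n_fragments()
    assert [f.start for f in from_file] == [f.start for f in in_memory]
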