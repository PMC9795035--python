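"""In-silico restriction digestion and position -> fragment lookup.

Hi-C libraries are built on a restriction digest of the genome (HindIII,
A^AGCTT, by default), so every genomic position must be resolvable to the
restriction fragment that carries it.  This module digests chromosome
sequences at every occurrence of the enzyme's recognition site and builds a
:class:`FragmentIndex` supporting O(log F) position lookup via binary search.

Coordinates are 0-based half-open throughout.  Recognition-site matching is
exact and case-insensitive; sites containing ``N`` never match, and runs of
``N`` in the genome are tiled like ordinary sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "EnzymeSpec",
    "RestrictionFragment",
    "FragmentIndex",
    "HINDIII",
    "digest_sequence",
    "build_fragment_index",
    "locate_fragment",
    "write_fragment_bed",
    "read_fragment_bed",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site plus cut offset.

    ``cut_offset`` is the distance in bp from the start of the recognition
    site to the cut, e.g. HindIII A^AGCTT cuts 1 bp into its AAGCTT site.
    """

    recognition_site: str = "AAGCTT"
    cut_offset: int = 1

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or not re.fullmatch(r"[ACGTN]+", site):
            raise ValueError(f"invalid recognition site: {self.recognition_site!r}")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )
        object.__setattr__(self, "recognition_site", site)


HINDIII = EnzymeSpec("AAGCTT", 1)


@dataclass(frozen=True)
class RestrictionFragment:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    frag_id: int  # consecutive per chromosome from 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")


def digest_sequence(sequence: str, enzyme: EnzymeSpec = HINDIII) -> list[tuple[int, int]]:
    """Digest one sequence, returning half-open fragment intervals.

    Cuts fall at ``site_start + cut_offset`` for every (possibly
    overlapping) occurrence of the recognition site.  Cuts at position 0 or
    at the sequence end would create empty fragments and are ignored.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    n = len(sequence)
    # lookahead regex finds overlapping occurrences
    pattern = re.compile(f"(?={re.escape(enzyme.recognition_site)})", re.IGNORECASE)
    cuts = sorted(
        {
            m.start() + enzyme.cut_offset
            for m in pattern.finditer(sequence)
            if 0 < m.start() + enzyme.cut_offset < n
        }
    )
    bounds = [0, *cuts, n]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


class FragmentIndex:
    """Restriction fragments of a genome, indexed for position lookup.

    Fragments tile each chromosome exactly; ``frag_id`` restarts at 0 on
    every chromosome, matching the per-chromosome fragment numbering used
    in Hi-C contact files.
    """

    def __init__(self, fragments_by_chrom: Mapping[str, list[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._lengths: dict[str, int] = {}
        for chrom, intervals in fragments_by_chrom.items():
            if chrom in self._starts:
                raise ValueError(f"duplicate chromosome name: {chrom}")
            if not intervals:
                raise ValueError(f"chromosome {chrom} has no fragments")
            starts = np.fromiter((s for s, _ in intervals), dtype=np.int64)
            prev_end = 0
            for s, e in intervals:
                if s != prev_end or s >= e:
                    raise ValueError(
                        f"fragments of {chrom} do not tile the chromosome at {s}"
                    )
                prev_end = e
            self._starts[chrom] = starts
            self._lengths[chrom] = intervals[-1][1]

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def chrom_length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._starts[chrom])
        return sum(len(v) for v in self._starts.values())

    def locate(self, chrom: str, pos: int) -> int:
        """Return the frag_id of the fragment containing (chrom, pos)."""
        if chrom not in self._starts:
            raise KeyError(f"unknown chromosome: {chrom}")
        if not (0 <= pos < self._lengths[chrom]):
            raise IndexError(
                f"position {pos} outside {chrom} [0, {self._lengths[chrom]})"
            )
        return int(np.searchsorted(self._starts[chrom], pos, side="right") - 1)

    def fragment(self, chrom: str, frag_id: int) -> RestrictionFragment:
        starts = self._starts[chrom]
        if not (0 <= frag_id < len(starts)):
            raise IndexError(f"no fragment {frag_id} on {chrom}")
        end = (
            int(starts[frag_id + 1])
            if frag_id + 1 < len(starts)
            else self._lengths[chrom]
        )
        return RestrictionFragment(chrom, int(starts[frag_id]), end, frag_id)

    def fragments(self, chrom: str) -> Iterator[RestrictionFragment]:
        for frag_id in range(len(self._starts[chrom])):
            yield self.fragment(chrom, frag_id)

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for chrom in self._starts:
            yield from self.fragments(chrom)

    def total_span(self) -> int:
        return sum(self._lengths.values())


def build_fragment_index(
    genome: Mapping[str, str] | str | Path, enzyme: EnzymeSpec = HINDIII
) -> FragmentIndex:
    """Digest a genome (chrom -> sequence mapping, or FASTA path) into a FragmentIndex."""
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome), as_raw=True, rebuild=True)
        seqs: Iterable[tuple[str, str]] = ((name, str(fasta[name][:])) for name in fasta.keys())
    else:
        seqs = genome.items()
    fragments: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in seqs:
        if chrom in fragments:
            raise ValueError(f"duplicate chromosome name: {chrom}")
        fragments[chrom] = digest_sequence(str(seq), enzyme)
    return FragmentIndex(fragments)


def locate_fragment(index: FragmentIndex, chrom: str, pos: int) -> int:
    """Functional alias for :meth:`FragmentIndex.locate`."""
    return index.locate(chrom, pos)


def write_fragment_bed(index: FragmentIndex, path: str | Path) -> None:
    """Write fragments as BED (chrom, start, end, frag_id), 0-based half-open."""
    with open(path, "w") as fh:
        for frag in index:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.frag_id}\n")


def read_fragment_bed(path: str | Path) -> FragmentIndex:
    fragments: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _fid = line.rstrip("\n").split("\t")
            fragments.setdefault(chrom, []).append((int(start), int(end)))
    return FragmentIndex(fragments)
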