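"""Hi-C contact library: parsing, mapping-quality filtering, QC and indexing.

Input is the cleaned 11-column whitespace-separated contact text produced by
standard Hi-C post-processing (one line per read pair):

    read_name str1 chr1 pos1 frag1 mapq1 str2 chr2 pos2 frag2 mapq2

Read pairs where both ends have mapq >= 30 enter the library; the rest are
dropped.  Contacts are undirected: each retained pair is keyed by its
order-normalised fragment endpoints, and per-pair counts are kept so that
fragment-level interaction lookups report contact multiplicities.

Library QC follows contact-level dedup semantics: two records are positional
duplicates when they share both (strand, chrom, pos) endpoints after order
normalisation.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "HiCContact",
    "QCReport",
    "ContactLibrary",
    "parse_contacts",
    "qc_contact_library",
    "interacting_fragments",
]

FragKey = tuple[str, int]  # (chrom, frag_id)


@dataclass(frozen=True)
class HiCContact:
    read_name: str
    str1: str
    chrom1: str
    pos1: int  # 1-based, as in the source file
    frag1: int
    mapq1: int
    str2: str
    chrom2: str
    pos2: int
    frag2: int
    mapq2: int


@dataclass(frozen=True)
class QCReport:
    total_records: int
    retained_records: int
    unique_contacts: int
    duplication_rate: float  # fraction of records that are positional duplicates
    unique_contact_fraction: float  # unique_contacts / total_records

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class ContactLibrary:
    """Multiset of undirected fragment-pair contacts plus QC statistics."""

    def __init__(self, pair_counts: Counter, qc: QCReport):
        self.pair_counts: Counter = pair_counts  # {(FragKey, FragKey): count}, keys sorted
        self.qc = qc
        self._neighbors: dict[FragKey, Counter] = {}
        for (a, b), count in pair_counts.items():
            self._neighbors.setdefault(a, Counter())[b] += count
            if b != a:
                self._neighbors.setdefault(b, Counter())[a] += count

    @property
    def retained_records(self) -> int:
        return self.qc.retained_records

    def contact_count(self, a: FragKey, b: FragKey) -> int:
        return self.pair_counts.get(tuple(sorted((a, b))), 0)

    def neighbors(self, frag: FragKey) -> Counter:
        """All fragments sharing >=1 contact with ``frag``, with counts."""
        return self._neighbors.get(frag, Counter())

    def write_pairs_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom1\tfrag1\tchrom2\tfrag2\tcount\n")
            for (a, b), count in sorted(self.pair_counts.items()):
                fh.write(f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{count}\n")

    def write_qc_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.qc.to_dict(), indent=2) + "\n")


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as fh:
            yield from fh
    else:  # iterable of lines / open stream
        yield from source


def parse_contact_line(line: str, lineno: int = 0) -> HiCContact:
    fields = line.split()
    if len(fields) != 11:
        raise ValueError(
            f"line {lineno}: expected 11 whitespace-separated fields, got {len(fields)}"
        )
    try:
        contact = HiCContact(
            read_name=fields[0],
            str1=fields[1],
            chrom1=fields[2],
            pos1=int(fields[3]),
            frag1=int(fields[4]),
            mapq1=int(fields[5]),
            str2=fields[6],
            chrom2=fields[7],
            pos2=int(fields[8]),
            frag2=int(fields[9]),
            mapq2=int(fields[10]),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None
    if contact.mapq1 < 0 or contact.mapq2 < 0:
        raise ValueError(f"line {lineno}: negative mapping quality")
    return contact


def parse_contacts(
    source: str | Path | Iterable[str] | Sequence[str | Path],
    mapq_min: int = 30,
) -> ContactLibrary:
    """Parse contact text into a :class:`ContactLibrary`.

    ``source`` may be a single path, an iterable of lines, or a list of
    paths; multiple files (e.g. replicate libraries of one tissue) are
    pooled into a single library before any downstream mapping.
    """
    def _is_path(entry) -> bool:
        return isinstance(entry, Path) or (isinstance(entry, str) and " " not in entry.strip())

    if isinstance(source, (list, tuple)) and source and all(_is_path(e) for e in source):
        sources: Iterable = source  # list of files to pool
    else:
        sources = [source]

    pair_counts: Counter = Counter()
    position_keys: Counter = Counter()
    total = 0
    retained = 0
    for one in sources:
        for lineno, line in enumerate(_iter_lines(one), start=1):
            if not line.strip():
                continue
            contact = parse_contact_line(line, lineno)
            total += 1
            if min(contact.mapq1, contact.mapq2) < mapq_min:
                continue
            retained += 1
            end1 = (contact.str1, contact.chrom1, contact.pos1)
            end2 = (contact.str2, contact.chrom2, contact.pos2)
            position_keys[tuple(sorted((end1, end2)))] += 1
            a: FragKey = (contact.chrom1, contact.frag1)
            b: FragKey = (contact.chrom2, contact.frag2)
            pair_counts[tuple(sorted((a, b)))] += 1

    unique = len(position_keys)
    dup_rate = (retained - unique) / total if total else 0.0
    qc = QCReport(
        total_records=total,
        retained_records=retained,
        unique_contacts=unique,
        duplication_rate=dup_rate,
        unique_contact_fraction=unique / total if total else 0.0,
    )
    return ContactLibrary(pair_counts, qc)


def qc_contact_library(
    library: ContactLibrary,
    min_unique_fraction: float = 0.5,
    max_dup_rate: float = 0.4,
) -> tuple[bool, QCReport]:
    """Pass/fail the library against contact-level QC thresholds.

    Pass requires unique_contact_fraction > min_unique_fraction AND
    duplication_rate < max_dup_rate.  Sequencing-level alignability cannot
    be recomputed from a contact list and is not checked here.
    """
    if library.qc.total_records == 0:
        raise ValueError("cannot QC an empty contact library")
    passed = (
        library.qc.unique_contact_fraction > min_unique_fraction
        and library.qc.duplication_rate < max_dup_rate
    )
    return passed, library.qc


def interacting_fragments(
    library: ContactLibrary, chrom: str, frag_id: int
) -> set[tuple[str, int, int]]:
    """Every fragment sharing >=1 retained contact with the query fragment.

    Returns (chrom, frag_id, total contact count) triples; a self-ligation
    record makes the query fragment its own interactor.  Unknown fragments
    yield the empty set.
    """
    return {
        (other[0], other[1], count)
        for other, count in library.neighbors((chrom, frag_id)).items()
    }
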