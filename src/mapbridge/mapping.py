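"""Alignment filtering modes and the builtin exact-substring test mapper.

Two filtering regimes are used when placing map markers on the intermediate
reference genome:

* ``standard`` — homology mode: a marker is kept only when it has a single
  reported placement with MAPQ >= 10.  Ambiguous markers are discarded, which
  matters in a post-duplication genome where many loci exist in two copies.
* ``homeolog`` — for comparing a non-duplicated outgroup map against
  duplicated genomes: the MAPQ floor drops to 2 and up to ``max_hits``
  placements per marker are kept (default 2, one per homeolog).

The builtin mapper reports every exact occurrence of each marker sequence
(forward or reverse complement) in the genome, so the whole pipeline can run
without an external aligner.  Its quality model is binary: MAPQ 60 for a
unique occurrence, 0 for multi-occurrence; pipelines driving it in homeolog
mode should therefore use a MAPQ floor of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from mapbridge.linkage_io import LinkageMap, MarkerAlignment, MarkerKey

DEFAULT_MIN_MAPQ = {"standard": 10, "homeolog": 2}
DEFAULT_MAX_HITS = {"standard": 1, "homeolog": 2}


@dataclass(frozen=True)
class FilterMode:
    """Alignment retention policy (see module docstring)."""

    name: str
    min_mapq: int
    max_hits: int

    def __post_init__(self) -> None:
        if self.name not in ("standard", "homeolog"):
            raise ValueError(f"unknown filter mode {self.name!r}")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    @classmethod
    def standard(cls, min_mapq: int | None = None) -> "FilterMode":
        return cls("standard", DEFAULT_MIN_MAPQ["standard"] if min_mapq is None else min_mapq, 1)

    @classmethod
    def homeolog(cls, min_mapq: int | None = None, max_hits: int | None = None) -> "FilterMode":
        return cls(
            "homeolog",
            DEFAULT_MIN_MAPQ["homeolog"] if min_mapq is None else min_mapq,
            DEFAULT_MAX_HITS["homeolog"] if max_hits is None else max_hits,
        )


@dataclass
class FilterReport:
    """Per-run retention bookkeeping: mapped = retained + rejected (markers)."""

    n_markers_mapped: int = 0
    n_markers_retained: int = 0
    n_records_retained: int = 0
    rejected: dict[MarkerKey, str] = field(default_factory=dict)

    @property
    def n_markers_rejected(self) -> int:
        return self.n_markers_mapped - self.n_markers_retained


def _group_by_marker(
    alignments: Iterable[MarkerAlignment],
) -> Mapping[MarkerKey, list[MarkerAlignment]]:
    groups: dict[MarkerKey, list[MarkerAlignment]] = {}
    for a in alignments:
        groups.setdefault(a.marker_key, []).append(a)
    return groups


def filter_alignments(
    alignments: Sequence[MarkerAlignment], mode: FilterMode
) -> tuple[list[MarkerAlignment], FilterReport]:
    """Apply a retention policy to marker alignments.

    Standard mode keeps a marker only when exactly one placement was reported
    (``n_hits == 1``) and its MAPQ clears the floor.  Homeolog mode keeps up
    to ``max_hits`` placements per marker, ranked by MAPQ then leftmost
    coordinate, each clearing the floor.
    """
    report = FilterReport()
    retained: list[MarkerAlignment] = []
    for key, group in sorted(_group_by_marker(alignments).items()):
        report.n_markers_mapped += 1
        if mode.name == "standard":
            # n_hits is the per-query count; every record of the group carries it
            if any(a.n_hits > 1 for a in group) or len(group) > 1:
                report.rejected[key] = "multiple placements"
                continue
            (a,) = group
            if a.mapq < mode.min_mapq:
                report.rejected[key] = f"mapq {a.mapq} < {mode.min_mapq}"
                continue
            retained.append(a)
            report.n_markers_retained += 1
            report.n_records_retained += 1
        else:
            ok = [a for a in group if a.mapq >= mode.min_mapq]
            ok.sort(key=lambda a: (-a.mapq, a.contig, a.start_bp))
            ok = ok[: mode.max_hits]
            if not ok:
                report.rejected[key] = f"no placement with mapq >= {mode.min_mapq}"
                continue
            retained.extend(ok)
            report.n_markers_retained += 1
            report.n_records_retained += len(ok)
    retained.sort(key=lambda a: (a.marker_key, a.contig, a.start_bp))
    return retained, report


# ---------------------------------------------------------------------------
# builtin test mapper
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence offsets of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def builtin_test_mapper(
    lmap: LinkageMap, genome_fasta
) -> list[MarkerAlignment]:
    """Exact-substring mapper used in place of an external aligner.

    Every exact occurrence of each marker sequence, forward or reverse
    complement, is reported as one record.  MAPQ is 60 for a unique
    occurrence and 0 otherwise; ``n_hits`` is the total occurrence count.
    A position matching on both strands (palindromic marker) is reported
    once.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    out: list[MarkerAlignment] = []
    for m in lmap:
        if not m.sequence:
            continue
        fwd = m.sequence
        rev = str(Seq(fwd).reverse_complement())
        occurrences: set[tuple[str, int]] = set()
        for name, seq in contigs.items():
            for patt in (fwd, rev) if rev != fwd else (fwd,):
                for pos in _find_all(seq, patt):
                    occurrences.add((name, pos))
        if not occurrences:
            continue
        n = len(occurrences)
        mapq = 60 if n == 1 else 0
        for rank, (name, pos) in enumerate(sorted(occurrences)):
            out.append(
                MarkerAlignment(
                    marker_key=m.key,
                    contig=name,
                    start_bp=pos,
                    mapq=mapq,
                    n_hits=n,
                    is_primary=(rank == 0),
                )
            )
    out.sort(key=lambda a: (a.marker_key, a.contig, a.start_bp))
    return out
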