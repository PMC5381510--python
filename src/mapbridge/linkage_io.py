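"""Reading and writing linkage maps, marker FASTA export and SAM parsing.

A linkage map is a table of markers, each carrying a species id, a linkage
group label, a position in centimorgans and (usually) the marker's nucleotide
sequence.  Marker sequences are exported to FASTA with the full marker key
encoded in the record header, so that after alignment to the intermediate
reference genome the pairing stage can recover species, linkage group, cM
position and marker id from the SAM query name alone.

Coordinates: SAM positions are 1-based on input and converted to 0-based,
half-open internally.  All genomic coordinates handled by this package are
0-based unless a writer explicitly labels them otherwise.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from mapbridge.errors import MapFormatError, MapValidationError

logger = logging.getLogger(__name__)

#: Separator used in FASTA headers; forbidden in species/LG/marker tokens.
HEADER_SEP = "|"

_ALLOWED_BASES = set("ACGTN")

_COLUMNS = ("species", "linkage_group", "position_cm", "marker_id", "sequence")
# accepted aliases for header detection (case-insensitive)
_ALIASES = {
    "species": {"species", "species_id", "sp"},
    "linkage_group": {"linkage_group", "lg", "chr", "linkagegroup"},
    "position_cm": {"position_cm", "position", "cm", "pos", "pos_cm"},
    "marker_id": {"marker_id", "marker", "id", "locus"},
    "sequence": {"sequence", "seq"},
}


@dataclass(frozen=True, order=True)
class MarkerKey:
    """The four fields that identify a mapped marker across the pipeline."""

    species_id: str
    linkage_group: str
    position_cm: float
    marker_id: str

    def to_header(self) -> str:
        for tok in (self.species_id, self.linkage_group, self.marker_id):
            if HEADER_SEP in tok:
                raise MapValidationError(
                    f"token {tok!r} contains reserved separator {HEADER_SEP!r}"
                )
        return HEADER_SEP.join(
            (self.species_id, self.linkage_group, repr(self.position_cm), self.marker_id)
        )

    @classmethod
    def from_header(cls, header: str) -> "MarkerKey":
        parts = header.split(HEADER_SEP)
        if len(parts) != 4:
            raise MapFormatError(
                f"query name {header!r} does not encode a marker key "
                f"(expected 4 {HEADER_SEP!r}-separated fields)"
            )
        sp, lg, cm, mid = parts
        try:
            pos = float(cm)
        except ValueError as exc:
            raise MapFormatError(f"query name {header!r}: bad cM field {cm!r}") from exc
        return cls(sp, lg, pos, mid)


@dataclass(frozen=True)
class MapMarker:
    """One marker of a linkage map.

    ``sequence`` may be empty for maps distributed without raw reads
    (e.g. EST-derived maps); such maps can feed the map-statistics and
    rearrangement modules but not FASTA export.
    """

    species_id: str
    linkage_group: str
    position_cm: float
    marker_id: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.position_cm < 0:
            raise MapValidationError(
                f"marker {self.marker_id}: negative cM position {self.position_cm}"
            )
        seq = self.sequence.upper()
        if seq and not set(seq) <= _ALLOWED_BASES:
            bad = sorted(set(seq) - _ALLOWED_BASES)
            raise MapValidationError(
                f"marker {self.marker_id}: sequence contains non-ACGTN symbols {bad}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def key(self) -> MarkerKey:
        return MarkerKey(
            self.species_id, self.linkage_group, self.position_cm, self.marker_id
        )


def _sort_markers(markers: Iterable[MapMarker]) -> list[MapMarker]:
    # cM ties within an LG break by marker id, for determinism
    return sorted(
        markers, key=lambda m: (m.linkage_group, m.position_cm, m.marker_id)
    )


@dataclass
class LinkageMap:
    """An ordered collection of markers for one species.

    Markers are kept sorted by (linkage group, cM, marker id); ``lg_index``
    groups them per linkage group in map order.
    """

    species_id: str
    markers: list[MapMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.markers:
            if m.species_id != self.species_id:
                raise MapValidationError(
                    f"marker {m.marker_id} belongs to {m.species_id!r}, "
                    f"not {self.species_id!r}"
                )
        seen: dict[str, int] = {}
        for m in self.markers:
            seen[m.marker_id] = seen.get(m.marker_id, 0) + 1
        dups = sorted(mid for mid, n in seen.items() if n > 1)
        if dups:
            raise MapValidationError(
                f"duplicate marker ids within species {self.species_id!r}: {dups}"
            )
        self.markers = _sort_markers(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def lg_index(self) -> dict[str, list[MapMarker]]:
        out: dict[str, list[MapMarker]] = {}
        for m in self.markers:
            out.setdefault(m.linkage_group, []).append(m)
        return out

    @property
    def linkage_groups(self) -> list[str]:
        return sorted({m.linkage_group for m in self.markers})

    def by_key(self) -> dict[MarkerKey, MapMarker]:
        return {m.key: m for m in self.markers}


@dataclass(frozen=True)
class MarkerAlignment:
    """Placement of one marker on the reference genome.

    ``start_bp`` is 0-based.  ``n_hits`` counts all reported placements of
    the marker (primary plus secondary); ``mapq`` is clamped to [0, 60] and
    the SAM sentinel 255 ("unavailable") maps to 0.
    """

    marker_key: MarkerKey
    contig: str
    start_bp: int
    mapq: int
    n_hits: int = 1
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise MapValidationError(f"negative start_bp {self.start_bp}")
        if not 0 <= self.mapq <= 60:
            raise MapValidationError(f"mapq {self.mapq} outside [0, 60]")
        if self.n_hits < 1:
            raise MapValidationError("n_hits must be >= 1 for a retained record")


# ---------------------------------------------------------------------------
# map tables
# ---------------------------------------------------------------------------

def read_map_table(
    path,
    delimiter: str = "\t",
    has_header: bool = True,
    species_id: str | None = None,
) -> LinkageMap:
    """Read a delimited linkage-map table.

    Expected columns (by name when ``has_header``, else by position):
    species, linkage_group, position_cm, marker_id, sequence.  The sequence
    column may be absent or empty.  Rows whose position does not parse as a
    non-negative number are rejected with a warning.

    Raises
    ------
    MapFormatError
        if a mandatory column is missing.
    MapValidationError
        if a marker id occurs twice within the species.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise MapFormatError(f"{path}: empty map table")

    if has_header:
        header = [c.strip().lower() for c in rows[0]]
        idx: dict[str, int] = {}
        for canon, aliases in _ALIASES.items():
            for i, col in enumerate(header):
                if col in aliases:
                    idx[canon] = i
                    break
        missing = [c for c in _COLUMNS[:4] if c not in idx]
        if missing:
            raise MapFormatError(
                f"{path}: missing mandatory column(s) {missing} in header {header}"
            )
        body = rows[1:]
    else:
        if len(rows[0]) < 4:
            raise MapFormatError(
                f"{path}: headerless table needs >= 4 columns "
                "(species, linkage_group, position_cm, marker_id[, sequence])"
            )
        idx = {c: i for i, c in enumerate(_COLUMNS)}
        body = rows

    markers: list[MapMarker] = []
    n_rejected = 0
    for row in body:
        def cell(col: str) -> str:
            i = idx.get(col)
            return row[i].strip() if i is not None and i < len(row) else ""

        try:
            pos = float(cell("position_cm"))
            if pos < 0:
                raise ValueError
        except ValueError:
            n_rejected += 1
            logger.warning("rejecting row with unparseable position: %r", row)
            continue
        markers.append(
            MapMarker(
                species_id=cell("species"),
                linkage_group=cell("linkage_group"),
                position_cm=pos,
                marker_id=cell("marker_id"),
                sequence=cell("sequence"),
            )
        )
    if n_rejected:
        logger.info("%s: rejected %d row(s) with bad positions", path, n_rejected)
    if not markers:
        raise MapFormatError(f"{path}: no parseable marker rows")
    sp = species_id or markers[0].species_id
    return LinkageMap(species_id=sp, markers=markers)


def write_map_table(lmap: LinkageMap, path, delimiter: str = "\t") -> int:
    """Write a linkage map back to a delimited table; returns row count."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_COLUMNS)
        for m in lmap:
            w.writerow(
                [m.species_id, m.linkage_group, repr(m.position_cm), m.marker_id, m.sequence]
            )
    return len(lmap)


def drop_duplicated_loci(
    lmap: LinkageMap,
    by: str = "sequence",
    flagged_ids: Iterable[str] | None = None,
) -> LinkageMap:
    """Remove duplicated loci from a map.

    ``by="sequence"`` removes every marker whose (non-empty) sequence occurs
    under more than one marker id in the species; ``by="flag"`` removes the
    explicitly listed ``flagged_ids``.  Duplicated loci confound pairing in
    post-duplication genomes, so only non-duplicated loci are retained.
    Idempotent; the removal count is logged.
    """
    if by == "sequence":
        counts: dict[str, int] = {}
        for m in lmap:
            if m.sequence:
                counts[m.sequence] = counts.get(m.sequence, 0) + 1
        keep = [m for m in lmap if not (m.sequence and counts[m.sequence] > 1)]
    elif by == "flag":
        flagged = set(flagged_ids or ())
        keep = [m for m in lmap if m.marker_id not in flagged]
    else:
        raise ValueError(f"unknown duplicate-detection mode {by!r}")
    removed = len(lmap) - len(keep)
    if removed:
        logger.info(
            "%s: removed %d duplicated locus marker(s)", lmap.species_id, removed
        )
    return LinkageMap(species_id=lmap.species_id, markers=keep)


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------

def write_marker_fasta(lmap: LinkageMap, path) -> int:
    """Write one FASTA record per marker; returns the record count.

    Headers encode (species, LG, cM, marker id) via :class:`MarkerKey` so the
    pairing stage can recover the full key from SAM query names.  Markers
    with empty sequences are skipped with a warning.
    """
    n = 0
    with open(path, "w") as fh:
        for m in lmap:
            if not m.sequence:
                logger.warning(
                    "marker %s has no sequence; skipped in FASTA export", m.marker_id
                )
                continue
            fh.write(f">{m.key.to_header()}\n{m.sequence}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def read_alignments(sam_path, include_secondary: bool = False) -> list[MarkerAlignment]:
    """Parse marker alignments from a SAM file produced by an external aligner.

    Query names must be headers written by :func:`write_marker_fasta`.  By
    default one :class:`MarkerAlignment` is emitted per primary alignment
    line, with ``n_hits`` aggregating the secondary lines of the same query;
    ``include_secondary=True`` additionally emits the secondary placements as
    records (needed when homeolog-mode pairing runs from an external SAM).
    Unmapped records are excluded.  SAM 1-based positions become 0-based.
    """
    per_query: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            per_query.setdefault(rec.query_name, []).append(
                (
                    rec.reference_name,
                    int(rec.reference_start),  # pysam is already 0-based
                    int(rec.mapping_quality),
                    bool(rec.is_secondary or rec.is_supplementary),
                )
            )
    out: list[MarkerAlignment] = []
    for qname, hits in per_query.items():
        key = MarkerKey.from_header(qname)  # raises MapFormatError citing qname
        n_hits = len(hits)
        for contig, start, mapq, secondary in hits:
            if secondary and not include_secondary:
                continue
            mapq = 0 if mapq == 255 else min(mapq, 60)
            out.append(
                MarkerAlignment(
                    marker_key=key,
                    contig=contig,
                    start_bp=start,
                    mapq=mapq,
                    n_hits=n_hits,
                    is_primary=not secondary,
                )
            )
    out.sort(key=lambda a: (a.marker_key, a.contig, a.start_bp))
    return out


def attach_sequences(alignments: Sequence[MarkerAlignment], lmap: LinkageMap):
    """Yield (alignment, marker) pairs, validating that keys exist in the map."""
    index = lmap.by_key()
    for a in alignments:
        m = index.get(a.marker_key)
        if m is None:
            raise MapValidationError(f"alignment references unknown marker {a.marker_key}")
        yield a, m
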