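"""The pairing core: closest-marker matching through a reference genome.

Markers from two species that align to the same contig of the intermediate
reference genome are candidate pairs.  Candidates are ranked by genomic
distance and accepted greedily *without replacement*: once a marker enters a
pair, every other candidate involving it is discarded.  A distance cap
(default 10 Mbp) bounds how far apart two paired markers may sit on the
contig.  Only the cM positions of the paired markers are carried to the
Oxford grid; the genomic coordinate is used solely for pairing.

A reciprocal-best-hit baseline (the usual direct marker-homology approach)
is provided for comparison, along with Oxford-grid construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from mapbridge.errors import MapValidationError
from mapbridge.linkage_io import LinkageMap, MarkerAlignment, MarkerKey

DEFAULT_MAX_DISTANCE_BP = 10_000_000


@dataclass(frozen=True)
class MarkerPair:
    """One marker from each species, joined via proximity on one contig."""

    marker_a: MarkerKey
    marker_b: MarkerKey
    contig: str
    pos_a_bp: int
    pos_b_bp: int

    @property
    def distance_bp(self) -> int:
        return abs(self.pos_a_bp - self.pos_b_bp)

    @property
    def cm_a(self) -> float:
        return self.marker_a.position_cm

    @property
    def cm_b(self) -> float:
        return self.marker_b.position_cm


@dataclass
class PairingResult:
    pairs: list[MarkerPair] = field(default_factory=list)
    unpaired_a: list[MarkerKey] = field(default_factory=list)
    unpaired_b: list[MarkerKey] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lg_a": p.marker_a.linkage_group,
                "lg_b": p.marker_b.linkage_group,
                "cm_a": p.cm_a,
                "cm_b": p.cm_b,
                "marker_a": p.marker_a.marker_id,
                "marker_b": p.marker_b.marker_id,
                "contig": p.contig,
                "pos_a_bp": p.pos_a_bp,
                "pos_b_bp": p.pos_b_bp,
                "distance_bp": p.distance_bp,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lg_a", "lg_b", "cm_a", "cm_b", "marker_a", "marker_b",
                "contig", "pos_a_bp", "pos_b_bp", "distance_bp",
            ],
        )


def _candidates(
    aln_a: Sequence[MarkerAlignment],
    aln_b: Sequence[MarkerAlignment],
    max_distance_bp: int,
):
    """All same-contig cross-species candidates within the distance cap,
    sorted by (distance, contig, min coordinate, marker ids)."""
    by_contig_b: dict[str, list[MarkerAlignment]] = {}
    for b in aln_b:
        by_contig_b.setdefault(b.contig, []).append(b)
    cands = []
    for a in aln_a:
        for b in by_contig_b.get(a.contig, ()):
            d = abs(a.start_bp - b.start_bp)
            if d <= max_distance_bp:
                cands.append((d, a.contig, min(a.start_bp, b.start_bp),
                              a.marker_key.marker_id, b.marker_key.marker_id, a, b))
    cands.sort(key=lambda c: c[:5])
    return cands


def pair_closest_without_replacement(
    aln_a: Sequence[MarkerAlignment],
    aln_b: Sequence[MarkerAlignment],
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
) -> PairingResult:
    """Greedy closest-pair matching without replacement (standard mode).

    Inputs are assumed pre-filtered (standard mode: single placement per
    marker).  Candidate pairs on a shared contig within ``max_distance_bp``
    are accepted in order of increasing distance, skipping any candidate
    whose marker (either side) is already paired.  Equal distances break by
    (contig label, lower coordinate, marker ids), making the matching
    deterministic.
    """
    used_a: set[MarkerKey] = set()
    used_b: set[MarkerKey] = set()
    pairs: list[MarkerPair] = []
    for d, contig, _lo, _ma, _mb, a, b in _candidates(aln_a, aln_b, max_distance_bp):
        if a.marker_key in used_a or b.marker_key in used_b:
            continue
        used_a.add(a.marker_key)
        used_b.add(b.marker_key)
        pairs.append(
            MarkerPair(a.marker_key, b.marker_key, contig, a.start_bp, b.start_bp)
        )
    unpaired_a = sorted({a.marker_key for a in aln_a} - used_a)
    unpaired_b = sorted({b.marker_key for b in aln_b} - used_b)
    return PairingResult(pairs, unpaired_a, unpaired_b)


def pair_homeolog_mode(
    aln_outgroup: Sequence[MarkerAlignment],
    aln_target: Sequence[MarkerAlignment],
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
) -> PairingResult:
    """Pairing against a non-duplicated outgroup map.

    Each outgroup marker may pair once per distinct retained placement (it
    can be present in duplicate in the post-duplication genome), while target
    markers remain single-use.  Outgroup alignments should have been filtered
    in homeolog mode, the target in standard mode.
    """
    used_og_placement: set[tuple[MarkerKey, str, int]] = set()
    used_b: set[MarkerKey] = set()
    pairs: list[MarkerPair] = []
    for d, contig, _lo, _ma, _mb, a, b in _candidates(
        aln_outgroup, aln_target, max_distance_bp
    ):
        placement = (a.marker_key, a.contig, a.start_bp)
        if placement in used_og_placement or b.marker_key in used_b:
            continue
        used_og_placement.add(placement)
        used_b.add(b.marker_key)
        pairs.append(
            MarkerPair(a.marker_key, b.marker_key, contig, a.start_bp, b.start_bp)
        )
    paired_og = {p.marker_a for p in pairs}
    unpaired_a = sorted({a.marker_key for a in aln_outgroup} - paired_og)
    unpaired_b = sorted({b.marker_key for b in aln_target} - used_b)
    return PairingResult(pairs, unpaired_a, unpaired_b)


# ---------------------------------------------------------------------------
# reciprocal best hit baseline
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, max(len(seq) - k + 1, 0))}


def shared_kmer_score(a: str, b: str, k: int = 12) -> float:
    """Builtin symmetric similarity: shared distinct k-mers, with an
    exact-identity override that outranks any inexact match."""
    if a and a == b:
        return float(10 * max(len(a), k))
    return float(len(_kmers(a, k) & _kmers(b, k)))


def reciprocal_best_hit_pairs(
    map_a: LinkageMap,
    map_b: LinkageMap,
    scorer: Callable[[str, str], float] | None = None,
    min_score: float = 1.0,
) -> PairingResult:
    """Direct marker homology: pair markers that are each other's unique best
    match under a symmetric sequence-similarity score.  Ties for best score
    produce no pair.  This is the baseline MapComp improves on by also
    pairing non-identical, proximate markers.
    """
    score = scorer or shared_kmer_score
    a_markers = [m for m in map_a if m.sequence]
    b_markers = [m for m in map_b if m.sequence]

    def best(m, others):
        scored = [(score(m.sequence, o.sequence), o) for o in others]
        scored = [(s, o) for s, o in scored if s >= min_score]
        if not scored:
            return None
        top = max(s for s, _ in scored)
        winners = [o for s, o in scored if s == top]
        return winners[0] if len(winners) == 1 else None

    best_a = {m.marker_id: best(m, b_markers) for m in a_markers}
    best_b = {m.marker_id: best(m, a_markers) for m in b_markers}
    pairs = []
    for m in a_markers:
        o = best_a[m.marker_id]
        if o is None:
            continue
        back = best_b[o.marker_id]
        if back is not None and back.marker_id == m.marker_id:
            pairs.append(MarkerPair(m.key, o.key, contig="", pos_a_bp=0, pos_b_bp=0))
    paired_a = {p.marker_a for p in pairs}
    paired_b = {p.marker_b for p in pairs}
    return PairingResult(
        pairs,
        sorted({m.key for m in a_markers} - paired_a),
        sorted({m.key for m in b_markers} - paired_b),
    )


# ---------------------------------------------------------------------------
# Oxford grid
# ---------------------------------------------------------------------------

@dataclass
class OxfordGrid:
    """Marker-pair counts and cM scatter per linkage-group pair.

    Only the linkage-map cM positions enter the grid; the genomic coordinate
    used for pairing is dropped.
    """

    species_a: str
    species_b: str
    cells: dict[tuple[str, str], int] = field(default_factory=dict)
    points: dict[tuple[str, str], list[tuple[float, float]]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return sum(self.cells.values())

    def cell_counts(self) -> pd.DataFrame:
        rows = [
            {"lg_a": la, "lg_b": lb, "n_pairs": n}
            for (la, lb), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["lg_a", "lg_b", "n_pairs"])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lg_a": la, "lg_b": lb, "cm_a": ca, "cm_b": cb}
            for (la, lb), pts in sorted(self.points.items())
            for ca, cb in pts
        ]
        return pd.DataFrame(rows, columns=["lg_a", "lg_b", "cm_a", "cm_b"])

    def plot(self, path) -> None:
        """Dot-plot of all LG x LG cells (one panel, LG offsets on axes)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        lgs_a = sorted({la for la, _ in self.cells})
        lgs_b = sorted({lb for _, lb in self.cells})
        fig, ax = plt.subplots(figsize=(8, 8))
        off_a = {lg: i for i, lg in enumerate(lgs_a)}
        off_b = {lg: i for i, lg in enumerate(lgs_b)}
        if not df.empty:
            span_a = max(df.cm_a.max(), 1.0)
            span_b = max(df.cm_b.max(), 1.0)
            xs = df.apply(lambda r: off_a[r.lg_a] + r.cm_a / (1.05 * span_a), axis=1)
            ys = df.apply(lambda r: off_b[r.lg_b] + r.cm_b / (1.05 * span_b), axis=1)
            ax.scatter(xs, ys, s=4, alpha=0.6)
        ax.set_xticks(range(len(lgs_a)))
        ax.set_xticklabels(lgs_a, rotation=90, fontsize=6)
        ax.set_yticks(range(len(lgs_b)))
        ax.set_yticklabels(lgs_b, fontsize=6)
        ax.set_xlabel(self.species_a)
        ax.set_ylabel(self.species_b)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def build_oxford_grid(
    pairing: PairingResult | Iterable[MarkerPair],
    map_a: LinkageMap,
    map_b: LinkageMap,
) -> OxfordGrid:
    """Aggregate marker pairs into an Oxford grid.

    Raises :class:`MapValidationError` when a pair references a marker absent
    from either map.
    """
    pairs = pairing.pairs if isinstance(pairing, PairingResult) else list(pairing)
    keys_a = set(map_a.by_key())
    keys_b = set(map_b.by_key())
    grid = OxfordGrid(species_a=map_a.species_id, species_b=map_b.species_id)
    for p in pairs:
        if p.marker_a not in keys_a or p.marker_b not in keys_b:
            raise MapValidationError(
                f"pair references unknown marker: {p.marker_a} / {p.marker_b}"
            )
        cell = (p.marker_a.linkage_group, p.marker_b.linkage_group)
        grid.cells[cell] = grid.cells.get(cell, 0) + 1
        grid.points.setdefault(cell, []).append((p.cm_a, p.cm_b))
    return grid
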