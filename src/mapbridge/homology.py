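"""Chromosome-arm homology and homeology calling from Oxford grids.

Dense cells of an Oxford grid identify corresponding linkage groups between
two species.  A metacentric linkage group that corresponds to two (or three)
counterpart groups is split into arms by 1-D clustering of its paired-marker
cM positions; arms are labelled a, b, c in ascending cM.  Comparisons against
a non-duplicated outgroup, run in homeolog mode, resolve each outgroup
chromosome into its two post-duplication homeologs (.1/.2 rows).  Calls from
several species pairs are merged by majority consensus into a Table-2-style
homology table keyed by ancestral arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mapbridge.errors import ConfigError, MapValidationError
from mapbridge.linkage_io import LinkageMap, MarkerAlignment
from mapbridge.pairing import OxfordGrid, PairingResult
from mapbridge.rearrangements import Karyotype

DEFAULT_MIN_PAIRS = 5
DEFAULT_DOMINANCE = 2.0
DEFAULT_MIN_GAP_CM = 5.0

ARM_LABELS = "abc"


@dataclass(frozen=True)
class ArmSegment:
    species_id: str
    linkage_group: str
    arm_label: str              # "a" | "b" | "c" | "whole"
    cm_span: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.cm_span
        if hi < lo:
            raise MapValidationError(f"reversed cm_span {self.cm_span}")


@dataclass
class CorrespondenceCall:
    lg: str
    status: str                           # "clear" | "ambiguous" | "missing"
    partners: list[tuple[str, int]]       # (counterpart LG, pair count), desc


def call_lg_correspondence(
    grid: OxfordGrid,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    dominance: float = DEFAULT_DOMINANCE,
) -> dict[str, CorrespondenceCall]:
    """Per-LG correspondence calls for the first species of the grid.

    The top counterpart cell must hold at least ``min_pairs`` pairs and at
    least ``dominance`` times the runner-up to be called "clear".
    """
    per_lg: dict[str, list[tuple[str, int]]] = {}
    for (la, lb), n in grid.cells.items():
        per_lg.setdefault(la, []).append((lb, n))
    calls: dict[str, CorrespondenceCall] = {}
    for la, partners in sorted(per_lg.items()):
        partners.sort(key=lambda x: (-x[1], x[0]))
        top = partners[0][1]
        runner = partners[1][1] if len(partners) > 1 else 0
        if top < min_pairs:
            status = "missing"
        elif runner and top < dominance * runner:
            status = "ambiguous"
        else:
            status = "clear"
        calls[la] = CorrespondenceCall(la, status, partners)
    return calls


def candidate_counterparts(
    call: CorrespondenceCall, min_pairs: int = DEFAULT_MIN_PAIRS
) -> list[str]:
    """Counterpart LGs with at least ``min_pairs`` support, best first."""
    return [lg for lg, n in call.partners if n >= min_pairs]


def split_arms(
    grid: OxfordGrid,
    lg: str,
    counterparts: Sequence[str],
    min_gap_cm: float = DEFAULT_MIN_GAP_CM,
) -> list[tuple[ArmSegment, str]] | None:
    """Partition a linkage group's cM axis by counterpart LG.

    Paired markers are grouped by counterpart; counterpart blocks are ordered
    by median cM and must be separated by at least ``min_gap_cm`` (1-D
    largest-gap clustering with k = number of counterparts).  Returns
    (segment, counterpart LG) tuples with arms labelled a, b, c in ascending
    cM, a single "whole" segment for one counterpart, or None when blocks
    overlap beyond tolerance (ambiguous, no split).
    """
    if not counterparts:
        return None
    if len(counterparts) == 1:
        pts = [ca for ca, _ in grid.points.get((lg, counterparts[0]), [])]
        if not pts:
            return None
        seg = ArmSegment(grid.species_a, lg, "whole", (min(pts), max(pts)))
        return [(seg, counterparts[0])]
    if len(counterparts) > len(ARM_LABELS):
        return None

    blocks = []
    for cp in counterparts:
        pts = sorted(ca for ca, _ in grid.points.get((lg, cp), []))
        if not pts:
            return None
        blocks.append((float(np.median(pts)), pts[0], pts[-1], cp))
    blocks.sort()
    for (_, _, hi_prev, _), (_, lo_next, _, _) in zip(blocks, blocks[1:]):
        if lo_next - hi_prev < min_gap_cm:
            return None  # overlapping clusters: ambiguous
    return [
        (ArmSegment(grid.species_a, lg, ARM_LABELS[i], (lo, hi)), cp)
        for i, (_, lo, hi, cp) in enumerate(blocks)
    ]


def call_arm_homology(
    grid: OxfordGrid,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    dominance: float = DEFAULT_DOMINANCE,
    min_gap_cm: float = DEFAULT_MIN_GAP_CM,
) -> tuple[list[tuple[ArmSegment, str]], dict[str, str]]:
    """Arm-level homology between the grid's two species.

    Single-counterpart LGs yield whole-LG correspondences; multi-counterpart
    LGs are split into arms.  Returns the correspondence list and a per-LG
    status map ("clear", "ambiguous", "missing").
    """
    calls = call_lg_correspondence(grid, min_pairs=min_pairs, dominance=dominance)
    out: list[tuple[ArmSegment, str]] = []
    status: dict[str, str] = {}
    for lg, call in calls.items():
        cands = candidate_counterparts(call, min_pairs=min_pairs)
        if not cands:
            status[lg] = "missing"
            continue
        segs = split_arms(grid, lg, cands, min_gap_cm=min_gap_cm)
        if segs is None:
            status[lg] = "ambiguous"
            continue
        status[lg] = "clear"
        out.extend(segs)
    return out, status


# ---------------------------------------------------------------------------
# homeologs
# ---------------------------------------------------------------------------

@dataclass
class HomeologCall:
    outgroup_lg: str
    first: str | None            # ".1" target LG (stronger support)
    second: str | None           # ".2" target LG or None -> "missing"
    status: str                  # "clear" | "missing_second" | "ambiguous"
    support: list[tuple[str, int]]


def assign_homeologs(
    outgroup_pairs: PairingResult,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> dict[str, HomeologCall]:
    """Resolve each outgroup chromosome into its two duplicated homeologs.

    For every outgroup LG the two target LGs with most pair support become
    the ".1" and ".2" rows (suffixes in support order; orientation across
    species is a convention fixed downstream by the consensus anchor).  One
    supported target leaves the second row missing; more than two strongly
    supported targets flag the chromosome ambiguous with all candidates
    reported.
    """
    counts: dict[str, dict[str, int]] = {}
    for p in outgroup_pairs.pairs:
        og = p.marker_a.linkage_group
        tg = p.marker_b.linkage_group
        counts.setdefault(og, {}).setdefault(tg, 0)
        counts[og][tg] += 1
    calls: dict[str, HomeologCall] = {}
    for og, tgs in sorted(counts.items()):
        ranked = sorted(tgs.items(), key=lambda x: (-x[1], x[0]))
        strong = [t for t, n in ranked if n >= min_pairs]
        if len(strong) > 2:
            calls[og] = HomeologCall(og, None, None, "ambiguous", ranked)
        elif len(strong) == 2:
            calls[og] = HomeologCall(og, strong[0], strong[1], "clear", ranked)
        elif len(strong) == 1:
            calls[og] = HomeologCall(og, strong[0], None, "missing_second", ranked)
        else:
            calls[og] = HomeologCall(og, None, None, "missing_second", ranked)
    return calls


# ---------------------------------------------------------------------------
# consensus across species pairs
# ---------------------------------------------------------------------------

@dataclass
class HomologyTable:
    """Ancestral-arm keyed homology matrix (rows = outgroup LG + .1/.2)."""

    cells: pd.DataFrame                     # index: ancestral arm, cols: species
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def validate_injective(self) -> None:
        for sp in self.cells.columns:
            col = self.cells[sp].dropna()
            col = col[~col.isin(["missing", "ambiguous"])]
            dup = col[col.duplicated()]
            if not dup.empty:
                raise MapValidationError(
                    f"species {sp}: arm(s) {sorted(set(dup))} occupy multiple rows"
                )

    @property
    def n_rows(self) -> int:
        return len(self.cells)


def consensus_homology(
    tables: Sequence[Mapping[str, Mapping[str, str]]],
    anchor_species: str,
) -> HomologyTable:
    """Merge per-comparison homology calls into one consensus table.

    Each input maps ancestral arm -> {species: arm label}.  Every comparison
    must include the anchor species (the reference whose .1/.2 orientation
    all rows follow); conflicts between comparisons resolve by majority,
    exact ties become "ambiguous".  Cell provenance records which
    comparisons supported the winning call.
    """
    for i, tab in enumerate(tables):
        if not any(anchor_species in cells for cells in tab.values()):
            raise ConfigError(
                f"comparison {i} does not involve anchor species {anchor_species!r}"
            )
    votes: dict[str, dict[str, dict[str, list[str]]]] = {}
    for i, tab in enumerate(tables):
        for arm, cells in tab.items():
            for sp, label in cells.items():
                votes.setdefault(arm, {}).setdefault(sp, {}).setdefault(label, []).append(
                    f"comparison_{i}"
                )
    arms = sorted(votes)
    species = sorted({sp for v in votes.values() for sp in v})
    data: dict[str, list[str | None]] = {sp: [] for sp in species}
    provenance: dict[tuple[str, str], list[str]] = {}
    for arm in arms:
        for sp in species:
            ballots = votes[arm].get(sp)
            if not ballots:
                data[sp].append("missing")
                continue
            ranked = sorted(ballots.items(), key=lambda x: (-len(x[1]), x[0]))
            if len(ranked) > 1 and len(ranked[0][1]) == len(ranked[1][1]):
                data[sp].append("ambiguous")
                provenance[(arm, sp)] = sorted(
                    src for _, srcs in ranked for src in srcs
                )
            else:
                data[sp].append(ranked[0][0])
                provenance[(arm, sp)] = ranked[0][1]
    cells = pd.DataFrame(data, index=pd.Index(arms, name="arm"))
    return HomologyTable(cells=cells, provenance=provenance)


# ---------------------------------------------------------------------------
# karyotype reconstruction from reference-arm alignments
# ---------------------------------------------------------------------------

def karyotype_from_alignments(
    lmap: LinkageMap,
    alignments: Sequence[MarkerAlignment],
    contig_to_arm: Mapping[str, str] | None = None,
    min_markers: int = 3,
) -> Karyotype:
    """Ordered ancestral-arm content per linkage group, from filtered
    alignments to an arm-resolved reference.

    Arms supported by fewer than ``min_markers`` markers in an LG are
    ignored as noise; arm order within an LG follows median marker cM.
    """
    by_key = lmap.by_key()
    arm_positions: dict[tuple[str, str], list[float]] = {}
    for a in alignments:
        m = by_key.get(a.marker_key)
        if m is None:
            continue
        arm = contig_to_arm[a.contig] if contig_to_arm else a.contig
        arm_positions.setdefault((m.linkage_group, arm), []).append(m.position_cm)
    lgs: dict[str, list[tuple[float, str]]] = {}
    for (lg, arm), positions in arm_positions.items():
        if len(positions) < min_markers:
            continue
        lgs.setdefault(lg, []).append((float(np.median(positions)), arm))
    return Karyotype(
        species_id=lmap.species_id,
        lgs={lg: [arm for _, arm in sorted(v)] for lg, v in sorted(lgs.items()) if v},
    )
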