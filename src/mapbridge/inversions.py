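"""Flanked-inversion detection in pairwise linkage-group comparisons.

Within one Oxford-grid cell the paired markers, ordered along the first
species' cM axis, should increase (or, for a whole-group orientation flip,
decrease) monotonically in the second species.  A run of markers whose order
is locally reversed signals a candidate inversion — but markers that fit a
linkage group poorly are often pushed to its distal ends during map
construction, so a reversed run is only called when non-inverted runs flank
it on both sides.  All calls are therefore "putative": linkage maps resolve
order, not breakpoints.

Monotonicity is evaluated on ranks of the second species' cM values, which
is robust to non-uniform marker spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import rankdata

from mapbridge.errors import MapValidationError

DEFAULT_MIN_RUN = 5
DEFAULT_MIN_FLANK = 3
DEFAULT_NOISE_TOLERANCE = 2  # segments shorter than this are absorbed


@dataclass
class SyntenyTrack:
    """Paired cM positions for one LG-vs-LG cell, sorted along species A."""

    lg_a: str
    lg_b: str
    cm_a: list[float]
    cm_b: list[float]
    ranks: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.cm_a) != len(self.cm_b):
            raise MapValidationError("cm_a and cm_b differ in length")
        order = sorted(range(len(self.cm_a)), key=lambda i: (self.cm_a[i], self.cm_b[i]))
        self.cm_a = [self.cm_a[i] for i in order]
        self.cm_b = [self.cm_b[i] for i in order]
        self.ranks = [int(r) for r in rankdata(self.cm_b, method="ordinal")]

    def __len__(self) -> int:
        return len(self.cm_a)


@dataclass
class Segment:
    sign: str            # "+" ascending, "-" descending
    start: int           # index into the track, inclusive
    end: int             # inclusive

    @property
    def n_pairs(self) -> int:
        return self.end - self.start + 1


@dataclass
class InversionCall:
    lg_a: str
    lg_b: str
    inverted_span_a: tuple[float, float]
    inverted_span_b: tuple[float, float]
    n_support: int
    flank_support: tuple[int, int]
    centromere_relation: str = "unknown"
    status: str = "putative"


def segment_collinearity(
    track: SyntenyTrack, min_run: int = DEFAULT_NOISE_TOLERANCE
) -> list[Segment]:
    """Partition a track into maximal monotone runs with sign.

    Descending steps claim both endpoints of each step, so a reversed block
    like ranks (5, 4, 3) inside an ascending context forms one "-" segment
    and the surrounding markers form "+" segments.  Segments shorter than
    ``min_run`` are then absorbed into their larger neighbour (noise
    tolerance for single discordant markers).
    """
    n = len(track)
    if n == 0:
        return []
    if n == 1:
        return [Segment("+", 0, 0)]
    r = track.ranks
    steps = ["-" if r[i + 1] < r[i] else "+" for i in range(n - 1)]

    # descending step-runs claim both endpoints of every step they contain;
    # the remaining contiguous element ranges form ascending segments
    desc: list[Segment] = []
    i = 0
    while i < n - 1:
        if steps[i] == "-":
            j = i
            while j < n - 1 and steps[j] == "-":
                j += 1
            desc.append(Segment("-", i, j))
            i = j
        else:
            i += 1
    claimed = [False] * n
    for s in desc:
        for e in range(s.start, s.end + 1):
            claimed[e] = True
    segments = list(desc)
    e = 0
    while e < n:
        if not claimed[e]:
            f = e
            while f + 1 < n and not claimed[f + 1]:
                f += 1
            segments.append(Segment("+", e, f))
            e = f + 1
        else:
            e += 1
    segments.sort(key=lambda s: s.start)

    # absorb short segments into the larger neighbour
    def absorb(segs: list[Segment]) -> list[Segment]:
        while len(segs) > 1:
            lengths = [s.n_pairs for s in segs]
            k = min(range(len(segs)), key=lambda i: (lengths[i], i))
            if lengths[k] >= min_run:
                break
            left = segs[k - 1] if k > 0 else None
            right = segs[k + 1] if k + 1 < len(segs) else None
            if left is not None and (right is None or left.n_pairs >= right.n_pairs):
                merged = Segment(left.sign, left.start, segs[k].end)
                segs[k - 1 : k + 1] = [merged]
            else:
                merged = Segment(right.sign, segs[k].start, right.end)
                segs[k : k + 2] = [merged]
            # merge adjacent same-sign segments
            out: list[Segment] = []
            for s in segs:
                if out and out[-1].sign == s.sign and out[-1].end >= s.start - 1:
                    out[-1] = Segment(s.sign, out[-1].start, s.end)
                else:
                    out.append(s)
            segs = out
        return segs

    return absorb(segments)


def call_inversions(
    track: SyntenyTrack,
    segments: Sequence[Segment] | None = None,
    min_run: int = DEFAULT_MIN_RUN,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[InversionCall]:
    """Call putative inversions from a segmented track.

    A descending segment is called only when it holds at least ``min_run``
    pairs and both adjacent segments are ascending with at least
    ``min_flank`` pairs.  Distal descending segments are never called
    (structural enforcement of the flanking rule); a fully descending track
    is a whole-group orientation flip, not an inversion.
    """
    if segments is None:
        segments = segment_collinearity(track)
    calls: list[InversionCall] = []
    for k in range(1, len(segments) - 1):
        seg = segments[k]
        if seg.sign != "-" or seg.n_pairs < min_run:
            continue
        left, right = segments[k - 1], segments[k + 1]
        if left.sign != "+" or right.sign != "+":
            continue
        if left.n_pairs < min_flank or right.n_pairs < min_flank:
            continue
        a = track.cm_a[seg.start : seg.end + 1]
        b = track.cm_b[seg.start : seg.end + 1]
        calls.append(
            InversionCall(
                lg_a=track.lg_a,
                lg_b=track.lg_b,
                inverted_span_a=(min(a), max(a)),
                inverted_span_b=(min(b), max(b)),
                n_support=seg.n_pairs,
                flank_support=(left.n_pairs, right.n_pairs),
            )
        )
    return calls


def classify_centromere_relation(
    call: InversionCall, centromere_cm_interval: tuple[float, float] | None
) -> str:
    """Pericentric when the inverted span overlaps the centromere interval,
    paracentric when disjoint, unknown without centromere data."""
    if centromere_cm_interval is None:
        return "unknown"
    lo, hi = centromere_cm_interval
    if hi < lo:
        raise MapValidationError(f"reversed centromere interval {centromere_cm_interval}")
    a_lo, a_hi = call.inverted_span_a
    relation = "pericentric" if (a_lo <= hi and lo <= a_hi) else "paracentric"
    call.centromere_relation = relation
    return relation


@dataclass(frozen=True)
class SpanLength:
    bp: int
    mb: float


def span_length_bp(flank_coord_low: int, flank_coord_high: int) -> SpanLength:
    """Physical size of an interval between two flanking genome coordinates,
    in bp and Mb (1 Mb = 10^6 bp, one-decimal rounding)."""
    if flank_coord_high < flank_coord_low:
        raise MapValidationError(
            f"flank coordinates reversed: {flank_coord_low} > {flank_coord_high}"
        )
    bp = int(flank_coord_high) - int(flank_coord_low)
    return SpanLength(bp=bp, mb=round(bp / 1e6, 1))
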