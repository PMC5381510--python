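"""Descriptive statistics of linkage maps."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from mapbridge.linkage_io import LinkageMap

#: Segregation types available in an outbred (pseudo-testcross) design.
MARKER_TYPES = ("abxac", "abxab", "abxaa", "aaxab")

_TYPE_ALIASES = {
    "abxac": "abxac", "ab x ac": "abxac", "ab×ac": "abxac",
    "abxab": "abxab", "ab x ab": "abxab", "ab×ab": "abxab",
    "abxaa": "abxaa", "ab x aa": "abxaa", "ab×aa": "abxaa",
    "aaxab": "aaxab", "aa x ab": "aaxab", "aa×ab": "aaxab",
}


def summarize_map(
    lmap: LinkageMap,
    classifications: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-LG summaries and map totals.

    LG length is the span between the first and the last marker (max cM -
    min cM); single-marker groups have length 0.  When ``classifications``
    maps LG labels to "metacentric"/"acrocentric", per-class means and
    ranges of length and marker count are added to the totals.
    """
    rows = []
    for lg, markers in sorted(lmap.lg_index.items()):
        positions = [m.position_cm for m in markers]
        rows.append(
            {
                "linkage_group": lg,
                "n_markers": len(markers),
                "length_cm": max(positions) - min(positions),
                "classification": (classifications or {}).get(lg, "unknown"),
            }
        )
    per_lg = pd.DataFrame(
        rows, columns=["linkage_group", "n_markers", "length_cm", "classification"]
    )
    totals = {
        "n_linkage_groups": len(per_lg),
        "n_markers": int(per_lg.n_markers.sum()) if len(per_lg) else 0,
        "total_length_cm": float(per_lg.length_cm.sum()) if len(per_lg) else 0.0,
    }
    if classifications:
        for cls in ("metacentric", "acrocentric"):
            sub = per_lg[per_lg.classification == cls]
            if len(sub):
                totals[cls] = {
                    "n_lgs": len(sub),
                    "mean_length_cm": float(sub.length_cm.mean()),
                    "length_range_cm": (float(sub.length_cm.min()), float(sub.length_cm.max())),
                    "mean_n_markers": float(sub.n_markers.mean()),
                    "n_markers_range": (int(sub.n_markers.min()), int(sub.n_markers.max())),
                }
    return per_lg, totals


def marker_type_tally(genotype_types: Iterable[str]) -> dict[str, int]:
    """Count markers per segregation type; unrecognized entries go to
    "unknown".  Tallies plus unknown always sum to the input length."""
    counts = {t: 0 for t in MARKER_TYPES}
    counts["unknown"] = 0
    for raw in genotype_types:
        t = _TYPE_ALIASES.get(str(raw).strip().lower())
        if t is None:
            counts["unknown"] += 1
        else:
            counts[t] += 1
    return counts
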