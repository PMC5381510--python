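"""Bundled comparative datasets.

Ships the published salmonid chromosome-arm homology matrix (50 ancestral
arms -- 25 pre-duplication chromosomes with .1/.2 homeolog designations --
across nine species), the species phylogeny, and the curated origin
constraints used by the rearrangement analysis.

Cell conventions in the arm-homology table:

* ``Ssa20b`` / ``Ots13q`` -- linkage group plus arm letter (a/b/c in map
  order, or cytogenetic p/q); a bare label (``BC25``) is a whole acrocentric
  linkage group.
* a trailing ``?`` -- orthology evidence is weak but the placement stands;
  in Lake Whitefish the two homeologous rows of several chromosomes resolve
  to the *same* map arm (probable pseudolinkage), so both ancestral arms are
  assigned to that linkage group.
* ``X+Y`` -- the arm maps across two linkage groups and has no single
  placement; treated as unplaced.
* ``-`` -- not identified in that species.
"""

from __future__ import annotations

import json
import re
from importlib import resources

import pandas as pd

from mapbridge.errors import MapFormatError
from mapbridge.rearrangements import Karyotype, Phylogeny, canonical_pair

_ARM_RE = re.compile(r"^([A-Za-z]+\d+)([abcpq])?$")
_ARM_ORDER = {"a": 0, "p": 0, "b": 1, "q": 1, "c": 2, None: 0}


def _data_path(name: str):
    return resources.files("mapbridge").joinpath("data", name)


def load_arm_homology() -> pd.DataFrame:
    """The arm-homology matrix: index = ancestral arm, columns = species."""
    with resources.as_file(_data_path("salmonid_arm_homology.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return df.set_index("arm")


def parse_arm_cell(cell: str) -> tuple[str, str | None] | None:
    """Split a cell into (linkage group, arm letter); None when unplaced."""
    cell = cell.strip()
    if cell in ("-", "") or "+" in cell:
        return None
    cell = cell.rstrip("?")
    m = _ARM_RE.match(cell)
    if not m:
        raise MapFormatError(f"unparseable arm-homology cell {cell!r}")
    return m.group(1), m.group(2)


def karyotypes_from_homology(table: pd.DataFrame) -> dict[str, Karyotype]:
    """Per-species karyotypes (ordered ancestral-arm lists per LG).

    Arms sort within a linkage group by arm letter (a < b < c, p < q); two
    ancestral arms sharing one map arm (collapsed homeologs) sort by their
    ancestral label.
    """
    def arm_sort_key(arm: str) -> tuple:
        chrom, dup = arm.split(".")
        return (int(chrom), int(dup))

    out: dict[str, Karyotype] = {}
    for species in table.columns:
        lgs: dict[str, list[tuple[int, tuple, str]]] = {}
        for arm, cell in table[species].items():
            parsed = parse_arm_cell(cell)
            if parsed is None:
                continue
            lg, letter = parsed
            lgs.setdefault(lg, []).append((_ARM_ORDER[letter], arm_sort_key(arm), arm))
        out[species] = Karyotype(
            species_id=species,
            lgs={lg: [a for _, _, a in sorted(v)] for lg, v in lgs.items()},
        )
    return out


def salmonid_karyotypes() -> dict[str, Karyotype]:
    return karyotypes_from_homology(load_arm_homology())


def salmonid_tree() -> Phylogeny:
    with resources.as_file(_data_path("salmonid_tree.nwk")) as p:
        return Phylogeny.from_file(p)


def salmonid_origin_policy() -> dict[tuple[str, str], str]:
    with resources.as_file(_data_path("salmonid_conventions.json")) as p:
        raw = json.loads(p.read_text())
    return {
        canonical_pair(*k.split("|")): v for k, v in raw["origin_policy"].items()
    }
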