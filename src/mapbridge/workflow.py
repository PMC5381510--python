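"""One-shot pairwise map comparison with a run manifest.

Chains prepare -> align -> filter -> pair -> grid for two maps and a
reference genome, writing every stage product plus a manifest that records
the configuration snapshot, input checksums, per-stage record counts and the
package version, so a run can be audited and reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

from mapbridge import __version__
from mapbridge.errors import ConfigError
from mapbridge.linkage_io import LinkageMap, read_alignments, read_map_table
from mapbridge.mapping import FilterMode, builtin_test_mapper, filter_alignments
from mapbridge.pairing import (
    DEFAULT_MAX_DISTANCE_BP,
    build_oxford_grid,
    pair_closest_without_replacement,
    pair_homeolog_mode,
)


@dataclasses.dataclass
class RunParams:
    mode: str = "standard"                    # "standard" | "homeolog"
    engine: str = "builtin"                   # "builtin" | "sam:<a.sam>,<b.sam>"
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP
    min_mapq: int | None = None               # None -> mode/engine default
    max_hits: int | None = None
    plot: bool = False

    def filter_mode_a(self) -> FilterMode:
        if self.mode == "homeolog":
            # the builtin mapper's quality model is binary {0, 60}; with it
            # the homeolog floor is 0, while external SAM keeps the >= 2 default
            floor = self.min_mapq
            if floor is None and self.engine == "builtin":
                floor = 0
            return FilterMode.homeolog(min_mapq=floor, max_hits=self.max_hits)
        return FilterMode.standard(min_mapq=self.min_mapq)

    def filter_mode_b(self) -> FilterMode:
        return FilterMode.standard(min_mapq=self.min_mapq)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pairwise(
    map_a,
    map_b,
    genome_fasta,
    out_dir,
    params: RunParams | None = None,
) -> dict:
    """Run the full pairwise comparison; returns the manifest dict.

    ``map_a``/``map_b`` are map-table paths or :class:`LinkageMap` objects.
    In homeolog mode map A is treated as the non-duplicated outgroup.
    Stage counts in the manifest conserve: markers >= mapped >= filtered,
    and each pair consumes one retained marker per side.
    """
    params = params or RunParams()
    if params.mode not in ("standard", "homeolog"):
        raise ConfigError(f"unknown mode {params.mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": {"name": "mapbridge", "version": __version__},
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "params": dataclasses.asdict(params),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts

    maps = {}
    for side, src in (("a", map_a), ("b", map_b)):
        if isinstance(src, LinkageMap):
            maps[side] = src
        else:
            manifest["inputs"][f"map_{side}"] = {"path": str(src), "sha256": _sha256(src)}
            maps[side] = read_map_table(src)
    if genome_fasta is not None:
        manifest["inputs"]["genome"] = {
            "path": str(genome_fasta),
            "sha256": _sha256(genome_fasta),
        }
    stage("prepare", markers_a=len(maps["a"]), markers_b=len(maps["b"]))

    if params.engine == "builtin":
        aln_a = builtin_test_mapper(maps["a"], genome_fasta)
        aln_b = builtin_test_mapper(maps["b"], genome_fasta)
    elif params.engine.startswith("sam:"):
        try:
            sam_a, sam_b = params.engine[4:].split(",")
        except ValueError as exc:
            raise ConfigError("sam engine spec must be 'sam:<a.sam>,<b.sam>'") from exc
        aln_a = read_alignments(sam_a, include_secondary=params.mode == "homeolog")
        aln_b = read_alignments(sam_b)
    else:
        raise ConfigError(f"unknown engine {params.engine!r}")
    stage(
        "align",
        mapped_markers_a=len({a.marker_key for a in aln_a}),
        mapped_markers_b=len({a.marker_key for a in aln_b}),
    )

    kept_a, rep_a = filter_alignments(aln_a, params.filter_mode_a())
    kept_b, rep_b = filter_alignments(aln_b, params.filter_mode_b())
    stage(
        "filter",
        retained_markers_a=rep_a.n_markers_retained,
        retained_markers_b=rep_b.n_markers_retained,
        rejected_markers_a=rep_a.n_markers_rejected,
        rejected_markers_b=rep_b.n_markers_rejected,
    )

    if params.mode == "homeolog":
        pairing = pair_homeolog_mode(kept_a, kept_b, params.max_distance_bp)
    else:
        pairing = pair_closest_without_replacement(kept_a, kept_b, params.max_distance_bp)
    stage("pair", n_pairs=len(pairing))

    pairs_path = out / "pairs.tsv"
    pairing.to_frame().to_csv(pairs_path, sep="\t", index=False)
    manifest["outputs"]["pairs"] = str(pairs_path)

    grid = build_oxford_grid(pairing, maps["a"], maps["b"])
    grid_path = out / "grid_cells.tsv"
    grid.cell_counts().to_csv(grid_path, sep="\t", index=False)
    manifest["outputs"]["grid_cells"] = str(grid_path)
    points_path = out / "grid_points.tsv"
    grid.to_frame().to_csv(points_path, sep="\t", index=False)
    manifest["outputs"]["grid_points"] = str(points_path)
    if params.plot:
        plot_path = out / "grid.pdf"
        grid.plot(plot_path)
        manifest["outputs"]["plot"] = str(plot_path)
    stage("grid", n_cells=len(grid.cells), n_pairs=grid.n_pairs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
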