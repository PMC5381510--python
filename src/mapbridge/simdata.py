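"""Synthetic post-duplication genomes and linkage maps with known truth.

The generator emulates the data regime the pipeline targets: an ancestral
karyotype of acrocentric chromosomes undergoes whole genome duplication
(WGD), producing homeolog arm pairs (``i.1``/``i.2``); lineages on a species
tree then accumulate programmed fusions, fissions and inversions; each tip
emits a linkage map whose markers are (possibly mutated) substrings of the
reference genome.  A designated outgroup tip is non-duplicated: it keeps one
ancestral chromosome per pair and its markers match both homeologs wherever
the homeologs have not diverged.

Genome model (miniaturized but order-faithful):

* each post-WGD arm is one reference contig: marker-length windows separated
  by arm-specific random spacers;
* ``.1`` windows carry the ancestral sequence; ``.2`` windows are diverged
  copies, except a ``tetraploid_fraction`` of windows kept identical between
  homeologs (residual-tetraploidy-like regions).  Markers in those windows
  are ambiguous in duplicated species (dropped by standard filtering, like
  isoloci) and are exactly what lets outgroup markers hit both homeologs in
  homeolog mode;
* cM positions are proportional to position within the arm (optionally
  jittered then re-sorted): only marker order and proximity matter to every
  consumer of these maps, so recombination-rate heterogeneity is not
  modelled.

All randomness derives from the config seed; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mapbridge.errors import ConfigError, MapValidationError
from mapbridge.linkage_io import LinkageMap, MapMarker, write_map_table
from mapbridge.rearrangements import Karyotype, Phylogeny, canonical_pair

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    ``branch_events`` maps a branch label (tip name, comma-joined sorted
    clade tips, or "root") to an ordered list of events:
    ``("fusion", arm_x, arm_y)``, ``("fission", arm_x, arm_y)`` (split
    between two currently adjacent arms) or
    ``("inversion", arm, lo_frac, hi_frac)`` (reverse marker order within
    that fraction of the arm, inherited by all descendants).
    """

    seed: int = 0
    n_ancestral_chromosomes: int = 5
    markers_per_arm: int = 30
    marker_length_bp: int = 80
    spacer_length_bp: int = 120
    tetraploid_fraction: float = 0.3
    homeolog_divergence: float = 0.05
    tree_newick: str = "(outgroup,(sp_a,(sp_b,sp_c)));"
    outgroup: str | None = "outgroup"
    branch_events: dict[str, list[tuple]] = field(default_factory=dict)
    mutation_rate: float = 0.0
    dropout_rate: float = 0.0
    arm_cm: float = 75.0
    arm_gap_cm: float = 10.0
    cm_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tetraploid_fraction", "homeolog_divergence", "mutation_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_ancestral_chromosomes < 1 or self.markers_per_arm < 2:
            raise ConfigError("need >= 1 chromosome and >= 2 markers per arm")


@dataclass
class TruthSet:
    """Machine-readable ground truth accompanying one simulation."""

    species: list[str]
    outgroup: str | None
    karyotypes: dict[str, Karyotype]
    # species -> arm -> (lg, order index, cm_lo, cm_hi)
    arm_spans: dict[str, dict[str, tuple[str, int, float, float]]]
    events: list[dict]
    # species -> list of {lg, arm, cm_lo, cm_hi}
    inversions: dict[str, list[dict]]
    homeolog_pairs: list[tuple[str, str]]

    def lg_of(self, species: str, arm: str) -> str:
        return self.arm_spans[species][arm][0]

    def to_json(self) -> str:
        payload = {
            "species": self.species,
            "outgroup": self.outgroup,
            "karyotypes": {
                sp: k.lgs for sp, k in sorted(self.karyotypes.items())
            },
            "arm_spans": {
                sp: {a: list(v) for a, v in sorted(spans.items())}
                for sp, spans in sorted(self.arm_spans.items())
            },
            "events": self.events,
            "inversions": self.inversions,
            "homeolog_pairs": [list(p) for p in self.homeolog_pairs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]          # contig -> sequence
    maps: dict[str, LinkageMap]
    truth: TruthSet

    def write(self, out_dir) -> dict[str, str]:
        """Write genome FASTA, per-species map tables and truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        genome_path = out / "genome.fasta"
        with open(genome_path, "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n{self.genome[name]}\n")
        paths["genome"] = str(genome_path)
        for sp in sorted(self.maps):
            p = out / f"{sp}_map.tsv"
            write_map_table(self.maps[sp], p)
            paths[f"map:{sp}"] = str(p)
        truth_path = out / "truth.json"
        truth_path.write_text(self.truth.to_json())
        paths["truth"] = str(truth_path)
        return paths


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at ~rate; guarantees at least one change."""
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if hits.size == 0:
        hits = np.array([0])
    shift = rng.integers(1, 4, size=hits.size)
    idx = np.array([("ACGT".index(b) + s) % 4 for b, s in zip(arr[hits], shift)])
    arr[hits] = _BASES[idx]
    return "".join(arr)


def _build_genome(cfg: SimConfig, rng: np.random.Generator):
    """Returns (contigs, window_seqs, window_starts, tetraploid_windows).

    ``window_seqs[(arm, w)]`` is the marker-window sequence in that arm's
    contig; the ancestral (outgroup) sequence of window w equals the ``.1``
    copy.  ``tetraploid_windows[chrom]`` is the set of windows identical
    between homeologs.
    """
    contigs: dict[str, str] = {}
    window_seqs: dict[tuple[str, int], str] = {}
    window_starts: dict[tuple[str, int], int] = {}
    tetraploid: dict[int, set[int]] = {}
    W, L, S = cfg.markers_per_arm, cfg.marker_length_bp, cfg.spacer_length_bp
    n_tet = int(round(cfg.tetraploid_fraction * W))
    for chrom in range(1, cfg.n_ancestral_chromosomes + 1):
        ancestral = [_random_seq(rng, L) for _ in range(W)]
        tet = set(map(int, rng.choice(W, size=n_tet, replace=False))) if n_tet else set()
        tetraploid[chrom] = tet
        for copy_id in (1, 2):
            arm = f"{chrom}.{copy_id}"
            parts = []
            pos = 0
            for w in range(W):
                spacer = _random_seq(rng, S)
                parts.append(spacer)
                pos += S
                if copy_id == 1 or w in tet:
                    seq = ancestral[w]
                else:
                    seq = _diverge(rng, ancestral[w], cfg.homeolog_divergence)
                window_seqs[(arm, w)] = seq
                window_starts[(arm, w)] = pos
                parts.append(seq)
                pos += L
            parts.append(_random_seq(rng, S))
            contigs[f"arm_{arm}"] = "".join(parts)
    return contigs, window_seqs, window_starts, tetraploid


# ---------------------------------------------------------------------------
# karyotype histories
# ---------------------------------------------------------------------------

def _apply_events(
    state: dict, events: Sequence[tuple], branch: str, record: list[dict]
) -> None:
    lgs: list[list[str]] = state["lgs"]

    def locate(arm: str) -> int:
        for i, lg in enumerate(lgs):
            if arm in lg:
                return i
        raise ConfigError(f"event on branch {branch!r} references unknown arm {arm!r}")

    for ev in events:
        kind = ev[0]
        if kind == "fusion":
            _, x, y = ev
            i, j = locate(x), locate(y)
            if i == j:
                raise ConfigError(f"fusion {x}-{y} on {branch!r}: arms already linked")
            merged = lgs[i] + lgs[j]
            junction = canonical_pair(lgs[i][-1], lgs[j][0])
            for k in sorted((i, j), reverse=True):
                del lgs[k]
            lgs.append(merged)
            record.append({"branch": branch, "type": "fusion", "arms": list(junction)})
        elif kind == "fission":
            _, x, y = ev
            i = locate(x)
            lg = lgs[i]
            if y not in lg:
                raise ConfigError(f"fission {x}-{y} on {branch!r}: arms not co-located")
            ix, iy = lg.index(x), lg.index(y)
            if abs(ix - iy) != 1:
                raise ConfigError(f"fission {x}-{y} on {branch!r}: arms not adjacent")
            cut = max(ix, iy)
            del lgs[i]
            lgs.extend([lg[:cut], lg[cut:]])
            record.append(
                {"branch": branch, "type": "fission", "arms": list(canonical_pair(x, y))}
            )
        elif kind == "inversion":
            _, arm, lo, hi = ev
            locate(arm)
            if not 0.0 <= lo < hi <= 1.0:
                raise ConfigError(f"inversion window [{lo}, {hi}] outside [0, 1]")
            state["inversions"].append((arm, float(lo), float(hi)))
            record.append(
                {"branch": branch, "type": "inversion", "arm": arm, "lo": lo, "hi": hi}
            )
        else:
            raise ConfigError(f"unknown event type {kind!r} on branch {branch!r}")


def _tip_states(cfg: SimConfig, tree: Phylogeny) -> tuple[dict[str, dict], list[dict]]:
    arms = [
        f"{c}.{d}"
        for c in range(1, cfg.n_ancestral_chromosomes + 1)
        for d in (1, 2)
    ]
    known_branches = {tree.branch_label(i) for i in tree.postorder()}
    unknown = set(cfg.branch_events) - known_branches
    if unknown:
        raise ConfigError(f"branch_events reference unknown branches {sorted(unknown)}")
    if cfg.outgroup is not None:
        if cfg.outgroup not in tree.tips:
            raise ConfigError(f"outgroup {cfg.outgroup!r} is not a tree tip")
        if cfg.outgroup in cfg.branch_events:
            raise ConfigError("the non-duplicated outgroup cannot carry events")

    record: list[dict] = []
    tips: dict[str, dict] = {}

    def walk(node: int, state: dict) -> None:
        label = tree.branch_label(node)
        _apply_events(state, cfg.branch_events.get(label, ()), label, record)
        if tree.is_leaf(node):
            tips[next(iter(tree.clade(node)))] = state
            return
        for child in tree.children(node):
            walk(child, copy.deepcopy(state))

    walk(tree.root, {"lgs": [[a] for a in arms], "inversions": []})
    return tips, record


# ---------------------------------------------------------------------------
# map emission
# ---------------------------------------------------------------------------

def _emit_map(
    cfg: SimConfig,
    species: str,
    rng: np.random.Generator,
    lgs: list[list[str]],
    inversions: Sequence[tuple[str, float, float]],
    window_seqs: Mapping[tuple[str, int], str],
) -> tuple[LinkageMap, dict, list[dict]]:
    W = cfg.markers_per_arm
    inv_by_arm: dict[str, list[tuple[float, float]]] = {}
    for arm, lo, hi in inversions:
        inv_by_arm.setdefault(arm, []).append((lo, hi))

    markers: list[MapMarker] = []
    arm_spans: dict[str, tuple[str, int, float, float]] = {}
    inversion_truth: list[dict] = []
    for lg_idx, arm_list in enumerate(sorted(lgs, key=lambda l: [_arm_key(a) for a in l])):
        lg_name = f"{species}_LG{lg_idx + 1:02d}"
        for order, arm in enumerate(arm_list):
            offset = order * (cfg.arm_cm + cfg.arm_gap_cm)
            arm_spans[arm] = (lg_name, order, offset, offset + cfg.arm_cm)
            for lo, hi in inv_by_arm.get(arm, ()):
                inversion_truth.append(
                    {
                        "lg": lg_name,
                        "arm": arm,
                        "cm_lo": offset + lo * cfg.arm_cm,
                        "cm_hi": offset + hi * cfg.arm_cm,
                    }
                )
            for w in range(W):
                u_drop = rng.random()
                u_mut = rng.random(cfg.marker_length_bp)
                shift = rng.integers(1, 4, size=cfg.marker_length_bp)
                if u_drop < cfg.dropout_rate:
                    continue
                frac = (w + 0.5) / W
                for lo, hi in inv_by_arm.get(arm, ()):
                    if lo <= frac <= hi:
                        frac = lo + hi - frac
                        break
                cm = offset + frac * cfg.arm_cm
                if cfg.cm_jitter_sd:
                    cm = max(0.0, cm + rng.normal(0.0, cfg.cm_jitter_sd))
                seq = window_seqs[(arm, w)]
                if cfg.mutation_rate:
                    chars = list(seq)
                    for i in np.flatnonzero(u_mut < cfg.mutation_rate):
                        chars[i] = "ACGT"[("ACGT".index(chars[i]) + int(shift[i])) % 4]
                    seq = "".join(chars)
                markers.append(
                    MapMarker(
                        species_id=species,
                        linkage_group=lg_name,
                        position_cm=round(cm, 6),
                        marker_id=f"{species}.{arm}.m{w:03d}",
                        sequence=seq,
                    )
                )
    return LinkageMap(species_id=species, markers=markers), arm_spans, inversion_truth


def _arm_key(arm: str) -> tuple[int, int]:
    c, d = arm.split(".")
    return int(c), int(d)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig, out_dir=None) -> SimResult:
    """Run one simulation; optionally write all files to ``out_dir``."""
    rng = np.random.default_rng(cfg.seed)
    contigs, window_seqs, _window_starts, tetraploid = _build_genome(cfg, rng)
    tree = Phylogeny(cfg.tree_newick)
    tips, event_record = _tip_states(cfg, tree)

    maps: dict[str, LinkageMap] = {}
    karyotypes: dict[str, Karyotype] = {}
    arm_spans: dict[str, dict] = {}
    inversion_truth: dict[str, list[dict]] = {}
    for idx, species in enumerate(sorted(tips)):
        tip_rng = np.random.default_rng([cfg.seed, idx + 1])
        if species == cfg.outgroup:
            # non-duplicated: one acrocentric LG per ancestral chromosome,
            # ancestral (= .1) marker sequences
            lgs = [[f"{c}.1"] for c in range(1, cfg.n_ancestral_chromosomes + 1)]
            lmap, spans, _ = _emit_map(cfg, species, tip_rng, lgs, [], window_seqs)
            # relabel truth arms as ancestral chromosomes
            spans = {arm.split(".")[0]: v for arm, v in spans.items()}
            karyotypes[species] = Karyotype(
                species, {v[0]: [a] for a, v in sorted(spans.items())}
            )
            maps[species] = lmap
            arm_spans[species] = spans
            inversion_truth[species] = []
            continue
        state = tips[species]
        lmap, spans, inv_truth = _emit_map(
            cfg, species, tip_rng, state["lgs"], state["inversions"], window_seqs
        )
        maps[species] = lmap
        ordered_lgs: dict[str, list[str]] = {}
        for arm, (lg, order, _, _) in spans.items():
            ordered_lgs.setdefault(lg, []).append((order, arm))
        karyotypes[species] = Karyotype(
            species,
            {lg: [a for _, a in sorted(v)] for lg, v in sorted(ordered_lgs.items())},
        )
        arm_spans[species] = spans
        inversion_truth[species] = inv_truth

    truth = TruthSet(
        species=sorted(tips),
        outgroup=cfg.outgroup,
        karyotypes=karyotypes,
        arm_spans=arm_spans,
        events=event_record,
        inversions=inversion_truth,
        homeolog_pairs=[
            (f"{c}.1", f"{c}.2") for c in range(1, cfg.n_ancestral_chromosomes + 1)
        ],
    )
    result = SimResult(config=cfg, genome=contigs, maps=maps, truth=truth)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

_CLASSES = ("homology", "homeolog", "fusion", "fission", "inversion")


def score_recovery(
    truth_items: Mapping[str, set],
    called_items: Mapping[str, set],
    known_species: Sequence[str] | None = None,
):
    """Precision/recall per call class against truth item sets.

    Items are hashable tuples; classes outside the known five raise, as do
    items whose species token (first tuple element, for species-keyed
    classes) is not in ``known_species``.
    """
    import pandas as pd

    rows = []
    for cls in sorted(set(truth_items) | set(called_items)):
        if cls not in _CLASSES:
            raise MapValidationError(f"unknown call class {cls!r}")
        t = set(truth_items.get(cls, set()))
        c = set(called_items.get(cls, set()))
        if known_species is not None and cls in ("homology", "homeolog", "inversion"):
            for item in c:
                if isinstance(item, tuple) and item and item[0] not in known_species:
                    raise MapValidationError(
                        f"{cls} call references unknown species {item[0]!r}"
                    )
        tp = len(t & c)
        fp = len(c - t)
        fn = len(t - c)
        rows.append(
            {
                "class": cls,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["class", "tp", "fp", "fn", "precision", "recall"])
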