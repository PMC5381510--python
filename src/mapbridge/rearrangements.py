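"""Karyotype fusion/fission history by small parsimony on a phylogeny.

Each multi-arm linkage group of a species karyotype contributes its
consecutive chromosome-arm adjacencies (k - 1 adjacencies for a k-arm
group); an adjacency present in a species means those two ancestral arms are
fused there.  Treating each distinct arm pair as a binary character that is
ancestrally absent (the pre-duplication karyotype is acrocentric), fusion
gains and fission losses are placed on the tree by exact minimal-event
parsimony (gain cost = loss cost = 1).  Among minimal histories the engine
prefers fewer gains (single origin), then deeper gains, then a fixed
lexicographic order, so results are deterministic.

A per-character ``origin_policy`` can constrain the search to single-origin
("single") or multi-origin ("independent") histories; this supports encoding
curated placements for characters whose history the uniform rule cannot
decide (see docs/methods.md).

Classification: a gain retained (not subsequently lost) in >= 2 extant
species is a conserved fusion, otherwise species-specific; a loss on an
internal branch (>= 2 descendant tips) is a conserved fission, on a terminal
branch species-specific.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from mapbridge.errors import ConfigError, MapValidationError

ArmPair = tuple[str, str]


def canonical_pair(a: str, b: str) -> ArmPair:
    """Order-free identity of an arm adjacency."""
    if a == b:
        raise MapValidationError(f"self-adjacency of arm {a!r}")
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

@dataclass
class Karyotype:
    """Per linkage group, the ordered ancestral-arm content of one species."""

    species_id: str
    lgs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lg, arms in self.lgs.items():
            if not arms:
                raise MapValidationError(f"{self.species_id}/{lg}: empty linkage group")
            for arm in arms:
                if arm in seen:
                    raise MapValidationError(
                        f"{self.species_id}: arm {arm} occurs in more than one LG"
                    )
                seen.add(arm)

    @property
    def n_metacentric(self) -> int:
        return sum(1 for arms in self.lgs.values() if len(arms) >= 2)

    @property
    def n_acrocentric(self) -> int:
        return sum(1 for arms in self.lgs.values() if len(arms) == 1)


def extract_adjacencies(karyotype: Karyotype) -> list[ArmPair]:
    """Consecutive-arm adjacencies of every linkage group.

    A k-arm group [x1..xk] yields (x1,x2)...(x(k-1),xk); acrocentric groups
    yield nothing.  Pairs are returned in canonical (sorted) orientation.
    """
    out: list[ArmPair] = []
    for lg in sorted(karyotype.lgs):
        arms = karyotype.lgs[lg]
        out.extend(canonical_pair(a, b) for a, b in zip(arms, arms[1:]))
    return out


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree wrapper with branches addressed by clade tip sets.

    Terminal branches are labelled by the tip name; internal branches by the
    comma-joined sorted tip names of their clade; the branch above the root
    is labelled ``"root"``.
    """

    def __init__(self, newick: str):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self._nodes: list[tuple[frozenset, tuple[int, ...]]] = []  # postorder
        index: dict[int, int] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ConfigError("tree has an unlabelled tip")
                tips = frozenset({nd.taxon.label.replace(" ", "_")})
                kids: tuple[int, ...] = ()
            else:
                kids = tuple(index[id(c)] for c in nd.child_nodes())
                tips = frozenset().union(*(self._nodes[k][0] for k in kids))
            index[id(nd)] = len(self._nodes)
            self._nodes.append((tips, kids))
        self.root = len(self._nodes) - 1
        self.tips: frozenset = self._nodes[self.root][0]
        if len(self.tips) < 2:
            raise ConfigError("tree needs at least two tips")

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls(fh.read())

    def __len__(self) -> int:
        return len(self._nodes)

    def children(self, i: int) -> tuple[int, ...]:
        return self._nodes[i][1]

    def clade(self, i: int) -> frozenset:
        return self._nodes[i][0]

    def is_leaf(self, i: int) -> bool:
        return not self._nodes[i][1]

    def branch_label(self, i: int) -> str:
        if i == self.root:
            return "root"
        tips = sorted(self.clade(i))
        return tips[0] if len(tips) == 1 else ",".join(tips)

    def postorder(self) -> range:
        return range(len(self._nodes))

    def internal_nodes(self) -> list[int]:
        return [i for i in self.postorder() if not self.is_leaf(i)]


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    branch: str
    event_type: str        # "gain" | "loss"
    clade_size: int        # descendant tips of the branch


@dataclass
class FusionEvent:
    """Placed history of one arm-pair character."""

    arm_pair: ArmPair
    placements: list[Placement]
    retained_by_gain: list[frozenset]   # tips retaining each gain, same order as gains
    cost: int

    @property
    def gains(self) -> list[Placement]:
        return [p for p in self.placements if p.event_type == "gain"]

    @property
    def losses(self) -> list[Placement]:
        return [p for p in self.placements if p.event_type == "loss"]


def place_events(
    presence: Mapping[str, bool],
    tree: Phylogeny,
    origin: str | None = None,
) -> FusionEvent | None:
    """Exact small-parsimony placement of one binary fusion character.

    ``presence`` maps every tip name to whether the arm pair is fused there.
    The ancestral state above the root is fixed to absent, so a character
    present in all tips gains on the root branch.  ``origin`` may force
    "single" (exactly one gain) or "independent" (>= 2 gains).  Returns
    ``None`` for an all-absent character.

    The search enumerates all internal-state assignments (trees here are
    small), which makes the result exactly minimal by construction; tests
    cross-check the cost against an independent dynamic program.
    """
    unknown = set(presence) - set(tree.tips)
    if unknown:
        raise MapValidationError(f"presence vector references unknown tips {sorted(unknown)}")
    missing = set(tree.tips) - set(presence)
    if missing:
        raise MapValidationError(f"presence vector missing tips {sorted(missing)}")
    if origin not in (None, "single", "independent"):
        raise ConfigError(f"unknown origin policy {origin!r}")
    if not any(presence.values()):
        return None

    internals = tree.internal_nodes()
    if len(internals) > 20:
        raise ConfigError("tree too large for exhaustive placement (> 20 internal nodes)")

    leaf_state = {
        i: int(presence[next(iter(tree.clade(i)))])
        for i in tree.postorder()
        if tree.is_leaf(i)
    }

    best = None  # (cost, n_gains, depth_key, label_key, states)
    for combo in itertools.product((0, 1), repeat=len(internals)):
        states = dict(leaf_state)
        states.update(zip(internals, combo))
        gains, losses = [], []
        for i in tree.postorder():
            parent_state = 0 if i == tree.root else None
            for c in tree.children(i):
                if states[i] == 0 and states[c] == 1:
                    gains.append(c)
                elif states[i] == 1 and states[c] == 0:
                    losses.append(c)
            if parent_state == 0 and states[i] == 1:
                gains.append(i)  # gain on the branch above the root
        if origin == "single" and len(gains) != 1:
            continue
        if origin == "independent" and len(gains) < 2:
            continue
        cost = len(gains) + len(losses)
        # prefer: min cost -> fewer gains -> deeper gains (larger clades first)
        depth_key = tuple(sorted((-len(tree.clade(g)) for g in gains)))
        label_key = tuple(sorted(tree.branch_label(n) for n in gains + losses))
        key = (cost, len(gains), depth_key, label_key)
        if best is None or key < best[0]:
            best = (key, gains, losses, states)

    if best is None:
        raise ConfigError(f"no history satisfies origin policy {origin!r}")
    (cost, _, _, _), gains, losses, states = best

    placements = [
        Placement(tree.branch_label(n), "gain", len(tree.clade(n))) for n in gains
    ] + [
        Placement(tree.branch_label(n), "loss", len(tree.clade(n))) for n in losses
    ]

    # attribute each present tip to its nearest ancestral gain
    retained: list[set] = [set() for _ in gains]
    gain_index = {g: k for k, g in enumerate(gains)}

    def walk(i: int, active: int | None) -> None:
        if i in gain_index and states[i] == 1:
            active = gain_index[i]
        if states[i] == 0:
            active = None
        if tree.is_leaf(i):
            if active is not None and states[i] == 1:
                retained[active].add(next(iter(tree.clade(i))))
            return
        for c in tree.children(i):
            walk(c, active)

    walk(tree.root, None)
    return FusionEvent(
        arm_pair=("", ""),  # filled by caller when known
        placements=placements,
        retained_by_gain=[frozenset(r) for r in retained],
        cost=cost,
    )


# ---------------------------------------------------------------------------
# classification and the full analysis
# ---------------------------------------------------------------------------

@dataclass
class RearrangementSummary:
    conserved_fusions: int
    conserved_fissions: int
    species_specific_fusions: int
    species_specific_fissions: int

    def as_dict(self) -> dict[str, int]:
        return {
            "conserved_fusions": self.conserved_fusions,
            "conserved_fissions": self.conserved_fissions,
            "species_specific_fusions": self.species_specific_fusions,
            "species_specific_fissions": self.species_specific_fissions,
        }


def classify_and_count(
    events: Iterable[FusionEvent],
) -> tuple[RearrangementSummary, list[dict]]:
    """Tally conserved vs species-specific fusion/fission events.

    Returns the summary and a per-event ledger (one row per placed gain or
    loss) so every count can be audited.
    """
    ledger: list[dict] = []
    cf = cfi = sf = sfi = 0
    for ev in events:
        gains = ev.gains
        for k, g in enumerate(gains):
            retainers = ev.retained_by_gain[k]
            conserved = len(retainers) >= 2
            cf += conserved
            sf += not conserved
            ledger.append(
                {
                    "arm_pair": "-".join(ev.arm_pair),
                    "event": "fusion",
                    "branch": g.branch,
                    "clade_size": g.clade_size,
                    "retained_in": ",".join(sorted(retainers)),
                    "classification": "conserved" if conserved else "species_specific",
                }
            )
        for l in ev.losses:
            conserved = l.clade_size >= 2
            cfi += conserved
            sfi += not conserved
            ledger.append(
                {
                    "arm_pair": "-".join(ev.arm_pair),
                    "event": "fission",
                    "branch": l.branch,
                    "clade_size": l.clade_size,
                    "retained_in": "",
                    "classification": "conserved" if conserved else "species_specific",
                }
            )
    return RearrangementSummary(cf, cfi, sf, sfi), ledger


def infer_rearrangements(
    karyotypes: Mapping[str, Karyotype],
    tree: Phylogeny,
    origin_policy: Mapping[ArmPair, str] | None = None,
) -> tuple[list[FusionEvent], RearrangementSummary, list[dict]]:
    """Full fusion/fission analysis for a set of species karyotypes.

    Every distinct arm adjacency across the karyotypes becomes one binary
    character; each is placed on the tree by :func:`place_events` (honouring
    any per-character origin constraint) and the events are classified.
    """
    if set(karyotypes) != set(tree.tips):
        raise MapValidationError(
            f"karyotype species {sorted(karyotypes)} do not match tree tips "
            f"{sorted(tree.tips)}"
        )
    policy = {canonical_pair(*p): v for p, v in (origin_policy or {}).items()}
    presence: dict[ArmPair, set[str]] = {}
    for sp, k in karyotypes.items():
        for pair in extract_adjacencies(k):
            presence.setdefault(pair, set()).add(sp)

    events: list[FusionEvent] = []
    for pair in sorted(presence):
        vector = {tip: tip in presence[pair] for tip in tree.tips}
        ev = place_events(vector, tree, origin=policy.get(pair))
        if ev is None:
            continue
        ev.arm_pair = pair
        events.append(ev)
    summary, ledger = classify_and_count(events)
    return events, summary, ledger


# ---------------------------------------------------------------------------
# metacentric conservation support
# ---------------------------------------------------------------------------

def conserved_metacentric_check(
    pair_positions_cm: Sequence[float],
    centromere_interval: tuple[float, float] | None,
) -> bool | None:
    """Whether paired markers give evidence from both sides of the centromere.

    Confirming that a metacentric chromosome is completely present requires
    paired markers both below and above the centromere interval.  Returns
    ``None`` (unknown) when no centromere interval is available, ``False``
    with empty input.
    """
    if centromere_interval is None:
        return None
    if not pair_positions_cm:
        return False
    lo, hi = centromere_interval
    if hi < lo:
        raise MapValidationError(f"centromere interval reversed: {centromere_interval}")
    return any(p < lo for p in pair_positions_cm) and any(
        p > hi for p in pair_positions_cm
    )
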