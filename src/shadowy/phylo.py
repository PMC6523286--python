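"""Dollo-parsimony placement of retrocopy gains on a fixed species tree.

A retrocopy insertion is an essentially unrepeatable event at a given
locus, so its presence/absence across species is modeled under Dollo
parsimony: a homologous copy is gained exactly once and may subsequently
be lost any number of times.  Given a rooted species tree and a per-tip
presence profile, :func:`dollo_place` finds the gain branch (plus any
losses) minimizing the total event count.

Tips can additionally be marked ``unknown`` (no constraint — e.g. a copy
whose chromosomal location could not be established) or
``present_independent`` (a non-homologous copy arising from a separate
insertion, which carries its own mandatory gain on its terminal branch and
is excluded from the shared copy's objective).

Branches are identified by the comma-joined sorted tip labels of the clade
below them; the branch above the root (id = all tips) is a valid gain
location and represents presence in the common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

PRESENT = "present"
ABSENT = "absent"
PRESENT_INDEPENDENT = "present_independent"
UNKNOWN = "unknown"
STATES = {PRESENT, ABSENT, PRESENT_INDEPENDENT, UNKNOWN}


class SpeciesTree:
    """Rooted species tree with stable clade-based branch identifiers."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._node_by_id: dict[str, dendropy.Node] = {}
        self._depth: dict[str, int] = {}
        for node in tree.preorder_node_iter():
            tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
            bid = ",".join(tips)
            node.branch_id = bid
            self._node_by_id[bid] = node
            parent = node.parent_node
            self._depth[bid] = 0 if parent is None else self._depth[parent.branch_id] + 1

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        if len(tree.leaf_nodes()) == 0:
            raise ValueError("tree has no tips")
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip names must be unique")
        return cls(tree)

    @property
    def tip_names(self) -> list[str]:
        return sorted(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def branch_ids(self) -> list[str]:
        return list(self._node_by_id)

    def node(self, branch_id: str) -> dendropy.Node:
        if branch_id not in self._node_by_id:
            raise KeyError(f"no branch {branch_id!r} in tree")
        return self._node_by_id[branch_id]

    def tips_below(self, branch_id: str) -> set[str]:
        return set(branch_id.split(","))

    def depth(self, branch_id: str) -> int:
        return self._depth[branch_id]

    def preorder_branch_ids(self):
        for node in self._tree.preorder_node_iter():
            yield node.branch_id

    def same_tree(self, other: "SpeciesTree") -> bool:
        return set(self.branch_ids) == set(other.branch_ids)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class EventPlacement:
    """Gain (and loss) branches explaining a presence/absence profile."""

    gain_branches: tuple[str, ...]
    loss_branches: tuple[str, ...] = ()
    n_events: int = 0
    tree: SpeciesTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_events == 0:
            self.n_events = len(self.gain_branches) + len(self.loss_branches)


@dataclass
class ReconcileReport:
    gains_match: bool
    event_count_diff: int
    missing_gains: tuple[str, ...]
    extra_gains: tuple[str, ...]


def _validate_profile(tree: SpeciesTree, profile: dict[str, str]) -> None:
    tips = set(tree.tip_names)
    for tip, state in profile.items():
        if tip not in tips:
            raise KeyError(f"profile names tip {tip!r} absent from the tree")
        if state not in STATES:
            raise ValueError(f"unknown state {state!r} for tip {tip!r}")
    uncovered = tips - set(profile)
    if uncovered:
        raise ValueError(f"profile does not cover tips: {sorted(uncovered)}")


def _losses_under(node, present: set[str], absent: set[str]):
    """Minimal loss branches explaining the absences below a kept node.

    One loss per maximal subtree containing no present tip but at least
    one known-absent tip (unknown-only subtrees need no event).
    """
    if node.is_leaf():
        return []
    losses = []
    for child in node.child_nodes():
        ctips = set(child.branch_id.split(","))
        if ctips & present:
            losses.extend(_losses_under(child, present, absent))
        elif ctips & absent:
            losses.append(child.branch_id)
    return losses


def dollo_place(
    tree: SpeciesTree, profile: dict[str, str], allow_loss: bool = True
) -> EventPlacement:
    """Minimum-event Dollo placement of a copy's gain on the tree.

    The shared copy receives exactly one gain; ``allow_loss`` permits
    subsequent losses on any branch below it.  Among event-count ties the
    gain closest to the root wins (then lexicographic branch id), so the
    output is deterministic.  ``present_independent`` tips each force an
    extra gain on their own terminal branch and otherwise act as
    ``unknown`` for the shared copy.
    """
    _validate_profile(tree, profile)
    present = {t for t, s in profile.items() if s == PRESENT}
    absent = {t for t, s in profile.items() if s == ABSENT}
    indep = sorted(t for t, s in profile.items() if s == PRESENT_INDEPENDENT)

    gains = [t for t in indep]  # terminal branch id of a tip is the tip name
    losses: list[str] = []
    if present:
        best_key = None
        best: tuple[str, list[str]] | None = None
        for bid in tree.preorder_branch_ids():
            if not present <= tree.tips_below(bid):
                continue
            br_losses = _losses_under(tree.node(bid), present, absent)
            if br_losses and not allow_loss:
                continue
            key = (1 + len(br_losses), tree.depth(bid), bid)
            if best_key is None or key < best_key:
                best_key, best = key, (bid, br_losses)
        if best is None:
            raise ValueError("no feasible single-gain placement (losses disallowed)")
        gains.append(best[0])
        losses = best[1]
    return EventPlacement(
        gain_branches=tuple(gains), loss_branches=tuple(losses), tree=tree
    )


def implied_states(tree: SpeciesTree, placement: EventPlacement) -> dict[str, bool]:
    """Tip presence implied by applying the placement's gains and losses."""
    state = {t: False for t in tree.tip_names}
    lost = set(placement.loss_branches)
    for gid in placement.gain_branches:
        carried = tree.tips_below(gid)
        # remove tips under any loss branch nested below this gain
        for lid in lost:
            if tree.tips_below(lid) <= carried:
                carried = carried - tree.tips_below(lid)
        for t in carried:
            state[t] = True
    return state


def reconcile_with_truth(
    placement: EventPlacement, truth: EventPlacement
) -> ReconcileReport:
    """Compare an inferred placement against a simulation's true one."""
    if placement.tree is not None and truth.tree is not None:
        if not placement.tree.same_tree(truth.tree):
            raise ValueError("placements refer to different trees")
    got, want = set(placement.gain_branches), set(truth.gain_branches)
    return ReconcileReport(
        gains_match=got == want,
        event_count_diff=placement.n_events - truth.n_events,
        missing_gains=tuple(sorted(want - got)),
        extra_gains=tuple(sorted(got - want)),
    )
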