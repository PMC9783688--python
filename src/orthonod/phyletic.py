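"""Gain/loss history and phyletic-pattern classification of gene families.

Each orthogroup's presence/absence profile over the species-tree tips is
reconciled with the tree under a single-gain (Dollo) assumption: the family
is gained once on the edge above the most recent common ancestor of its
present tips and can only be lost thereafter.  Losses are then the maximal
absent subtrees inside the gain clade, which is the loss-minimal history for
a single gain.

On top of the reconstruction, orthogroups are classified into the phyletic
patterns of interest for nodulation evolution:

* ``clade_loss_punctuated`` — a focal clade wiped out by one or two loss
  events (e.g. a family lost once before the radiation of a subfamily);
* ``gradual_loss`` — many independent losses inside a focal clade with
  retained (present) species interleaved;
* ``clade_exclusive_gain`` — the family exists only inside a focal clade;
* ``expansion`` — copy-number amplification in one comparison group;
* ``background`` / ``absent_everywhere`` — everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_io import (
    OrthogroupCountMatrix,
    PanelError,
    SpeciesPanel,
    SpeciesTree,
)

PATTERN_CATEGORIES = (
    "absent_everywhere",
    "clade_exclusive_gain",
    "clade_loss_punctuated",
    "gradual_loss",
    "expansion",
    "background",
)


@dataclass
class DolloReconstruction:
    """Single-gain ancestral states and loss events for one profile.

    ``gain_clade`` is the tip set below the gain node (None for an empty
    profile); ``loss_subtrees`` are the tip sets of the maximal absent
    subtrees within the gain clade, one per loss event; ``node_states`` maps
    a canonical node key (tip label, or the sorted tip labels of an internal
    node joined by ``|``) to its reconstructed presence state.
    """

    gain_clade: frozenset[str] | None
    loss_subtrees: tuple[frozenset[str], ...]
    node_states: dict[str, bool]

    @property
    def n_losses(self) -> int:
        return len(self.loss_subtrees)

    @property
    def present_tips(self) -> frozenset[str]:
        return frozenset(
            k for k, v in self.node_states.items() if v and "|" not in k
        )


@dataclass
class PatternConfig:
    """Thresholds for phyletic-pattern calls (all configurable defaults)."""

    k_punctuated: int = 2          # max loss edges for a punctuated clade loss
    k_gradual: int = 4             # min loss edges for a gradual loss
    min_absent_fraction: float = 0.9
    gradual_min_absent_fraction: float = 0.5
    min_clade_size: int = 3        # smaller clades cannot anchor a loss call
    expansion_fold: float = 1.5
    presence_threshold: int = 1
    mode: str = "Viridiplantae"    # mode whose groups define expansion folds


@dataclass
class PhyleticPattern:
    orthogroup_id: str
    category: str
    focal_clade: str | None
    n_losses: int
    absent_tip_fraction_in_clade: float
    expansion_fold: float | None = None


@dataclass
class ExpansionSummary:
    orthogroup_id: str
    mean_count_group1: float
    mean_count_group2: float
    mean_count_outgroup: float
    fold_change: float  # nan when the group2 mean is zero


def presence_profile(
    matrix: OrthogroupCountMatrix,
    og: str,
    threshold: int = 1,
    tips: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Binarize one orthogroup's counts over tree tips (count >= threshold)."""
    if og not in matrix.counts.index:
        raise PanelError(f"unknown orthogroup {og!r}")
    tips = list(tips) if tips is not None else matrix.species_ids
    row = matrix.counts.loc[og]
    missing = [t for t in tips if t not in row.index]
    if missing:
        raise PanelError(f"tips absent from the count matrix: {', '.join(missing)}")
    return {t: bool(row[t] >= threshold) for t in tips}


def _node_key(leafset: frozenset[str]) -> str:
    if len(leafset) == 1:
        return next(iter(leafset))
    return "|".join(sorted(leafset))


def dollo_reconstruct(
    tree: SpeciesTree, profile: Mapping[str, bool]
) -> DolloReconstruction:
    """Reconstruct the loss-minimal single-gain history of a profile.

    The gain node is the MRCA of the present tips; inside the gain clade a
    node is present iff it retains at least one present tip, so every absent
    region collapses to its maximal subtree and contributes exactly one loss
    edge.  An empty profile has no gain and no losses.
    """
    dtree = tree.tree
    unknown = set(profile) - set(tree.tip_labels)
    if unknown:
        raise PanelError(f"profile tips not in the tree: {', '.join(sorted(unknown))}")

    leafsets: dict[int, frozenset[str]] = {}
    present_below: dict[int, bool] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            leafsets[id(node)] = frozenset([label])
            present_below[id(node)] = bool(profile.get(label, False))
        else:
            ls: set[str] = set()
            pb = False
            for ch in node.child_nodes():
                ls |= leafsets[id(ch)]
                pb = pb or present_below[id(ch)]
            leafsets[id(node)] = frozenset(ls)
            present_below[id(node)] = pb

    present_tips = {t for t, v in profile.items() if v}
    if not present_tips:
        states = {
            _node_key(leafsets[id(n)]): False for n in dtree.preorder_node_iter()
        }
        return DolloReconstruction(None, (), states)

    # gain node: the smallest-leafset node covering every present tip
    gain = dtree.seed_node
    for node in dtree.preorder_node_iter():
        ls = leafsets[id(node)]
        if present_tips <= ls and len(ls) < len(leafsets[id(gain)]):
            gain = node
    gain_set = leafsets[id(gain)]

    states: dict[str, bool] = {}
    losses: list[frozenset[str]] = []
    in_gain: set[int] = {id(gain)}
    for node in dtree.preorder_node_iter():
        nid = id(node)
        if node is not gain and (node.parent_node is None or id(node.parent_node) not in in_gain):
            states[_node_key(leafsets[nid])] = False
            continue
        if node is not gain:
            in_gain.add(nid)
        present = present_below[nid]
        states[_node_key(leafsets[nid])] = present
        parent = node.parent_node
        if (
            not present
            and node is not gain
            and parent is not None
            and id(parent) in in_gain
            and present_below[id(parent)]
        ):
            losses.append(leafsets[nid])
    # keep only maximal absent subtrees (children of a lost subtree are pruned
    # by the parent-present condition above, so `losses` is already maximal)
    return DolloReconstruction(gain_set, tuple(losses), states)


def _absent_fraction(profile: Mapping[str, bool], clade: Iterable[str]) -> float:
    clade = list(clade)
    if not clade:
        return 0.0
    return sum(1 for t in clade if not profile.get(t, False)) / len(clade)


def expansion_summary(
    matrix: OrthogroupCountMatrix,
    panel: SpeciesPanel,
    og: str,
    mode: str = "Viridiplantae",
) -> ExpansionSummary:
    """Raw-count group means and fold change for one orthogroup.

    Means are arithmetic means of per-species raw counts; ``fold_change`` is
    the group1/group2 ratio (nan when group2's mean is zero).  The outgroup
    mean covers species outside both mode groups.
    """
    if og not in matrix.counts.index:
        raise PanelError(f"unknown orthogroup {og!r}")
    g1, g2 = panel.groups(mode)
    if not g1 or not g2:
        raise PanelError(f"mode {mode!r} has an empty group")
    row = matrix.counts.loc[og]
    in_groups = set(g1) | set(g2)
    rest = [s for s in matrix.species_ids if s not in in_groups]
    m1 = float(row[g1].mean())
    m2 = float(row[g2].mean())
    m_out = float(row[rest].mean()) if rest else math.nan
    fold = m1 / m2 if m2 > 0 else math.nan
    return ExpansionSummary(og, m1, m2, m_out, fold)


def classify_pattern(
    rec: DolloReconstruction,
    tree: SpeciesTree,
    panel: SpeciesPanel,
    focal_clades: Mapping[str, Iterable[str]],
    matrix: OrthogroupCountMatrix,
    og: str,
    cfg: PatternConfig | None = None,
) -> PhyleticPattern:
    """Assign one phyletic category by the first matching rule.

    Rule order: absent_everywhere, clade_exclusive_gain, clade_loss_punctuated,
    gradual_loss, expansion, background.  When several focal clades satisfy a
    rule the largest clade wins (ties broken alphabetically).
    """
    cfg = cfg or PatternConfig()
    tipset = set(tree.tip_labels)
    clades: dict[str, list[str]] = {}
    for name, members in focal_clades.items():
        members = list(members)
        bad = [t for t in members if t not in tipset]
        if bad:
            raise PanelError(
                f"focal clade {name!r} names tips not in the tree: {', '.join(bad)}"
            )
        clades[name] = members

    profile = presence_profile(
        matrix, og, threshold=cfg.presence_threshold, tips=tree.tip_labels
    )
    present = {t for t, v in profile.items() if v}

    if not present:
        return PhyleticPattern(og, "absent_everywhere", None, 0, 1.0)

    def ranked(names: Iterable[str]) -> list[str]:
        return sorted(names, key=lambda n: (-len(clades[n]), n))

    # exclusive gain: the gain node sits inside a focal clade and nothing is
    # present outside it (most specific clade wins)
    gain_set = set(rec.gain_clade or ())
    gain_hits = [
        n
        for n, members in clades.items()
        if members and present <= set(members) and gain_set <= set(members)
    ]
    if gain_hits:
        name = sorted(gain_hits, key=lambda n: (len(clades[n]), n))[0]
        return PhyleticPattern(
            og, "clade_exclusive_gain", name, rec.n_losses,
            _absent_fraction(profile, clades[name]),
        )

    def clade_losses(members: list[str]) -> int:
        mset = set(members)
        return sum(1 for sub in rec.loss_subtrees if sub & mset)

    punct = []
    for name, members in clades.items():
        if len(members) < cfg.min_clade_size:
            continue
        frac = _absent_fraction(profile, members)
        n_cl = clade_losses(members)
        if frac >= cfg.min_absent_fraction and 1 <= n_cl <= cfg.k_punctuated:
            punct.append(name)
    if punct:
        name = ranked(punct)[0]
        return PhyleticPattern(
            og, "clade_loss_punctuated", name, rec.n_losses,
            _absent_fraction(profile, clades[name]),
        )

    gradual = []
    for name, members in clades.items():
        if len(members) < cfg.min_clade_size:
            continue
        n_cl = clade_losses(members)
        frac = _absent_fraction(profile, members)
        has_present = any(profile.get(t, False) for t in members)
        if (
            n_cl >= cfg.k_gradual
            and has_present
            and frac >= cfg.gradual_min_absent_fraction
        ):
            gradual.append(name)
    if gradual:
        name = ranked(gradual)[0]
        return PhyleticPattern(
            og, "gradual_loss", name, rec.n_losses,
            _absent_fraction(profile, clades[name]),
        )

    summ = expansion_summary(matrix, panel, og, mode=cfg.mode)
    if (
        not math.isnan(summ.fold_change)
        and summ.fold_change >= cfg.expansion_fold
        and summ.mean_count_group1 > 0
        and summ.mean_count_group2 > 0
    ):
        return PhyleticPattern(
            og, "expansion", None, rec.n_losses, 0.0, summ.fold_change
        )

    return PhyleticPattern(og, "background", None, rec.n_losses, 0.0)


def classify_orthogroups(
    matrix: OrthogroupCountMatrix,
    tree: SpeciesTree,
    panel: SpeciesPanel,
    focal_clades: Mapping[str, Iterable[str]],
    orthogroups: Sequence[str] | None = None,
    cfg: PatternConfig | None = None,
) -> list[PhyleticPattern]:
    """Dollo-reconstruct and classify a set of orthogroups."""
    cfg = cfg or PatternConfig()
    ogs = list(orthogroups) if orthogroups is not None else matrix.orthogroup_ids
    out = []
    for og in ogs:
        profile = presence_profile(
            matrix, og, threshold=cfg.presence_threshold, tips=tree.tip_labels
        )
        rec = dollo_reconstruct(tree, profile)
        out.append(
            classify_pattern(rec, tree, panel, focal_clades, matrix, og, cfg)
        )
    return out
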