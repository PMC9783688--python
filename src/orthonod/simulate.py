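"""Synthetic species panels and orthogroup count matrices with ground truth.

The generator emulates the statistical structure of a comparative
orthogroup study of nodulation: a rooted species tree over a panel dominated
by legumes (Fabaceae) plus outgroups, heavy-tailed per-species family sizes,
clade-structured gene losses and gains, group-specific copy-number
expansions, and transcriptome dropout (a truly present gene observed as
count zero because it was not expressed in the sampled tissue).

Default panel shape: 74 species, 35 nodulating / 39 non-nodulating, with the
nodulators confined to Fabaceae (a nodulating Caesalpinioideae subclade plus
all of Papilionoideae) — the group margins of the study design this emulates.

Background family sizes are negative binomial in the NB2 parameterization:
variance = mu + alpha * mu^2 (shape k = 1/alpha).  The defaults mu = 2,
alpha = 0.5 give a per-species zero mass of 0.25, i.e. a typical background
family is detected in ~75% of species before dropout.

Planted expansion families draw their baseline from a larger, tighter model
(mu = 10, alpha = 0.1 by default): copy-number expansions are a phenomenon
of large families that are consistently present across the panel, and a
group-wise fold change on such a family is what the count track is meant to
detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    OrthogroupCountMatrix,
    PanelError,
    SpeciesPanel,
    SpeciesRecord,
    SpeciesTree,
    write_gene_counts,
    write_species_metadata,
)
from .stats import DiffRepResult


@dataclass(frozen=True)
class CladeSpec:
    """One terminal clade of the synthetic tree."""

    name: str
    n_species: int
    status: str  # nodulating | non_nodulating | unknown
    order_label: str = ""
    family_label: str = ""
    subfamily_label: str = ""


#: Default 74-species panel: 35 nodulating, 39 non-nodulating.  The backbone
#: ladder is (outgroup,(basal eudicots,(other NFC orders,(Fabaceae)))) with
#: Fabaceae split into (Cercidoideae,(Detarioideae,((Caesalpinioideae
#: non-nodulating, Caesalpinioideae nodulating), Papilionoideae))).
DEFAULT_CLADES: tuple[CladeSpec, ...] = (
    CladeSpec("Outgroup", 2, "non_nodulating", order_label="Poales"),
    CladeSpec("BasalEudicots", 18, "non_nodulating", order_label="Other"),
    CladeSpec("NFCOther", 10, "non_nodulating", order_label="Rosales"),
    CladeSpec("Cercidoideae", 3, "non_nodulating", "Fabales", "Fabaceae", "Cercidoideae"),
    CladeSpec("Detarioideae", 2, "non_nodulating", "Fabales", "Fabaceae", "Detarioideae"),
    CladeSpec("CaesalpinioideaeNN", 4, "non_nodulating", "Fabales", "Fabaceae", "Caesalpinioideae"),
    CladeSpec("CaesalpinioideaeN", 9, "nodulating", "Fabales", "Fabaceae", "Caesalpinioideae"),
    CladeSpec("Papilionoideae", 26, "nodulating", "Fabales", "Fabaceae", "Papilionoideae"),
)


@dataclass(frozen=True)
class PlantedLoss:
    clade: str                   # clade name, or "nodulating"/"non_nodulating"
    kind: str = "punctuated"     # punctuated | gradual
    tip_loss_prob: float = 0.6   # per-tip loss probability (gradual only)


@dataclass(frozen=True)
class PlantedGain:
    clade: str


@dataclass(frozen=True)
class PlantedExpansion:
    group: str = "nodulating"    # tip set receiving the fold multiplier
    fold: float = 3.0


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters plus the seed; all randomness flows from `seed`."""

    seed: int
    clades: tuple[CladeSpec, ...] = DEFAULT_CLADES
    n_background_families: int = 1000
    family_mean: float = 2.0
    family_dispersion: float = 0.5       # NB2 alpha: var = mu + alpha*mu^2
    planted_losses: tuple[PlantedLoss, ...] = ()
    planted_gains: tuple[PlantedGain, ...] = ()
    planted_expansions: tuple[PlantedExpansion, ...] = ()
    expansion_base_mean: float = 10.0
    expansion_base_dispersion: float = 0.1
    dropout_prob: float = 0.05
    unassigned_fraction: float = 0.12    # extra genes outside orthogroups

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must lie in [0, 1]")
        for exp in self.planted_expansions:
            if exp.fold <= 1.0:
                raise ValueError("expansion fold multiplier must exceed 1")
        for loss in self.planted_losses:
            if not (0.0 <= loss.tip_loss_prob <= 1.0):
                raise ValueError("tip_loss_prob must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return sum(c.n_species for c in self.clades)


def default_scenario(seed: int, **overrides) -> SimulationScenario:
    """The study-shaped scenario: 20 complete losses in nodulators among
    1000 background families, plus 10 three-fold nodulator expansions."""
    params = dict(
        seed=seed,
        planted_losses=tuple(
            PlantedLoss("nodulating", "punctuated") for _ in range(20)
        ),
        planted_expansions=tuple(
            PlantedExpansion("nodulating", 3.0) for _ in range(10)
        ),
    )
    params.update(overrides)
    return SimulationScenario(**params)


def null_scenario(seed: int, **overrides) -> SimulationScenario:
    """No planted effects: background families only."""
    return SimulationScenario(seed=seed, **overrides)


def showcase_scenario(seed: int) -> SimulationScenario:
    """One of each phyletic pattern, for classification demonstrations."""
    return SimulationScenario(
        seed=seed,
        n_background_families=200,
        planted_losses=(
            PlantedLoss("nodulating", "punctuated"),
            PlantedLoss("Papilionoideae", "gradual", tip_loss_prob=0.6),
        ),
        planted_gains=(PlantedGain("Fabaceae"),),
        planted_expansions=(PlantedExpansion("nodulating", 3.0),),
    )


@dataclass
class PlantedTruth:
    """Ground truth: family id -> representation class and intended pattern."""

    rep_class: dict[str, str]        # background | under_represented | over_represented
    category: dict[str, str]         # intended phyletic category
    focal_clade: dict[str, str]      # planted clade name ("" for background)

    def families(self) -> list[str]:
        return list(self.rep_class)

    def planted(self) -> list[str]:
        return [f for f, c in self.rep_class.items() if c != "background"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orthogroup": list(self.rep_class),
                "rep_class": [self.rep_class[f] for f in self.rep_class],
                "category": [self.category[f] for f in self.rep_class],
                "focal_clade": [self.focal_clade[f] for f in self.rep_class],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlantedTruth":
        df = df.fillna("")
        return cls(
            rep_class=dict(zip(df["orthogroup"], df["rep_class"])),
            category=dict(zip(df["orthogroup"], df["category"])),
            focal_clade=dict(zip(df["orthogroup"], df["focal_clade"])),
        )


def _balanced_newick(labels: Sequence[str]) -> str:
    if len(labels) == 1:
        return labels[0]
    mid = (len(labels) + 1) // 2
    return f"({_balanced_newick(labels[:mid])},{_balanced_newick(labels[mid:])})"


def simulate_panel(scenario: SimulationScenario) -> tuple[SpeciesTree, SpeciesPanel]:
    """Build the synthetic species tree and metadata panel.

    The clade list nests as a ladder (each clade sister to everything after
    it), except that the last two clades are placed as sisters so the final
    pair (by default the two Caesalpinioideae blocks + Papilionoideae) forms
    the legume crown.  Tip labels are ``<CladeName>_<k>``.  The construction
    is fully deterministic for a given scenario.
    """
    if not scenario.clades:
        raise ValueError("scenario defines no clades")
    labels: dict[str, list[str]] = {}
    records: list[SpeciesRecord] = []
    for clade in scenario.clades:
        if clade.n_species < 1:
            raise ValueError(f"clade {clade.name!r} has no species")
        tips = [f"{clade.name}_{i + 1:02d}" for i in range(clade.n_species)]
        labels[clade.name] = tips
        for t in tips:
            records.append(
                SpeciesRecord(
                    species_id=t,
                    order_label=clade.order_label or None,
                    family_label=clade.family_label or None,
                    subfamily_label=clade.subfamily_label or None,
                    clade_label=clade.name,
                    nodulation_status=clade.status,
                )
            )
    subtrees = [_balanced_newick(labels[c.name]) for c in scenario.clades]
    # ladder from the outside in; the innermost two clades become sisters
    nested = subtrees[-1]
    if len(subtrees) >= 2:
        nested = f"({subtrees[-2]},{subtrees[-1]})"
    for sub in reversed(subtrees[:-2]):
        nested = f"({sub},{nested})"
    newick = nested + ";"
    tree = SpeciesTree.from_newick(newick)
    return tree, SpeciesPanel(records)


def _clade_tips(name: str, panel: SpeciesPanel) -> list[str]:
    if name in ("nodulating", "non_nodulating", "unknown"):
        tips = panel.tips_with_status(name)
    else:
        tips = panel.tips_in_clade(name)
    if not tips:
        raise PanelError(f"focal clade {name!r} has no tips")
    return tips


def _nb_draw(
    rng: np.random.Generator, mean: float, alpha: float, size
) -> np.ndarray:
    """Negative binomial draw, NB2 parameterization (var = mu + alpha*mu^2)."""
    if alpha <= 0:
        return np.full(size, round(mean), dtype=np.int64)
    k = 1.0 / alpha
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int64)


def simulate_counts(
    tree: SpeciesTree,
    panel: SpeciesPanel,
    scenario: SimulationScenario,
) -> tuple[OrthogroupCountMatrix, PlantedTruth]:
    """Draw the orthogroup count matrix and its planted ground truth.

    Families are generated in a fixed order (background, losses, gains,
    expansions), then relabelled ``OG0000001..`` in that order; dropout is
    applied to every cell last, and species totals are the assigned-gene
    column sums inflated by the unassigned-gene fraction.
    """
    rng = np.random.default_rng(scenario.seed)
    species = panel.species_ids
    n_sp = len(species)
    sp_index = {s: j for j, s in enumerate(species)}

    blocks: list[np.ndarray] = []
    rep_class: list[str] = []
    category: list[str] = []
    focal: list[str] = []

    bg = _nb_draw(
        rng, scenario.family_mean, scenario.family_dispersion,
        (scenario.n_background_families, n_sp),
    )
    blocks.append(bg)
    rep_class += ["background"] * scenario.n_background_families
    category += ["background"] * scenario.n_background_families
    focal += [""] * scenario.n_background_families

    for loss in scenario.planted_losses:
        tips = _clade_tips(loss.clade, panel)
        row = _nb_draw(rng, scenario.family_mean, scenario.family_dispersion, n_sp)
        idx = [sp_index[t] for t in tips]
        if loss.kind == "punctuated":
            row[idx] = 0
            cat = "clade_loss_punctuated"
        elif loss.kind == "gradual":
            lost = rng.random(len(idx)) < loss.tip_loss_prob
            row[np.asarray(idx)[lost]] = 0
            cat = "gradual_loss"
        else:
            raise ValueError(f"unknown planted loss kind {loss.kind!r}")
        blocks.append(row[None, :])
        rep_class.append("under_represented")
        category.append(cat)
        focal.append(loss.clade)

    for gain in scenario.planted_gains:
        tips = _clade_tips(gain.clade, panel)
        row = np.zeros(n_sp, dtype=np.int64)
        idx = [sp_index[t] for t in tips]
        draws = _nb_draw(
            rng, scenario.family_mean, scenario.family_dispersion, len(idx)
        )
        row[idx] = np.maximum(draws, 1)  # gained and retained inside the clade
        blocks.append(row[None, :])
        rep_class.append("over_represented")
        category.append("clade_exclusive_gain")
        focal.append(gain.clade)

    for exp in scenario.planted_expansions:
        tips = _clade_tips(exp.group, panel)
        row = _nb_draw(
            rng, scenario.expansion_base_mean, scenario.expansion_base_dispersion,
            n_sp,
        )
        idx = [sp_index[t] for t in tips]
        row[idx] = np.rint(row[idx] * exp.fold).astype(np.int64)
        blocks.append(row[None, :])
        rep_class.append("over_represented")
        category.append("expansion")
        focal.append(exp.group)

    counts = np.vstack(blocks)
    if scenario.dropout_prob > 0:
        mask = rng.random(counts.shape) < scenario.dropout_prob
        counts = np.where(mask, 0, counts)

    ids = [f"OG{i + 1:07d}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=ids, columns=species)
    colsums = df.sum(axis=0)
    totals = np.maximum(
        1, np.rint(colsums * (1.0 + scenario.unassigned_fraction)).astype(np.int64)
    )
    matrix = OrthogroupCountMatrix(df, pd.Series(totals, index=species))
    truth = PlantedTruth(
        rep_class=dict(zip(ids, rep_class)),
        category=dict(zip(ids, category)),
        focal_clade=dict(zip(ids, focal)),
    )
    return matrix, truth


@dataclass
class RecoveryReport:
    sensitivity: float               # planted families recovered (any track/mode)
    sensitivity_under: float
    sensitivity_over: float
    false_positives: int             # significant background families
    n_planted: int
    confusion: pd.DataFrame          # planted class x recovered direction counts


def evaluate_recovery(
    results: Iterable[DiffRepResult], truth: PlantedTruth
) -> RecoveryReport:
    """Compare significant calls with the planted truth.

    A family is recovered when any mode/track flags it significant with the
    planted direction; a false positive is a background family flagged in any
    mode or track.  Sensitivities are NaN when nothing was planted in that
    direction.
    """
    sig_dir: dict[str, set[str]] = {}
    for r in results:
        if r.significant_presence or r.significant_count:
            sig_dir.setdefault(r.orthogroup_id, set()).add(r.direction)

    recovered = {"under_represented": 0, "over_represented": 0}
    planted = {"under_represented": 0, "over_represented": 0}
    fp = 0
    cells: dict[tuple[str, str], int] = {}
    for fam, cls in truth.rep_class.items():
        directions = sig_dir.get(fam, set())
        called = "+".join(sorted(directions)) if directions else "not_significant"
        cells[(cls, called)] = cells.get((cls, called), 0) + 1
        if cls == "background":
            if directions:
                fp += 1
        else:
            planted[cls] += 1
            if cls in directions:
                recovered[cls] += 1

    def rate(cls: str) -> float:
        return recovered[cls] / planted[cls] if planted[cls] else math.nan

    n_planted = sum(planted.values())
    n_recovered = sum(recovered.values())
    confusion = (
        pd.Series(cells).rename_axis(["planted", "called"]).unstack(fill_value=0)
        if cells
        else pd.DataFrame()
    )
    return RecoveryReport(
        sensitivity=n_recovered / n_planted if n_planted else math.nan,
        sensitivity_under=rate("under_represented"),
        sensitivity_over=rate("over_represented"),
        false_positives=fp,
        n_planted=n_planted,
        confusion=confusion,
    )


def default_focal_clades(
    scenario: SimulationScenario, panel: SpeciesPanel
) -> dict[str, list[str]]:
    """Focal tip sets for classification: every terminal clade, the Fabaceae
    family, and the two status groups."""
    clades = {c.name: _clade_tips(c.name, panel) for c in scenario.clades}
    fab = [
        r.species_id for r in panel.records if r.family_label == "Fabaceae"
    ]
    if fab:
        clades["Fabaceae"] = fab
    for status in ("nodulating", "non_nodulating"):
        tips = panel.tips_with_status(status)
        if tips:
            clades[status] = tips
    return clades


def write_scenario_files(
    outdir: str | Path,
    tree: SpeciesTree,
    panel: SpeciesPanel,
    matrix: OrthogroupCountMatrix,
    truth: PlantedTruth,
) -> dict[str, Path]:
    """Write the exact input dialects panel_io reads, plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "Orthogroups.GeneCount.tsv",
        "metadata": outdir / "species_metadata.tsv",
        "tree": outdir / "species_tree.nwk",
        "truth": outdir / "planted_truth.tsv",
    }
    write_gene_counts(matrix, paths["counts"])
    write_species_metadata(panel, paths["metadata"])
    newick = tree.tree.as_string(schema="newick", suppress_rooting=True).strip()
    paths["tree"].write_text(newick + "\n")
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
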