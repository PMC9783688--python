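"""Differential representation of orthogroups between species groups.

Two statistical tracks, run per orthogroup and per comparison mode:

* presence/absence — a 2x2 contingency table (present/absent x group1/group2)
  tested with a two-sided Fisher exact test, summarized by the unconditional
  sample odds ratio a*d/(b*c);
* normalized count — per-species gene counts divided by each species' total
  annotated gene number, compared between groups with an independent-samples
  t test (pooled variance by default, Welch by flag).

Both tracks are Bonferroni-corrected across the orthogroups actually tested,
with a family-wise significance threshold of 0.001 by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .panel_io import OrthogroupCountMatrix, SpeciesPanel, PanelError

#: Relative tolerance for point-probability ties in the two-sided Fisher test.
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 present/absent x group table.

    ``a``: group1 species with the orthogroup present, ``b``: group1 absent,
    ``c``: group2 present, ``d``: group2 absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class TestConfig:
    """Tuning knobs for the differential-representation run."""

    alpha: float = 0.001
    presence_threshold: int = 1
    min_species_represented: int = 2
    t_variant: str = "pooled"  # or "welch"
    m_override: int | None = None
    modes: tuple[str, ...] = ("Fabales", "Viridiplantae")

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.presence_threshold < 1:
            raise ValueError("presence_threshold must be >= 1")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError("t_variant must be 'pooled' or 'welch'")


@dataclass
class DiffRepResult:
    """Per-(orthogroup, mode) outcome of both statistical tracks."""

    orthogroup_id: str
    mode: str
    table: ContingencyTable
    odds_ratio: float  # nan encodes "undefined" (both products zero)
    fisher_p_raw: float
    fisher_p_adj: float
    t_stat: float
    t_p_raw: float
    t_p_adj: float
    direction: str  # over_represented | under_represented
    significant_presence: bool
    significant_count: bool


def presence_table(
    matrix: OrthogroupCountMatrix,
    panel: SpeciesPanel,
    og: str,
    mode: str,
    cfg: TestConfig | None = None,
) -> ContingencyTable:
    """Contingency table for one orthogroup under one comparison mode."""
    cfg = cfg or TestConfig()
    if og not in matrix.counts.index:
        raise PanelError(f"unknown orthogroup {og!r}")
    g1, g2 = panel.groups(mode)
    if not g1 or not g2:
        raise PanelError(f"empty groups in mode {mode!r}")
    row = matrix.counts.loc[og]
    present1 = int((row[g1] >= cfg.presence_threshold).sum())
    present2 = int((row[g2] >= cfg.presence_threshold).sum())
    return ContingencyTable(present1, len(g1) - present1, present2, len(g2) - present2)


def sample_odds_ratio(t: ContingencyTable) -> float:
    """Unconditional sample odds ratio a*d/(b*c).

    Zero-product conventions: ``+inf`` when only the denominator product is
    zero, ``0`` when only the numerator product is zero, and ``nan``
    (undefined, reported as NA) when both are zero.
    """
    num = t.a * t.d
    den = t.b * t.c
    if den == 0 and num == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den


@lru_cache(maxsize=200_000)
def _fisher_cached(n1: int, n2: int, k: int, a: int) -> float:
    """Two-sided Fisher p for margins (n1, n2) with k total present, a in group1."""
    total = n1 + n2
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = np.arange(lo, hi + 1)
    logpmf = sps.hypergeom.logpmf(support, total, k, n1)
    obs = logpmf[a - lo]
    # point-probability method: sum over tables no more likely than observed,
    # with a relative tolerance for ties, accumulated in log space
    include = logpmf <= obs + math.log1p(FISHER_TIE_RTOL)
    p = float(np.exp(logsumexp(logpmf[include])))
    return min(1.0, max(0.0, p))


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by the point-probability method.

    Degenerate margins (an empty row or column) carry no information; they
    return p = 1 with a warning.
    """
    n1, n2 = t.a + t.b, t.c + t.d
    k, kc = t.a + t.c, t.b + t.d
    if n1 == 0 or n2 == 0 or k == 0 or kc == 0:
        warnings.warn(
            "degenerate contingency margins; returning p = 1 by convention",
            stacklevel=2,
        )
        return 1.0
    return _fisher_cached(n1, n2, k, t.a)


def normalize_counts(matrix: OrthogroupCountMatrix) -> pd.DataFrame:
    """Counts divided by each species' total annotated gene number."""
    totals = matrix.species_totals
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise PanelError(f"zero or negative total for species {bad!r}")
    return matrix.counts.div(totals.astype(float), axis=1)


def t_test_independent(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> tuple[float, float]:
    """Independent two-sample t test; positive t means mean(x) > mean(y).

    ``pooled`` uses the classic pooled-variance statistic (df = nx+ny-2);
    ``welch`` uses the Welch-Satterthwaite correction.  Two identical
    constant samples yield (t=0, p=1) rather than an indeterminate value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (math.copysign(math.inf, x.mean() - y.mean()), 0.0)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise adjustment min(1, p*m)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, p * m)


def _filtered_orthogroups(
    matrix: OrthogroupCountMatrix,
    species: list[str],
    cfg: TestConfig,
) -> pd.Index:
    """Orthogroups present in >= cfg.min_species_represented tested species."""
    present = (matrix.counts[species] >= cfg.presence_threshold).sum(axis=1)
    return matrix.counts.index[present >= cfg.min_species_represented]


def run_differential_representation(
    matrix: OrthogroupCountMatrix,
    panel: SpeciesPanel,
    cfg: TestConfig | None = None,
) -> list[DiffRepResult]:
    """Run both statistical tracks for every mode and qualifying orthogroup.

    Orthogroups observed in fewer than ``cfg.min_species_represented`` of the
    tested (status-assigned) species are filtered out before testing; the
    Bonferroni multiplier m is the number of orthogroups actually tested in
    each mode (per track) unless ``cfg.m_override`` is given.  Results are
    ordered by their smaller adjusted p-value.
    """
    cfg = cfg or TestConfig()
    normalized = normalize_counts(matrix)
    results: list[DiffRepResult] = []
    for mode in cfg.modes:
        g1, g2 = panel.groups(mode)
        if not g1 or not g2:
            raise PanelError(f"mode {mode!r} has an empty group")
        tested = _filtered_orthogroups(matrix, g1 + g2, cfg)
        if len(tested) == 0:
            continue
        m = cfg.m_override if cfg.m_override is not None else len(tested)

        sub = matrix.counts.loc[tested]
        pres1 = (sub[g1] >= cfg.presence_threshold).sum(axis=1).to_numpy()
        pres2 = (sub[g2] >= cfg.presence_threshold).sum(axis=1).to_numpy()

        norm1 = normalized.loc[tested, g1].to_numpy()
        norm2 = normalized.loc[tested, g2].to_numpy()
        mean1 = norm1.mean(axis=1)
        mean2 = norm2.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tres = sps.ttest_ind(
                norm1, norm2, axis=1, equal_var=(cfg.t_variant == "pooled")
            )
        t_stats = np.asarray(tres.statistic, dtype=float)
        t_ps = np.asarray(tres.pvalue, dtype=float)
        # zero pooled variance: identical groups -> (0, 1); separated -> (inf, 0)
        degenerate = ~np.isfinite(t_stats)
        t_stats[degenerate & (mean1 == mean2)] = 0.0
        t_ps[degenerate & (mean1 == mean2)] = 1.0
        sep = degenerate & (mean1 != mean2)
        t_stats[sep] = np.sign((mean1 - mean2)[sep]) * np.inf
        t_ps[sep] = 0.0

        for i, og in enumerate(tested):
            table = ContingencyTable(
                int(pres1[i]), len(g1) - int(pres1[i]),
                int(pres2[i]), len(g2) - int(pres2[i]),
            )
            fisher_p = fisher_exact_two_sided(table)
            fisher_adj = bonferroni_adjust(fisher_p, m)
            t_adj = bonferroni_adjust(min(1.0, float(t_ps[i])), m)
            direction = (
                "over_represented" if mean1[i] > mean2[i] else "under_represented"
            )
            results.append(
                DiffRepResult(
                    orthogroup_id=str(og),
                    mode=mode,
                    table=table,
                    odds_ratio=sample_odds_ratio(table),
                    fisher_p_raw=fisher_p,
                    fisher_p_adj=fisher_adj,
                    t_stat=float(t_stats[i]),
                    t_p_raw=float(min(1.0, t_ps[i])),
                    t_p_adj=t_adj,
                    direction=direction,
                    significant_presence=fisher_adj < cfg.alpha,
                    significant_count=t_adj < cfg.alpha,
                )
            )
    results.sort(
        key=lambda r: (min(r.fisher_p_adj, r.t_p_adj), r.orthogroup_id, r.mode)
    )
    return results


def results_to_frame(results: Iterable[DiffRepResult]) -> pd.DataFrame:
    """Flatten results into the Tables 3+4-shaped output frame."""
    rows = []
    for r in results:
        odds = r.odds_ratio
        rows.append(
            {
                "orthogroup": r.orthogroup_id,
                "mode": r.mode,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": "NA" if isinstance(odds, float) and math.isnan(odds) else odds,
                "fisher_p_raw": r.fisher_p_raw,
                "fisher_p_adj": r.fisher_p_adj,
                "t_stat": r.t_stat,
                "t_p_raw": r.t_p_raw,
                "t_p_adj": r.t_p_adj,
                "direction": r.direction,
                "significant_presence": r.significant_presence,
                "significant_count": r.significant_count,
            }
        )
    return pd.DataFrame(rows)
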