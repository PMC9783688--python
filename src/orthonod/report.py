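"""Result tables, matrix exports, and run provenance records."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .panel_io import OrthogroupCountMatrix, SpeciesPanel, SpeciesTree
from .phyletic import PhyleticPattern
from .stats import DiffRepResult, results_to_frame


def presence_absence_frame(results: Iterable[DiffRepResult]) -> pd.DataFrame:
    """Presence/absence-only view: one row per orthogroup with the reporting
    mode chosen as the mode with the smaller adjusted presence-track p
    (ties resolved to Viridiplantae)."""
    by_og: dict[str, list[DiffRepResult]] = {}
    for r in results:
        by_og.setdefault(r.orthogroup_id, []).append(r)
    rows = []
    for og, rs in by_og.items():
        best = min(
            rs, key=lambda r: (r.fisher_p_adj, 0 if r.mode == "Viridiplantae" else 1)
        )
        odds = best.odds_ratio
        rows.append(
            {
                "orthogroup": og,
                "present_group1": best.table.a,
                "absent_group1": best.table.b,
                "present_group2": best.table.c,
                "absent_group2": best.table.d,
                "odds_ratio": "NA" if isinstance(odds, float) and math.isnan(odds) else odds,
                "fisher_p_raw": best.fisher_p_raw,
                "fisher_p_adj": best.fisher_p_adj,
                "dataset": best.mode,
                "significant_presence": best.significant_presence,
            }
        )
    return pd.DataFrame(rows).sort_values("orthogroup").reset_index(drop=True)


def join_annotations(
    frame: pd.DataFrame, annotations: Mapping[str, str]
) -> pd.DataFrame:
    """Attach functional labels (orthogroup id -> label) to an output frame."""
    out = frame.copy()
    out["functional_annotation"] = out["orthogroup"].map(
        lambda og: annotations.get(og, "")
    )
    return out


def read_annotations(path: str | Path) -> dict[str, str]:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    id_col, label_col = df.columns[0], df.columns[1]
    return dict(zip(df[id_col], df[label_col].fillna("")))


def patterns_to_frame(patterns: Iterable[PhyleticPattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        rows.append(
            {
                "orthogroup": p.orthogroup_id,
                "category": p.category,
                "focal_clade": p.focal_clade or "",
                "n_losses": p.n_losses,
                "absent_fraction": p.absent_tip_fraction_in_clade,
                "fold_change": (
                    ""
                    if p.expansion_fold is None or math.isnan(p.expansion_fold)
                    else p.expansion_fold
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "orthogroup", "category", "focal_clade",
            "n_losses", "absent_fraction", "fold_change",
        ],
    )


def export_presence_matrix(
    matrix: OrthogroupCountMatrix,
    panel: SpeciesPanel,
    ogs: Sequence[str],
    tree: SpeciesTree | None = None,
) -> pd.DataFrame:
    """Long-format (orthogroup, species, count, status) table for heatmaps.

    Species follow tree tip-traversal order when a tree is given, panel order
    otherwise, so external plotting tools reproduce the phylogenetic layout.
    """
    missing = [og for og in ogs if og not in matrix.counts.index]
    if missing:
        raise ValueError(f"orthogroups not in matrix: {', '.join(missing)}")
    if tree is not None:
        species = [s for s in tree.tip_labels if s in matrix.counts.columns]
    else:
        species = [s for s in panel.species_ids if s in matrix.counts.columns]
    rows = []
    for og in ogs:
        row = matrix.counts.loc[og]
        for sp in species:
            status = panel.status_of(sp) if sp in panel else "unknown"
            rows.append(
                {"orthogroup": og, "species": sp, "count": int(row[sp]), "status": status}
            )
    return pd.DataFrame(rows, columns=["orthogroup", "species", "count", "status"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(
    outdir: str | Path,
    inputs: Mapping[str, str | Path | None],
    config: Mapping[str, object],
) -> Path:
    """Machine-readable record sufficient to re-run bit-identically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "software": f"orthonod {__version__}",
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
        "config": {k: _jsonable(v) for k, v in config.items()},
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return str(v)
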