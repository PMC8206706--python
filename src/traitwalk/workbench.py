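"""Experiment orchestration: mode grids, alternative starts, sweeps.

``run_grid`` executes a list of simulation configurations (one per grid
row), runs the phenotype census per mode, pools the per-type mean-correlation
signatures (optionally together with the empirical ancestral/evolved
signatures) for the bootstrap clustering meta-analysis, and records every
seed and config hash in a manifest so a study can be re-executed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .census import census, census_frame, membership_frame, replicate_signature
from .corrtable import CorrelationTable
from .scape import TraitScape
from .sim import MODES, RunResult, SimConfig, run

__all__ = ["GridRow", "StudyGrid", "standard_grid", "run_grid", "start_variants"]


@dataclass
class GridRow:
    """One study-grid entry: a mode plus config overrides."""

    name: str
    mode: str
    overrides: dict = field(default_factory=dict)
    start_kind: str | None = None  # None | equidistant_single | four_subpopulations


@dataclass
class StudyGrid:
    rows: list[GridRow]
    base_seed: int = 0

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("grid row names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyGrid":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rows = [
            GridRow(
                name=str(e.get("name", e["mode"])),
                mode=str(e["mode"]),
                overrides=dict(e.get("overrides", {})),
                start_kind=e.get("start_kind"),
            )
            for e in raw["rows"]
        ]
        return cls(rows=rows, base_seed=int(raw.get("base_seed", 0)))


def standard_grid(base_seed: int = 0, **overrides) -> StudyGrid:
    """The 9-mode grid: mixed plus the A1–A4 and E1–E4 bias sub-modes."""
    modes = ["mixed", "A1", "A2", "A3", "A4", "E1", "E2", "E3", "E4"]
    rows = [GridRow(name=m, mode=m, overrides=dict(overrides)) for m in modes]
    return StudyGrid(rows=rows, base_seed=base_seed)


def start_variants(
    scape: TraitScape, kind: str, angle_deg: float = 90.0
) -> list[tuple[float, np.ndarray]]:
    """Alternative starting phenotypes for the walk.

    ``equidistant_single`` rotates the start about the endpoint in the
    retained-axis plane (default 90 degrees) and lifts it back to trait space
    through the retained loadings, preserving the start-to-end distance
    exactly.  ``four_subpopulations`` returns four equally weighted starts at
    rotations of 45, 135, 225 and 315 degrees.
    """
    if scape.n_axes != 2:
        raise ValueError("start variants require a 2-D trait-scape")
    v = scape.start - scape.end
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("degenerate trait-scape: start equals end")
    axes = scape.loadings[:, : scape.n_axes]

    def rotated(theta_deg: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        point = scape.end + rot @ v
        return axes @ point  # lift: projection of this vector is exact

    if kind == "equidistant_single":
        return [(1.0, rotated(angle_deg))]
    if kind == "four_subpopulations":
        return [(0.25, rotated(a)) for a in (45.0, 135.0, 225.0, 315.0)]
    raise ValueError(f"unknown start variant kind {kind!r}")


def _pooled_signature_rows(
    name: str, types, corr_labels: list[str]
) -> list[dict]:
    rows = []
    for t in types:
        row = {"mode": name, "type": t.label, "label": f"{name}:{t.label}",
               "accessibility": t.accessibility, "rate": t.rate}
        for lab, v in zip(corr_labels, t.corr_mean):
            row[f"corr_{lab}"] = v
        rows.append(row)
    return rows


def run_grid(
    grid: StudyGrid,
    scape: TraitScape,
    corr_table: CorrelationTable | None = None,
    out_dir: str | Path | None = None,
    defaults: SimConfig | None = None,
    k_max: int = 8,
    include_empirical: bool = True,
) -> dict:
    """Execute every grid row; returns the study manifest.

    The manifest carries per-row seeds, config hashes, census tables and the
    pooled signature table.  Row failures are recorded and the grid
    continues.  When ``out_dir`` is given, census/membership/signature CSVs
    and the manifest JSON are written there.
    """
    defaults = defaults or SimConfig()
    manifest: dict = {"base_seed": grid.base_seed, "rows": [], "errors": {}}
    pooled_rows: list[dict] = []
    results_by_row: dict[str, list[RunResult]] = {}
    corr_labels: list[str] = []
    censuses: dict[str, list] = {}

    for i, row in enumerate(grid.rows):
        try:
            if row.mode not in MODES:
                raise ValueError(f"unknown mode {row.mode!r}")
            cfg_dict = defaults.to_dict()
            cfg_dict.update(row.overrides)
            cfg_dict["mode"] = row.mode
            cfg_dict["base_seed"] = grid.base_seed + 10_000 * i
            if row.start_kind:
                cfg_dict["start_spec"] = start_variants(scape, row.start_kind)
            cfg = SimConfig.from_dict(cfg_dict)
            results = run(cfg, scape, corr_table)
            results_by_row[row.name] = results
            types = census(results, k_max=k_max)
            censuses[row.name] = types
            corr_labels = types[0].corr_labels
            pooled_rows.extend(_pooled_signature_rows(row.name, types, corr_labels))
            manifest["rows"].append(
                {
                    "name": row.name,
                    "mode": row.mode,
                    "config": cfg.to_dict(),
                    "config_hash": cfg.config_hash(),
                    "seeds": [r.seed for r in results],
                    "n_types": len(types),
                }
            )
        except Exception as exc:  # partial failure: record and continue
            manifest["errors"][row.name] = f"{type(exc).__name__}: {exc}"
            manifest["rows"].append({"name": row.name, "mode": row.mode,
                                     "failed": True})
            continue

    if include_empirical and corr_table is not None and corr_labels:
        for cond in ("ancestral", "evolved"):
            sig = corr_table.signature(cond)
            row = {"mode": "empirical", "type": cond,
                   "label": f"empirical:{cond}",
                   "accessibility": float("nan"), "rate": float("nan")}
            for lab, v in zip(corr_labels, sig):
                row[f"corr_{lab}"] = v
            pooled_rows.append(row)

    pooled = pd.DataFrame(pooled_rows)
    manifest["n_pooled_signatures"] = len(pooled)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, types in censuses.items():
            census_frame(types).to_csv(out / f"census_{name}.csv", index=False)
            membership_frame(types).to_csv(out / f"membership_{name}.csv", index=False)
        pooled.to_csv(out / "pooled_signatures.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    manifest["pooled_signatures"] = pooled
    manifest["censuses"] = censuses
    manifest["results"] = results_by_row
    return manifest
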