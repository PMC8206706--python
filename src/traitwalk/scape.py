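"""Build a low-dimensional trait landscape ("trait-scape") from a trait table.

The input is a long-format table with one row per biological population
(culture): a genotype label, a replicate label, a condition (``ancestral`` or
``evolved``) and K numeric trait columns.  Evolved rows are standardized
(z-scored with evolved means and standard deviations), a PCA is fitted to the
standardized evolved matrix, and every row — ancestral rows included — is
projected onto the evolved axes.  The centroid of a focal genotype's ancestral
rows defines the start of the adaptive walk; the centroid of its evolved rows
defines the end (the high-fitness coordinate).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TraitScape",
    "trait_columns",
    "validate_trait_table",
    "standardize",
    "fit_trait_scape",
    "project",
    "project_table",
]

CONDITIONS = ("ancestral", "evolved")

_TRAIT_RE = re.compile(r"^trait_(\d+)$")


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Return the trait columns of a table, sorted by their numeric suffix."""
    cols = [(int(m.group(1)), c) for c in table.columns if (m := _TRAIT_RE.match(c))]
    return [c for _, c in sorted(cols)]


def validate_trait_table(table: pd.DataFrame) -> list[str]:
    """Validate the trait-table schema and return its trait columns.

    Raises ``ValueError`` on missing columns, unknown condition labels,
    fewer than two traits, or missing/non-finite trait values.
    """
    for col in ("genotype", "replicate", "condition"):
        if col not in table.columns:
            raise ValueError(f"trait table is missing required column {col!r}")
    traits = trait_columns(table)
    if len(traits) < 2:
        raise ValueError("trait table must contain at least 2 trait_<n> columns")
    cond = table["condition"].astype(str).str.lower()
    bad = sorted(set(cond) - set(CONDITIONS))
    if bad:
        raise ValueError(f"unknown condition labels {bad}; expected {CONDITIONS}")
    values = table[traits].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("trait table contains missing or non-finite trait values")
    return traits


def _normalized(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["condition"] = out["condition"].astype(str).str.lower()
    return out


@dataclass
class TraitScape:
    """Standardization parameters, PCA axes and walk endpoints.

    ``loadings`` is the K x K orthonormal matrix whose columns are principal
    axes ordered by decreasing explained variance; ``start``/``end`` live in
    the retained ``n_axes``-dimensional axis space and ``start_traits`` is the
    full standardized K-vector at the start.
    """

    mu: np.ndarray
    sigma: np.ndarray
    loadings: np.ndarray
    var_explained: np.ndarray
    n_axes: int
    start: np.ndarray
    start_traits: np.ndarray
    end: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    focal_genotype: str = ""

    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]

    def project(self, traits: np.ndarray) -> np.ndarray:
        return project(self, traits)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "loadings": self.loadings.tolist(),  # row-major, rows = traits
            "var_explained": self.var_explained.tolist(),
            "n_axes": int(self.n_axes),
            "start": self.start.tolist(),
            "start_traits": self.start_traits.tolist(),
            "end": self.end.tolist(),
            "trait_names": list(self.trait_names),
            "focal_genotype": self.focal_genotype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitScape":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            var_explained=np.asarray(d["var_explained"], dtype=float),
            n_axes=int(d["n_axes"]),
            start=np.asarray(d["start"], dtype=float),
            start_traits=np.asarray(d["start_traits"], dtype=float),
            end=np.asarray(d["end"], dtype=float),
            trait_names=list(d.get("trait_names", [])),
            focal_genotype=str(d.get("focal_genotype", "")),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TraitScape":
        return cls.from_dict(json.loads(Path(path).read_text()))


def standardize(
    table: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Z-score every row using means/sds of the *evolved* rows only.

    Returns ``(standardized table, mu, sigma)``.  ``ddof=0`` is the population
    standard-deviation convention (default); pass ``ddof=1`` for the sample
    convention.  A zero-variance evolved trait is rejected by name.
    """
    traits = validate_trait_table(table)
    table = _normalized(table)
    evolved = table.loc[table["condition"] == "evolved", traits]
    if len(evolved) < 2:
        raise ValueError("need at least 2 evolved rows to standardize")
    mu = evolved.to_numpy(dtype=float).mean(axis=0)
    sigma = evolved.to_numpy(dtype=float).std(axis=0, ddof=ddof)
    for name, s in zip(traits, sigma):
        if not s > 0:
            raise ValueError(f"trait {name!r} has zero variance over evolved rows")
    out = table.copy()
    out[traits] = (table[traits].to_numpy(dtype=float) - mu) / sigma
    return out, mu, sigma


def fit_trait_scape(
    table: pd.DataFrame,
    focal_genotype: str,
    n_axes: int = 2,
    ddof: int = 0,
) -> TraitScape:
    """Standardize, fit PCA axes on evolved rows, and fix walk endpoints.

    Loadings are the right singular vectors of the standardized evolved matrix
    (equivalently, eigenvectors of the evolved correlation matrix).  Each
    loading column is flipped so its largest-magnitude entry is positive,
    which makes the decomposition reproducible across platforms.
    """
    traits = validate_trait_table(table)
    k = len(traits)
    if not 1 <= n_axes <= k:
        raise ValueError(f"n_axes must be in [1, {k}], got {n_axes}")
    std, mu, sigma = standardize(table, ddof=ddof)
    focal = str(focal_genotype)
    for cond in CONDITIONS:
        sub = std[(std["genotype"].astype(str) == focal) & (std["condition"] == cond)]
        if len(sub) == 0:
            raise ValueError(f"focal genotype {focal!r} has no {cond} rows")

    x = std.loc[std["condition"] == "evolved", traits].to_numpy(dtype=float)
    # Columns of x already have mean zero; eigenvectors of X'X are the PCA
    # axes (identical to the right singular vectors of x).
    evals, evecs = np.linalg.eigh(x.T @ x)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order]
    # Deterministic sign convention: largest-|entry| of each column positive.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var_explained = evals / np.sum(evals)

    is_focal = std["genotype"].astype(str) == focal
    anc = std.loc[is_focal & (std["condition"] == "ancestral"), traits]
    evo = std.loc[is_focal & (std["condition"] == "evolved"), traits]
    start_traits = anc.to_numpy(dtype=float).mean(axis=0)
    axes = loadings[:, :n_axes]
    start = axes.T @ start_traits
    end = axes.T @ evo.to_numpy(dtype=float).mean(axis=0)

    return TraitScape(
        mu=mu,
        sigma=sigma,
        loadings=loadings,
        var_explained=var_explained,
        n_axes=n_axes,
        start=start,
        start_traits=start_traits,
        end=end,
        trait_names=traits,
        focal_genotype=focal,
    )


def project(scape: TraitScape, traits: np.ndarray) -> np.ndarray:
    """Project standardized trait vectors onto the retained axes.

    Accepts a single K-vector or an (n, K) matrix; the projection is linear.
    """
    arr = np.asarray(traits, dtype=float)
    k = scape.n_traits
    if arr.shape[-1] != k:
        raise ValueError(f"expected trait vectors of length {k}, got {arr.shape[-1]}")
    return arr @ scape.loadings[:, : scape.n_axes]


def project_table(scape: TraitScape, table: pd.DataFrame) -> pd.DataFrame:
    """Standardize a trait table with the scape's mu/sigma and project it.

    Returns one row per input culture with genotype/replicate/condition and
    the retained-axis coordinates ``pc1..pc{n_axes}``.
    """
    traits = validate_trait_table(table)
    if traits != scape.trait_names:
        raise ValueError("trait columns do not match the fitted trait-scape")
    table = _normalized(table)
    z = (table[traits].to_numpy(dtype=float) - scape.mu) / scape.sigma
    coords = project(scape, z)
    out = table[["genotype", "replicate", "condition"]].copy()
    for j in range(scape.n_axes):
        out[f"pc{j + 1}"] = coords[:, j]
    return out
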