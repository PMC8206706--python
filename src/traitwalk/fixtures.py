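"""Synthetic trait tables with known ground truth.

Trait tables are drawn from per-(genotype, condition) multivariate Gaussians
with user-specified means, standard deviations and target correlation
matrices.  Target matrices are repaired to the nearest positive semidefinite
correlation matrix (eigenvalue clipping followed by rescaling to unit
diagonal) before sampling, so mildly inconsistent pairwise targets are
accepted.  ``make_reference_fixture`` packages a 5-genotype, 4-trait table
built so that the evolved PCA has two dominant axes and the focal genotype's
ancestral and evolved centroids are well separated, together with ranked
ancestral/evolved correlation tables for the bias initialization modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .corrtable import CorrelationTable
from .pairs import canonical_pairs, pair_labels
from .scape import fit_trait_scape

__all__ = [
    "GroupSpec",
    "FixtureSpec",
    "nearest_psd_corr",
    "make_trait_table",
    "make_reference_fixture",
]


@dataclass
class GroupSpec:
    """Gaussian parameters for one (genotype, condition) cell."""

    mean: np.ndarray
    sd: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        k = self.mean.size
        if self.sd.shape != (k,) or self.corr.shape != (k, k):
            raise ValueError("inconsistent mean/sd/corr shapes")
        if np.any(self.sd <= 0):
            raise ValueError("trait sds must be positive")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("target correlation matrix must have unit diagonal")


@dataclass
class FixtureSpec:
    """Full sampling design: groups keyed by (genotype, condition)."""

    n_traits: int
    replicates: int
    groups: dict[tuple[str, str], GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        for (g, cond), spec in self.groups.items():
            if cond not in ("ancestral", "evolved"):
                raise ValueError(f"unknown condition {cond!r} for genotype {g!r}")
            if spec.mean.size != self.n_traits:
                raise ValueError(f"group {(g, cond)} has wrong trait count")

    @classmethod
    def from_yaml(cls, path: str) -> "FixtureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = {}
        for entry in raw["groups"]:
            key = (str(entry["genotype"]), str(entry["condition"]).lower())
            groups[key] = GroupSpec(
                mean=np.asarray(entry["mean"], dtype=float),
                sd=np.asarray(entry["sd"], dtype=float),
                corr=np.asarray(entry["corr"], dtype=float),
            )
        return cls(
            n_traits=int(raw["n_traits"]),
            replicates=int(raw["replicates"]),
            groups=groups,
            seed=int(raw.get("seed", 0)),
        )


def nearest_psd_corr(corr: np.ndarray, min_eig: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal.

    A no-op (up to float fuzz) for inputs that are already PSD.
    """
    c = np.asarray(corr, dtype=float)
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= min_eig:
        return c.copy()
    vals = np.clip(vals, max(min_eig, 1e-12), None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def make_trait_table(spec: FixtureSpec) -> pd.DataFrame:
    """Sample a long-format trait table; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    tcols = [f"trait_{i + 1}" for i in range(spec.n_traits)]
    for (genotype, condition), g in sorted(spec.groups.items()):
        corr = nearest_psd_corr(g.corr)
        cov = corr * np.outer(g.sd, g.sd)
        draws = rng.multivariate_normal(g.mean, cov, size=spec.replicates,
                                        method="svd")
        for rep in range(spec.replicates):
            row = {"genotype": genotype, "replicate": f"r{rep + 1}",
                   "condition": condition}
            row.update(dict(zip(tcols, draws[rep])))
            rows.append(row)
    return pd.DataFrame(rows)


def _corr_from_pairs(k: int, values: dict[str, float], default: float = 0.0) -> np.ndarray:
    labels = pair_labels(k)
    c = np.full((k, k), default)
    np.fill_diagonal(c, 1.0)
    for lab, (i, j) in zip(labels, canonical_pairs(k)):
        r = values.get(lab, default)
        c[i, j] = r
        c[j, i] = r
    return c


# Two orthogonal-ish trait patterns spanning the plane of between-genotype
# variation; they keep the first two evolved PCA axes dominant by design.
_U = np.array([1.0, 0.75, -0.65, 0.5])
_V = np.array([0.3, -0.6, 0.55, 0.9])

# Plane coefficients (a, b) per genotype: evolved means = a*U + b*V.
_EVOLVED_AB = {
    "G1": (1.4, 0.5),
    "G2": (-1.2, 0.4),
    "G3": (0.3, -1.2),
    "G4": (-0.6, -0.8),
    "G5": (0.1, 1.1),
}

# Ancestral correlations: four significant pairs ranked 1..4, opposed in
# sign to the landscape's dominant adaptive archetype (maladaptive bias).
_ANCESTRAL_SIG = {"2v4": (-0.89, 1), "3v4": (0.54, 2), "1v2": (0.35, 3),
                  "1v4": (-0.25, 4)}
_ANCESTRAL_REST = {"1v3": 0.10, "2v3": 0.08}

# Evolved correlations: the all-positive moderate-correlation archetype that
# dominates adaptive walks on this landscape (bias aligned with selection).
_EVOLVED_SIG = {"1v2": (0.66, 1), "1v4": (0.64, 2), "1v3": (0.52, 3),
                "2v4": (0.51, 4)}
_EVOLVED_REST = {"2v3": 0.46, "3v4": 0.38}

_WITHIN_SD = 0.4


def make_reference_fixture(
    replicates: int = 6, seed: int = 2021
) -> tuple[pd.DataFrame, CorrelationTable]:
    """The packaged 5-genotype / 4-trait fixture plus its correlation table.

    The evolved sampling correlations and the evolved correlation-table
    entries follow the landscape's dominant adaptive archetype, so
    evolved-bias starts are aligned with the walk; the ancestral entries
    oppose it, making ancestral-bias starts maladaptive.
    """
    k = 4
    labels = pair_labels(k)
    evolved_values = {**{lab: r for lab, (r, _) in _EVOLVED_SIG.items()},
                      **_EVOLVED_REST}
    anc_values = {**{lab: r for lab, (r, _) in _ANCESTRAL_SIG.items()},
                  **_ANCESTRAL_REST}
    evolved_corr = nearest_psd_corr(_corr_from_pairs(k, evolved_values))
    ancestral_corr = nearest_psd_corr(_corr_from_pairs(k, anc_values))

    groups: dict[tuple[str, str], GroupSpec] = {}
    sd = np.full(k, _WITHIN_SD)
    for g, (a, b) in _EVOLVED_AB.items():
        evolved_mean = a * _U + b * _V
        # Ancestral populations sit far back along the dominant pattern.
        ancestral_mean = evolved_mean - 2.4 * _U - 1.1 * _V
        groups[(g, "evolved")] = GroupSpec(evolved_mean, sd, evolved_corr)
        groups[(g, "ancestral")] = GroupSpec(ancestral_mean, sd, ancestral_corr)

    spec = FixtureSpec(n_traits=k, replicates=replicates, groups=groups, seed=seed)
    table = make_trait_table(spec)

    ancestral = {}
    evolved = {}
    for lab in labels:
        if lab in _ANCESTRAL_SIG:
            r, rank = _ANCESTRAL_SIG[lab]
            ancestral[lab] = (r, True, rank)
        else:
            ancestral[lab] = (_ANCESTRAL_REST[lab], False, None)
        if lab in _EVOLVED_SIG:
            r, rank = _EVOLVED_SIG[lab]
            evolved[lab] = (r, True, rank)
        else:
            evolved[lab] = (_EVOLVED_REST[lab], False, None)
    corr_table = CorrelationTable.from_values(k, ancestral, evolved)
    return table, corr_table
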