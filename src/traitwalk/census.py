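"""Identify emergent population types across replicate runs.

Each replicate is summarized by its *signature*: the mean of every pairwise
trait correlation over the final population.  Signatures are clustered with
UPGMA on Euclidean distance; the cluster count is chosen by maximum mean
silhouette (one single type when the best silhouette falls below a
configurable threshold).  A type's *accessibility* is the fraction of
replicates assigned to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import silhouette_score

from .msboot import upgma
from .sim import RunResult

__all__ = [
    "PhenotypeType",
    "replicate_signature",
    "census",
    "adaptation_rate",
    "fitness_auc",
    "census_frame",
    "membership_frame",
]


@dataclass
class PhenotypeType:
    """One emergent population type over a set of member replicates."""

    label: str
    member_replicates: list[int]
    accessibility: float
    corr_mean: np.ndarray
    corr_sd: np.ndarray
    trait_mean: np.ndarray
    trait_sd: np.ndarray
    rate: float
    rate_auc: float = float("nan")
    corr_labels: list[str] = field(default_factory=list)


def replicate_signature(result: RunResult) -> np.ndarray:
    """Mean final-population correlation vector of one replicate."""
    corr = result.final_corr()
    if corr.shape[0] == 0:
        raise ValueError("replicate has an empty final population")
    return corr.mean(axis=0)


def adaptation_rate(
    trajectory: np.ndarray, plateau_frac: float = 0.1, level: float = 0.95
) -> float:
    """1 / (first generation at ``level`` x plateau), in generations^-1.

    The plateau is the mean fitness over the final ``plateau_frac`` of the
    trajectory.  If the threshold is already met at generation 0 the rate is
    guarded to 1.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.size < 2:
        raise ValueError("trajectory must have at least 2 generations")
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory contains non-finite values")
    tail = max(1, int(np.ceil(plateau_frac * traj.size)))
    plateau = traj[-tail:].mean()
    hits = np.nonzero(traj >= level * plateau)[0]
    t95 = int(hits[0]) if hits.size else traj.size - 1
    return 1.0 if t95 == 0 else 1.0 / t95


def fitness_auc(trajectory: np.ndarray) -> float:
    """Mean fitness over the walk — an area-under-curve rate alternative."""
    traj = np.asarray(trajectory, dtype=float)
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory contains non-finite values")
    return float(traj.mean())


def _choose_k(signatures: np.ndarray, k_max: int, threshold: float) -> np.ndarray:
    """Cluster labels (0-based) via UPGMA + silhouette model selection."""
    n = signatures.shape[0]
    if np.allclose(signatures, signatures[0], atol=1e-12):
        return np.zeros(n, dtype=int)
    tree = upgma(signatures)
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(tree.linkage, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(signatures, labels, metric="euclidean")
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels - 1
    if best_k == 1 or best_score < threshold:
        return np.zeros(n, dtype=int)
    return best_labels


def census(
    results: list[RunResult],
    k_max: int = 8,
    silhouette_threshold: float = 0.25,
) -> list[PhenotypeType]:
    """Partition replicates into emergent population types.

    Types are labelled ``Pop-A``, ``Pop-B``, ... by decreasing accessibility.
    Per-type correlation/trait moments are pooled over all individuals of all
    member replicates; the adaptation rate is computed on the member-averaged
    mean-fitness trajectory.
    """
    if len(results) < 2:
        raise ValueError("census needs at least 2 replicates")
    signatures = np.vstack([replicate_signature(r) for r in results])
    labels = _choose_k(signatures, k_max, silhouette_threshold)

    corr_cols = [c for c in results[0].final.columns if c.startswith("corr_")]
    sizes = {c: np.sum(labels == c) for c in np.unique(labels)}
    order = sorted(sizes, key=lambda c: (-sizes[c], c))

    types: list[PhenotypeType] = []
    for rank, c in enumerate(order):
        members = [i for i in range(len(results)) if labels[i] == c]
        corr = np.vstack([results[i].final_corr() for i in members])
        traits = np.vstack([results[i].final_traits() for i in members])
        traj = np.mean([results[i].mean_fitness for i in members], axis=0)
        types.append(
            PhenotypeType(
                label=f"Pop-{chr(ord('A') + rank)}",
                member_replicates=members,
                accessibility=len(members) / len(results),
                corr_mean=corr.mean(axis=0),
                corr_sd=corr.std(axis=0),
                trait_mean=traits.mean(axis=0),
                trait_sd=traits.std(axis=0),
                rate=adaptation_rate(traj) if traj.size >= 2 else float("nan"),
                rate_auc=fitness_auc(traj),
                corr_labels=[c.removeprefix("corr_") for c in corr_cols],
            )
        )
    return types


def census_frame(types: list[PhenotypeType]) -> pd.DataFrame:
    """Tabular census: one row per type with accessibility, rate, moments."""
    rows = []
    for t in types:
        row: dict[str, object] = {
            "type": t.label,
            "n_replicates": len(t.member_replicates),
            "accessibility": t.accessibility,
            "rate": t.rate,
            "rate_auc": t.rate_auc,
        }
        labs = t.corr_labels or [str(i + 1) for i in range(t.corr_mean.size)]
        for lab, m, s in zip(labs, t.corr_mean, t.corr_sd):
            row[f"corr_mean_{lab}"] = m
            row[f"corr_sd_{lab}"] = s
        for i, (m, s) in enumerate(zip(t.trait_mean, t.trait_sd), start=1):
            row[f"trait_mean_{i}"] = m
            row[f"trait_sd_{i}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def membership_frame(types: list[PhenotypeType]) -> pd.DataFrame:
    rows = [
        {"replicate": rep, "type": t.label}
        for t in types
        for rep in t.member_replicates
    ]
    return pd.DataFrame(rows).sort_values("replicate").reset_index(drop=True)
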