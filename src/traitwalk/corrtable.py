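"""Table of empirical ancestral/evolved pairwise trait correlations.

Each trait pair carries a correlation value per condition, a per-condition
significance flag and, for significant pairs, a significance rank (1 = most
significant).  Ranked pairs drive the bias initialization modes: mode ``A2``
pins the two top-ranked significant ancestral correlations in the starting
population, ``E3`` the three top-ranked evolved ones, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import pair_labels

__all__ = ["CorrelationTable"]


@dataclass
class CorrelationTable:
    """Pairwise trait correlations for both conditions.

    ``data`` has one row per trait pair in canonical order with columns
    ``pair, ancestral_r, evolved_r, ancestral_significant,
    evolved_significant, ancestral_rank, evolved_rank`` (ranks are nullable
    integers, present only on significant pairs).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "pair",
            "ancestral_r",
            "evolved_r",
            "ancestral_significant",
            "evolved_significant",
            "ancestral_rank",
            "evolved_rank",
        }
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"correlation table is missing columns {sorted(missing)}")
        for cond in ("ancestral", "evolved"):
            r = self.data[f"{cond}_r"].to_numpy(dtype=float)
            finite = np.isfinite(r)
            if np.any(np.abs(r[finite]) > 1):
                raise ValueError(f"{cond} correlations must lie in [-1, 1]")
            sig = self.data[f"{cond}_significant"].astype(bool)
            ranks = self.data.loc[sig, f"{cond}_rank"].dropna()
            if ranks.duplicated().any():
                raise ValueError(f"duplicate {cond} significance ranks")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def n_ranked(self, condition: str) -> int:
        cond = _check_condition(condition)
        sig = self.data[f"{cond}_significant"].astype(bool)
        return int(self.data.loc[sig, f"{cond}_rank"].notna().sum())

    def top_ranked(self, condition: str, m: int) -> list[tuple[int, float]]:
        """The ``m`` most significant pairs as (pair index, r), rank order."""
        cond = _check_condition(condition)
        sig = self.data[f"{cond}_significant"].astype(bool)
        ranked = self.data.loc[sig].dropna(subset=[f"{cond}_rank"])
        ranked = ranked.sort_values(f"{cond}_rank")
        if m > len(ranked):
            raise ValueError(
                f"requested {m} ranked {cond} pairs but only {len(ranked)} available"
            )
        head = ranked.head(m)
        return [(int(i), float(r)) for i, r in zip(head.index, head[f"{cond}_r"])]

    def signature(self, condition: str) -> np.ndarray:
        """All pairwise correlations of one condition, canonical pair order."""
        cond = _check_condition(condition)
        return self.data[f"{cond}_r"].to_numpy(dtype=float)

    @classmethod
    def from_values(
        cls,
        n_traits: int,
        ancestral: dict[str, tuple[float, bool, int | None]],
        evolved: dict[str, tuple[float, bool, int | None]],
    ) -> "CorrelationTable":
        """Build from per-pair ``label -> (r, significant, rank)`` mappings."""
        labels = pair_labels(n_traits)
        rows = []
        for lab in labels:
            a_r, a_sig, a_rank = ancestral[lab]
            e_r, e_sig, e_rank = evolved[lab]
            rows.append(
                {
                    "pair": lab,
                    "ancestral_r": a_r,
                    "evolved_r": e_r,
                    "ancestral_significant": a_sig,
                    "evolved_significant": e_sig,
                    "ancestral_rank": a_rank,
                    "evolved_rank": e_rank,
                }
            )
        df = pd.DataFrame(rows)
        for col in ("ancestral_rank", "evolved_rank"):
            df[col] = df[col].astype("Int64")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationTable":
        df = pd.read_csv(path)
        for col in ("ancestral_rank", "evolved_rank"):
            if col in df.columns:
                df[col] = df[col].astype("Int64")
        return cls(df)


def _check_condition(condition: str) -> str:
    cond = condition.lower()
    if cond not in ("ancestral", "evolved"):
        raise ValueError(f"condition must be 'ancestral' or 'evolved', got {condition!r}")
    return cond
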