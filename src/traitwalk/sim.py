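"""Adaptive-walk engine for populations with heritable trait correlations.

Each individual carries K standardized trait values plus the K(K-1)/2
pairwise trait correlations (canonical pair order).  Per generation a fixed
fraction ``p_corr`` of individuals (default 10%, exact count, sampled without
replacement) receive a joint correlation + trait perturbation; the rest
receive a trait perturbation propagated through their own correlations.
Fitness is ``exp(-z^2 / 2)`` where z is the Euclidean distance between the
individual's retained-axis projection and the landscape endpoint; the next
generation is drawn by fitness-weighted sampling with replacement.  Offspring
are exact copies of their parents (correlations are heritable).

Two propagation semantics are available for how a focal trait change touches
the other traits:

* ``replace`` (default): trait_j <- corr(k, j) * trait_k_new — the literal
  multiplicative update, i.e. the conditional-expectation value of trait_j
  given the new trait_k under standardized units;
* ``delta``: trait_j <- trait_j + corr(k, j) * delta — the incremental
  alternative.

Reproducibility: each replicate uses an independent ``numpy`` Generator
seeded ``base_seed + replicate``.  Within a generation draws are consumed in
a fixed order: (1) the permutation that partitions the population into the
correlation-change and trait-change groups, (2) vectorized draws for the
correlation-change group (pair index, correlation step, endpoint choice,
trait step), (3) vectorized draws for the trait-change group (trait index,
trait step), (4) the resampling draw.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corrtable import CorrelationTable
from .pairs import canonical_pairs, n_pairs, pair_index_matrix, pair_labels
from .scape import TraitScape, project

__all__ = [
    "MODES",
    "Individual",
    "SimConfig",
    "Population",
    "RunResult",
    "init_population",
    "trait_change",
    "trait_and_corr_change",
    "fitness",
    "select",
    "step_generation",
    "run",
    "save_results",
    "load_results",
]

_BIAS_MODE_RE = re.compile(r"^([AE])([1-9])$")
MODES = ("mixed", "uncorrelated", "A1", "A2", "A3", "A4", "E1", "E2", "E3", "E4")


@dataclass
class Individual:
    """One evolving unit: K trait values + K(K-1)/2 pairwise correlations."""

    traits: np.ndarray
    corr: np.ndarray

    def copy(self) -> "Individual":
        return Individual(self.traits.copy(), self.corr.copy())


@dataclass
class Population:
    """Column-oriented population state: traits (N, K) and corr (N, P)."""

    traits: np.ndarray
    corr: np.ndarray

    @property
    def size(self) -> int:
        return self.traits.shape[0]

    def copy(self) -> "Population":
        return Population(self.traits.copy(), self.corr.copy())


_CONFIG_KEYS = {
    "n_individuals",
    "generations",
    "replicates",
    "p_corr",
    "step_sd",
    "propagation",
    "mode",
    "start_spec",
    "base_seed",
}


@dataclass
class SimConfig:
    """Run configuration.

    ``start_spec`` is a list of ``(weight, trait-vector)`` starting
    phenotypes; ``None`` means a single start at the trait-scape's
    ``start_traits``.  ``mode`` selects how starting correlations are drawn;
    the bias modes ``A1..A4`` / ``E1..E4`` pin the top-ranked significant
    empirical ancestral/evolved correlations, ``mixed`` draws all of them
    iid Uniform(-1, 1), and ``uncorrelated`` zeroes the correlations and
    disables correlation propagation and evolution entirely (control run).
    """

    n_individuals: int = 1000
    generations: int = 2000
    replicates: int = 100
    p_corr: float = 0.10
    step_sd: float = 0.05
    propagation: str = "replace"
    mode: str = "mixed"
    start_spec: list[tuple[float, np.ndarray]] | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.p_corr <= 1.0:
            raise ValueError("p_corr must lie in [0, 1]")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.propagation not in ("replace", "delta"):
            raise ValueError("propagation must be 'replace' or 'delta'")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.start_spec is not None:
            spec = [(float(w), np.asarray(t, dtype=float)) for w, t in self.start_spec]
            weights = np.array([w for w, _ in spec])
            if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
                raise ValueError("start_spec weights must be positive and sum to 1")
            self.start_spec = spec

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        if d.get("start_spec") is not None:
            d["start_spec"] = [(float(w), np.asarray(t, dtype=float)) for w, t in d["start_spec"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in sorted(_CONFIG_KEYS)}
        if self.start_spec is not None:
            d["start_spec"] = [[w, list(map(float, t))] for w, t in self.start_spec]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    """One replicate: per-generation summaries + final population snapshot.

    ``summary`` has ``generations + 1`` rows (generation 0 is the initial
    state) with columns ``generation, mean_fitness, sd_fitness,
    mean_trait_1..K, mean_corr_1..P, pc1..pc{n_axes}``; ``final`` has one row
    per individual with trait, correlation and fitness values.
    """

    summary: pd.DataFrame
    final: pd.DataFrame
    seed: int
    mode: str
    config_hash: str
    replicate: int = 0

    @property
    def mean_fitness(self) -> np.ndarray:
        return self.summary["mean_fitness"].to_numpy(dtype=float)

    def final_corr(self) -> np.ndarray:
        cols = [c for c in self.final.columns if c.startswith("corr_")]
        return self.final[cols].to_numpy(dtype=float)

    def final_traits(self) -> np.ndarray:
        cols = [c for c in self.final.columns if c.startswith("trait_")]
        return self.final[cols].to_numpy(dtype=float)


def _start_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n individuals to start weights."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def init_population(
    config: SimConfig,
    scape: TraitScape,
    corr_table: CorrelationTable | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Build the starting population for one replicate.

    Trait vectors come from ``config.start_spec`` (default: every individual
    at ``scape.start_traits``); correlations are drawn according to the mode.
    """
    rng = rng if rng is not None else np.random.default_rng(config.base_seed)
    k = scape.n_traits
    p = n_pairs(k)
    n = config.n_individuals

    spec = config.start_spec or [(1.0, scape.start_traits)]
    weights = np.array([w for w, _ in spec], dtype=float)
    counts = _start_counts(weights, n)
    traits = np.vstack(
        [np.tile(np.asarray(t, dtype=float), (c, 1)) for (_, t), c in zip(spec, counts)]
    )

    mode = config.mode
    if mode == "uncorrelated":
        corr = np.zeros((n, p))
    elif mode == "mixed":
        corr = rng.uniform(-1.0, 1.0, size=(n, p))
    else:
        m = _BIAS_MODE_RE.match(mode)
        if m is None:  # pragma: no cover - guarded by SimConfig
            raise ValueError(f"unknown mode {mode!r}")
        condition = "ancestral" if m.group(1) == "A" else "evolved"
        n_pinned = int(m.group(2))
        if corr_table is None:
            raise ValueError(f"mode {mode} requires a correlation table")
        pinned = corr_table.top_ranked(condition, n_pinned)
        corr = rng.uniform(-1.0, 1.0, size=(n, p))
        for pair_idx, r in pinned:
            corr[:, pair_idx] = r
    return Population(traits=traits, corr=corr)


def _mutate_traits(
    traits: np.ndarray,
    corr: np.ndarray,
    rows: np.ndarray,
    k_idx: np.ndarray,
    delta: np.ndarray,
    propagation: str,
    pair_idx: np.ndarray,
    propagate: bool,
) -> None:
    """In-place focal-trait perturbation plus correlation propagation.

    A draw of exactly zero leaves the individual untouched (degenerate
    Gaussian: no change happened, so nothing is propagated).
    """
    active = delta != 0.0
    rows, k_idx, delta = rows[active], k_idx[active], delta[active]
    if rows.size == 0:
        return
    new_focal = traits[rows, k_idx] + delta
    if propagate:
        k = traits.shape[1]
        for j in range(k):
            sub = k_idx != j
            r, kk = rows[sub], k_idx[sub]
            rj = corr[r, pair_idx[kk, j]]
            if propagation == "replace":
                traits[r, j] = rj * new_focal[sub]
            else:
                traits[r, j] = traits[r, j] + rj * delta[sub]
    traits[rows, k_idx] = new_focal


def trait_change(
    ind: Individual,
    rng: np.random.Generator,
    step_sd: float = 0.05,
    propagation: str = "replace",
    uncorrelated: bool = False,
) -> Individual:
    """Perturb one uniformly chosen trait and propagate through correlations.

    In the uncorrelated control only the Gaussian step is applied.
    Correlations are untouched.  Consumes one integer and one Gaussian draw.
    """
    out = ind.copy()
    k = out.traits.shape[0]
    k_idx = np.array([rng.integers(k)])
    delta = np.array([rng.normal(0.0, step_sd)])
    traits = out.traits[None, :]
    _mutate_traits(
        traits,
        out.corr[None, :],
        np.array([0]),
        k_idx,
        delta,
        propagation,
        pair_index_matrix(k),
        propagate=not uncorrelated,
    )
    out.traits = traits[0]
    return out


def trait_and_corr_change(
    ind: Individual,
    rng: np.random.Generator,
    step_sd: float = 0.05,
    propagation: str = "replace",
) -> Individual:
    """Joint correlation + trait perturbation.

    One pair is chosen uniformly; its correlation takes a Gaussian step
    (clipped to [-1, 1]).  One endpoint of the pair, chosen uniformly, takes
    a Gaussian trait step; the other endpoint is updated from the *new*
    correlation and the first trait.  No other trait or correlation moves.
    """
    out = ind.copy()
    k = out.traits.shape[0]
    pairs = canonical_pairs(k)
    p_idx = int(rng.integers(len(pairs)))
    d_corr = rng.normal(0.0, step_sd)
    which = int(rng.integers(2))
    delta = rng.normal(0.0, step_sd)
    if d_corr == 0.0 and delta == 0.0:
        return out
    out.corr[p_idx] = np.clip(out.corr[p_idx] + d_corr, -1.0, 1.0)
    i, j = pairs[p_idx]
    first, second = (i, j) if which == 0 else (j, i)
    out.traits[first] = out.traits[first] + delta
    r = out.corr[p_idx]
    if propagation == "replace":
        out.traits[second] = r * out.traits[first]
    else:
        out.traits[second] = out.traits[second] + r * delta
    return out


def fitness(traits: np.ndarray, scape: TraitScape) -> np.ndarray | float:
    """Selection weight ``exp(-z^2/2)``: z = retained-axis distance to end."""
    coords = project(scape, traits)
    z2 = np.sum((coords - scape.end) ** 2, axis=-1)
    return np.exp(-z2 / 2.0)


def select(
    population: Population, weights: np.ndarray, rng: np.random.Generator
) -> tuple[Population, np.ndarray]:
    """Fitness-weighted resampling with replacement, size-preserving.

    Returns the offspring population (exact parental copies) and the chosen
    parent indices.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("fitness weights must be non-negative")
    total = w.sum()
    if not total > 0:
        raise ValueError("cannot select: all fitness weights are zero")
    idx = rng.choice(population.size, size=population.size, p=w / total)
    return Population(population.traits[idx].copy(), population.corr[idx].copy()), idx


def _mutate_population(
    pop: Population, config: SimConfig, pair_idx: np.ndarray, rng: np.random.Generator
) -> None:
    """One generation's mutation phase, in place, in documented draw order."""
    n = pop.size
    uncorrelated = config.mode == "uncorrelated"
    n_corr = 0 if uncorrelated else int(round(config.p_corr * n))
    perm = rng.permutation(n)
    corr_rows, trait_rows = perm[:n_corr], perm[n_corr:]

    if n_corr:
        p = pop.corr.shape[1]
        pairs = np.asarray(canonical_pairs(pop.traits.shape[1]))
        pick = rng.integers(p, size=n_corr)
        d_corr = rng.normal(0.0, config.step_sd, size=n_corr)
        which = rng.integers(2, size=n_corr)
        delta = rng.normal(0.0, config.step_sd, size=n_corr)
        active = (d_corr != 0.0) | (delta != 0.0)
        rows, pick, d_corr = corr_rows[active], pick[active], d_corr[active]
        which, delta = which[active], delta[active]
        pop.corr[rows, pick] = np.clip(pop.corr[rows, pick] + d_corr, -1.0, 1.0)
        ij = pairs[pick]
        first = np.where(which == 0, ij[:, 0], ij[:, 1])
        second = np.where(which == 0, ij[:, 1], ij[:, 0])
        pop.traits[rows, first] = pop.traits[rows, first] + delta
        r = pop.corr[rows, pick]
        if config.propagation == "replace":
            pop.traits[rows, second] = r * pop.traits[rows, first]
        else:
            pop.traits[rows, second] = pop.traits[rows, second] + r * delta

    k_idx = rng.integers(pop.traits.shape[1], size=trait_rows.size)
    delta = rng.normal(0.0, config.step_sd, size=trait_rows.size)
    _mutate_traits(
        pop.traits,
        pop.corr,
        trait_rows,
        k_idx,
        delta,
        config.propagation,
        pair_idx,
        propagate=not uncorrelated,
    )


def step_generation(
    population: Population,
    config: SimConfig,
    scape: TraitScape,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Mutation phase, fitness evaluation, fitness-weighted resampling.

    Exactly ``round(p_corr * N)`` individuals, sampled without replacement,
    receive the joint correlation + trait change; the rest receive the plain
    trait change.  Returns the new population and the per-individual fitness
    values carried over from the sampled parents.
    """
    pop = population.copy()
    pair_idx = pair_index_matrix(pop.traits.shape[1])
    _mutate_population(pop, config, pair_idx, rng)
    w = np.asarray(fitness(pop.traits, scape))
    new_pop, idx = select(pop, w, rng)
    return new_pop, w[idx]


def _summarize(
    gen: int, pop: Population, fit: np.ndarray, scape: TraitScape
) -> dict[str, float]:
    coords = project(scape, pop.traits).mean(axis=0)
    row: dict[str, float] = {
        "generation": gen,
        "mean_fitness": float(np.mean(fit)),
        "sd_fitness": float(np.std(fit)),
    }
    for i, v in enumerate(pop.traits.mean(axis=0), start=1):
        row[f"mean_trait_{i}"] = float(v)
    for lab, v in zip(pair_labels(pop.traits.shape[1]), pop.corr.mean(axis=0)):
        row[f"mean_corr_{lab}"] = float(v)
    for j, v in enumerate(coords, start=1):
        row[f"pc{j}"] = float(v)
    return row


def _run_replicate(
    config: SimConfig,
    scape: TraitScape,
    corr_table: CorrelationTable | None,
    replicate: int,
) -> RunResult:
    seed = config.base_seed + replicate
    rng = np.random.default_rng(seed)
    pop = init_population(config, scape, corr_table, rng)
    fit = np.asarray(fitness(pop.traits, scape))
    rows = [_summarize(0, pop, fit, scape)]
    pair_idx = pair_index_matrix(pop.traits.shape[1])
    for gen in range(1, config.generations + 1):
        _mutate_population(pop, config, pair_idx, rng)
        w = np.asarray(fitness(pop.traits, scape))
        pop, idx = select(pop, w, rng)
        fit = w[idx]
        rows.append(_summarize(gen, pop, fit, scape))

    summary = pd.DataFrame(rows)
    k = pop.traits.shape[1]
    final = pd.DataFrame({"individual": np.arange(pop.size)})
    for i in range(k):
        final[f"trait_{i + 1}"] = pop.traits[:, i]
    for lab, col in zip(pair_labels(k), pop.corr.T):
        final[f"corr_{lab}"] = col
    final["fitness"] = fit
    return RunResult(
        summary=summary,
        final=final,
        seed=seed,
        mode=config.mode,
        config_hash=config.config_hash(),
        replicate=replicate,
    )


def run(
    config: SimConfig,
    scape: TraitScape,
    corr_table: CorrelationTable | None = None,
) -> list[RunResult]:
    """Run all replicates; replicate r is seeded ``base_seed + r``."""
    if config.mode not in ("mixed", "uncorrelated") and corr_table is None:
        raise ValueError(f"mode {config.mode} requires a correlation table")
    return [
        _run_replicate(config, scape, corr_table, r) for r in range(config.replicates)
    ]


def save_results(results: list[RunResult], out_dir: str | Path) -> None:
    """Write per-replicate summary/final CSVs plus a run manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"replicates": []}
    for res in results:
        s = out / f"rep{res.replicate:03d}_summary.csv"
        f = out / f"rep{res.replicate:03d}_final.csv"
        res.summary.to_csv(s, index=False)
        res.final.to_csv(f, index=False)
        manifest["replicates"].append(
            {
                "replicate": res.replicate,
                "seed": res.seed,
                "mode": res.mode,
                "config_hash": res.config_hash,
                "summary": s.name,
                "final": f.name,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_results(run_dir: str | Path) -> list[RunResult]:
    """Load a directory written by :func:`save_results`."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    results = []
    for entry in manifest["replicates"]:
        results.append(
            RunResult(
                summary=pd.read_csv(run_dir / entry["summary"]),
                final=pd.read_csv(run_dir / entry["final"]),
                seed=entry["seed"],
                mode=entry["mode"],
                config_hash=entry["config_hash"],
                replicate=entry["replicate"],
            )
        )
    return results
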