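"""Artificial bee colony (ABC) metaheuristic.

Canonical Karaboga formulation: a population of food sources (candidate
solutions) is refined by three phases per iteration —

* employed phase: each source i proposes a one-coordinate neighbor
  v_ij = x_ij + phi * (x_ij - x_kj) with phi ~ Uniform(-1, 1) and a random
  partner k != i, keeping the better of source and candidate (greedy);
* onlooker phase: sources are re-sampled with probability proportional to
  fitness and perturbed the same way;
* scout phase: at most one source whose trial counter exceeds the
  abandonment limit is re-initialized uniformly.

Minimization throughout; fitness is the standard transform
1/(1 + f) for f >= 0 and 1 + |f| otherwise. The search space is either a
continuous box or a binary feature mask decoded by thresholding the
continuous position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel objective for infeasible decodings (e.g. an all-zero mask):
#: the largest finite float, so infeasible sources are never preferred and
#: are quickly abandoned.
INFEASIBLE_OBJECTIVE = float(np.finfo(float).max)


@dataclass
class FoodSource:
    """One candidate solution with its objective, fitness and trial counter."""

    position: np.ndarray
    objective: float
    fitness: float
    trials: int = 0

    def copy(self) -> "FoodSource":
        return FoodSource(
            self.position.copy(), self.objective, self.fitness, self.trials
        )


@dataclass(frozen=True)
class ABCConfig:
    """ABC control parameters.

    Defaults follow the published configuration: 15 food sources, 30
    iterations, abandonment parameter 0.01. A fractional ``abandonment``
    (< 1) is read as a fraction of the n_sources * max_iterations trial
    budget, giving an integer limit of max(1, round(0.01 * 15 * 30)) = 5 at
    the defaults; values >= 1 are used directly as the integer limit.
    """

    n_sources: int = 15
    max_iterations: int = 30
    abandonment: float = 0.01
    seed: int = 0
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.abandonment <= 0:
            raise ValueError("abandonment must be positive")

    @property
    def abandonment_limit(self) -> int:
        if self.abandonment >= 1:
            return int(round(self.abandonment))
        # round half up, so the documented 0.01 * 15 * 30 = 4.5 -> 5
        budget = self.abandonment * self.n_sources * self.max_iterations
        return max(1, int(np.floor(budget + 0.5)))


@dataclass(frozen=True)
class SearchSpace:
    """Continuous box or thresholded binary-mask search space."""

    dimension: int
    encoding: str = "continuous"  # or "binary-mask"
    lower: np.ndarray | float = 0.0
    upper: np.ndarray | float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.encoding not in ("continuous", "binary-mask"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        lo, hi = self.bounds()
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dimension,))
        hi = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dimension,))
        return lo.copy(), hi.copy()


@dataclass
class OptimizeResult:
    best: FoodSource
    history: np.ndarray  # best-so-far objective per iteration
    mean_history: np.ndarray  # population mean objective per iteration
    n_evaluations: int
    sources: list[FoodSource] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.history) + 1),
                "best_objective": self.history,
                "mean_objective": self.mean_history,
            }
        )


def fitness_transform(objective: float) -> float:
    """Canonical ABC objective-to-fitness map (positive, larger is better)."""
    if objective >= 0:
        return 1.0 / (1.0 + objective)
    return 1.0 + abs(objective)


def decode_mask(position: np.ndarray, space: SearchSpace) -> tuple[np.ndarray, bool]:
    """Threshold a continuous position into a binary mask.

    Returns (mask, feasible). The threshold boundary is closed from below:
    a coordinate exactly at the threshold maps to 1. An all-zero mask is
    infeasible.
    """
    if space.encoding != "binary-mask":
        raise ValueError("decode_mask requires a binary-mask space")
    mask = (np.asarray(position) >= space.threshold).astype(int)
    return mask, bool(mask.any())


def neighbor_move(
    source: FoodSource,
    partner: FoodSource,
    dim: int,
    rng: np.random.Generator,
    space: SearchSpace,
    phi: float | None = None,
) -> np.ndarray:
    """One-coordinate perturbation toward/away from a partner source.

    v_j = x_j + phi * (x_j - x_k j), phi ~ Uniform(-1, 1), clipped to bounds.
    ``phi`` may be forced for testing. If source and partner coincide on the
    chosen coordinate the move degenerates to a no-op.
    """
    lo, hi = space.bounds()
    if phi is None:
        phi = rng.uniform(-1.0, 1.0)
    candidate = source.position.copy()
    candidate[dim] = np.clip(
        source.position[dim] + phi * (source.position[dim] - partner.position[dim]),
        lo[dim],
        hi[dim],
    )
    return candidate


def selection_probabilities(sources: list[FoodSource]) -> np.ndarray:
    """Fitness-proportional onlooker recruitment probabilities."""
    fit = np.array([s.fitness for s in sources], dtype=float)
    if not np.all(np.isfinite(fit)) or np.any(fit < 0):
        raise ValueError("fitness values must be finite and non-negative")
    total = fit.sum()
    if total == 0:
        return np.full(len(sources), 1.0 / len(sources))
    return fit / total


class ArtificialBeeColony:
    """ABC minimizer over a continuous box or binary-mask space.

    Parameters
    ----------
    objective : callable position -> float
        For binary-mask spaces the callable receives the *decoded* mask; an
        infeasible all-zero decoding never reaches it (sentinel objective).
    space : SearchSpace
    config : ABCConfig
    """

    def __init__(self, objective, space: SearchSpace, config: ABCConfig) -> None:
        self.raw_objective = objective
        self.space = space
        self.config = config
        self.n_evaluations = 0

    # ------------------------------------------------------------------
    def _evaluate(self, position: np.ndarray) -> float:
        if self.space.encoding == "binary-mask":
            mask, feasible = decode_mask(position, self.space)
            if not feasible:
                return INFEASIBLE_OBJECTIVE
            value = self.raw_objective(mask)
        else:
            value = self.raw_objective(position)
        self.n_evaluations += 1
        if not np.isfinite(value):
            raise ValueError(f"non-finite objective {value!r} at position {position}")
        return float(value)

    def _make_source(self, position: np.ndarray) -> FoodSource:
        obj = self._evaluate(position)
        return FoodSource(position, obj, fitness_transform(obj))

    def init_sources(
        self, rng: np.random.Generator, init_positions: np.ndarray | None = None
    ) -> list[FoodSource]:
        """Uniform initial population; optional seed positions for the first
        rows (e.g. a warm-start mask)."""
        lo, hi = self.space.bounds()
        n = self.config.n_sources
        positions = rng.uniform(lo, hi, size=(n, self.space.dimension))
        if init_positions is not None:
            init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
            k = min(len(init_positions), n)
            positions[:k] = np.clip(init_positions[:k], lo, hi)
        return [self._make_source(pos) for pos in positions]

    def _greedy(self, sources: list[FoodSource], i: int, rng: np.random.Generator):
        partner = int(rng.integers(self.config.n_sources - 1))
        if partner >= i:
            partner += 1
        dim = int(rng.integers(self.space.dimension))
        candidate = neighbor_move(sources[i], sources[partner], dim, rng, self.space)
        obj = self._evaluate(candidate)
        if obj < sources[i].objective:
            sources[i] = FoodSource(candidate, obj, fitness_transform(obj))
        else:
            sources[i].trials += 1

    def optimize(self, init_positions: np.ndarray | None = None) -> OptimizeResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        sources = self.init_sources(rng, init_positions)

        best = min(sources, key=lambda s: s.objective).copy()
        history, mean_history = [], []

        for _ in range(cfg.max_iterations):
            # employed phase
            for i in range(cfg.n_sources):
                self._greedy(sources, i, rng)

            # onlooker phase: n_sources fitness-proportional selections
            probs = selection_probabilities(sources)
            picks = rng.choice(cfg.n_sources, size=cfg.n_sources, p=probs)
            for i in picks:
                self._greedy(sources, int(i), rng)

            # scout phase: at most one replacement per iteration
            limit = cfg.abandonment_limit
            over = [s.trials for s in sources]
            worst = int(np.argmax(over))
            if over[worst] > limit:
                lo, hi = self.space.bounds()
                pos = rng.uniform(lo, hi, size=self.space.dimension)
                sources[worst] = self._make_source(pos)

            iter_best = min(sources, key=lambda s: s.objective)
            if iter_best.objective < best.objective:
                best = iter_best.copy()
            history.append(best.objective if cfg.elitism else iter_best.objective)
            feasible = [
                s.objective for s in sources if s.objective < INFEASIBLE_OBJECTIVE
            ]
            mean_history.append(float(np.mean(feasible)) if feasible else float("nan"))

        final = best if cfg.elitism else min(sources, key=lambda s: s.objective).copy()
        return OptimizeResult(
            best=final,
            history=np.array(history),
            mean_history=np.array(mean_history),
            n_evaluations=self.n_evaluations,
            sources=sources,
        )


def optimize(objective, space: SearchSpace, config: ABCConfig, **kwargs) -> OptimizeResult:
    """Functional entry point: run ABC and return the best source + history."""
    return ArtificialBeeColony(objective, space, config).optimize(**kwargs)


def sensitivity_grid(
    objective,
    space: SearchSpace,
    n_sources_grid=(10, 15, 20),
    iterations_grid=(20, 30, 40),
    abandonment_grid=(0.005, 0.01, 0.02),
    seeds=(0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Parameter-sensitivity protocol: mean +/- SD of the best objective over
    seeds for each (n_sources, iterations, abandonment) cell."""
    rows = []
    for ns in n_sources_grid:
        for it in iterations_grid:
            for ab in abandonment_grid:
                vals = []
                for seed in seeds:
                    cfg = ABCConfig(
                        n_sources=ns, max_iterations=it, abandonment=ab, seed=seed
                    )
                    vals.append(optimize(objective, space, cfg).best.objective)
                rows.append(
                    {
                        "n_sources": ns,
                        "iterations": it,
                        "abandonment": ab,
                        "mean_objective": float(np.mean(vals)),
                        "sd_objective": float(np.std(vals, ddof=1)),
                    }
                )
    return pd.DataFrame(rows)
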