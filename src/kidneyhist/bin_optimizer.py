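"""Genetic-algorithm search for discriminative histogram bin edges.

The seven interior edges of the 8-bin histogram are free parameters. A good
edge set makes corresponding windows of same-class images look alike and
windows of different-class images look different. The objective is therefore
the mean Pearson correlation of corresponding window histograms over
same-class image pairs minus the same mean over different-class pairs;
higher is more class-discriminative. A genetic algorithm over integer edge
candidates (strictly increasing, no repetition, in [1, 254]) maximises it —
once for the intensity image and once, independently, for its gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .local_histogram import (
    N_BINS,
    N_WINDOWS,
    BinEdges,
    gradient_magnitude,
    make_window_grid,
)

__all__ = ["GAConfig", "GAResult", "objective", "ga_optimize"]

logger = logging.getLogger(__name__)

_N_INTERIOR = 7
_DOMAIN_LO, _DOMAIN_HI = 1, 254


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the evolutionary search (all overridable)."""

    population_size: int = 60
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elite_count: int = 2
    tournament_size: int = 3
    seed: int = 0
    #: Optional restriction of edge alleles to a fixed grid of values
    #: (used for desk-scale exhaustive cross-checks); None = all of [1, 254].
    allowed_values: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elite_count < 1 or self.elite_count > self.population_size:
            raise ValueError("elite_count must be in [1, population_size]")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.allowed_values is not None:
            vals = tuple(sorted(set(int(v) for v in self.allowed_values)))
            if len(vals) < _N_INTERIOR:
                raise ValueError("allowed_values must contain at least 7 distinct values")
            if vals[0] < _DOMAIN_LO or vals[-1] > _DOMAIN_HI:
                raise ValueError("allowed_values must lie in [1, 254]")
            object.__setattr__(self, "allowed_values", vals)


@dataclass
class GAResult:
    best_edges: BinEdges
    best_score: float
    history: list[float] = field(default_factory=list)
    skipped_pairs: int = 0


class _Workspace:
    """Per-run precomputation so each candidate evaluation is a bincount.

    For every image, pixels are flattened together with their window index;
    one candidate then costs a ``searchsorted`` + ``bincount`` per image and
    a single correlation pass over the stacked (n_images, 100, 8) tensor.
    """

    def __init__(self, images: list[tuple[str, np.ndarray]], mode: str) -> None:
        if mode not in ("intensity", "gradient"):
            raise ValueError("mode must be 'intensity' or 'gradient'")
        labels = [lab for lab, _ in images]
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError("at least 2 classes are required")
        for c in classes:
            if labels.count(c) < 2:
                raise ValueError(f"class {c!r} needs at least 2 images")
        self.labels = np.array(labels)
        self.pixels: list[np.ndarray] = []
        self.window_ids: list[np.ndarray] = []
        for _, img in images:
            if mode == "gradient":
                img = gradient_magnitude(img)
            grid = make_window_grid(img.shape[0], img.shape[1])
            wid = np.empty(img.shape, dtype=np.intp)
            for w, (i, j) in enumerate(
                (i, j) for i in range(grid.n_rows) for j in range(grid.n_cols)
            ):
                wid[grid.row_bounds[i]:grid.row_bounds[i + 1],
                    grid.col_bounds[j]:grid.col_bounds[j + 1]] = w
            self.pixels.append(np.asarray(img).ravel())
            self.window_ids.append(wid.ravel() * N_BINS)
        same = self.labels[:, None] == self.labels[None, :]
        iu = np.triu_indices(len(images), k=1)
        self.pair_a, self.pair_b = iu
        self.pair_same = same[iu]

    def histograms(self, interior: np.ndarray) -> np.ndarray:
        cut = np.asarray(interior)
        out = np.empty((len(self.pixels), N_WINDOWS, N_BINS))
        for k, (px, wid) in enumerate(zip(self.pixels, self.window_ids)):
            bins = np.searchsorted(cut, px, side="right")
            counts = np.bincount(wid + bins, minlength=N_WINDOWS * N_BINS)
            h = counts.reshape(N_WINDOWS, N_BINS).astype(np.float64)
            out[k] = h / h.sum(axis=1, keepdims=True)
        return out

    def score(self, interior: np.ndarray) -> tuple[float, int]:
        h = self.histograms(interior)
        mean = h.mean(axis=2, keepdims=True)
        std = h.std(axis=2, keepdims=True)
        valid = (std > 0)[..., 0]                        # (n_img, 100)
        z = np.where(std > 0, (h - mean) / np.where(std > 0, std, 1), 0.0)
        # Pearson r of two 8-vectors = mean of their z-score products.
        r = np.einsum("awk,bwk->abw", z, z) / N_BINS     # (n_img, n_img, 100)
        pv = valid[self.pair_a] & valid[self.pair_b]     # (n_pairs, 100)
        pr = r[self.pair_a, self.pair_b]
        n_skipped = int((~pv).sum())
        same_mask = self.pair_same[:, None] & pv
        diff_mask = ~self.pair_same[:, None] & pv
        if not same_mask.any() or not diff_mask.any():
            raise ValueError("degenerate histograms: every comparable pair was skipped")
        return float(pr[same_mask].mean() - pr[diff_mask].mean()), n_skipped


def objective(
    candidate: np.ndarray | tuple[int, ...],
    images: list[tuple[str, np.ndarray]],
    mode: str = "intensity",
) -> float:
    """Correlation-contrast score of one interior-edge candidate.

    ``candidate`` is the 7 strictly increasing interior edges; the implied
    bin edges are ``(0, *candidate, 255)``. Image pairs whose 8-vector at a
    window has zero variance are skipped (Pearson undefined) and counted in
    a debug log entry.
    """
    cand = np.asarray(candidate, dtype=np.int64)
    BinEdges.from_interior(cand)  # validates monotonicity and range
    ws = _Workspace(list(images), mode)
    score, skipped = ws.score(cand)
    if skipped:
        logger.debug("objective: skipped %d zero-variance (pair, window) combinations", skipped)
    return score


def _repair(cand: np.ndarray, rng: np.random.Generator,
            domain: np.ndarray) -> np.ndarray:
    """Restore candidate invariants: values from the domain, distinct, sorted."""
    cand = np.clip(cand, domain[0], domain[-1])
    # snap to the nearest allowed value (no-op for the full integer domain)
    idx = np.clip(np.searchsorted(domain, cand), 0, len(domain) - 1)
    left = np.clip(idx - 1, 0, len(domain) - 1)
    cand = np.where(np.abs(domain[left] - cand) <= np.abs(domain[idx] - cand),
                    domain[left], domain[idx])
    uniq = np.unique(cand)
    while len(uniq) < _N_INTERIOR:
        pool = np.setdiff1d(domain, uniq)
        extra = rng.choice(pool, size=_N_INTERIOR - len(uniq), replace=False)
        uniq = np.union1d(uniq, extra)
    return np.sort(uniq)


def ga_optimize(
    images: list[tuple[str, np.ndarray]],
    mode: str = "intensity",
    cfg: GAConfig | None = None,
) -> GAResult:
    """Evolve interior bin edges maximising :func:`objective`.

    Tournament selection, uniform crossover, per-gene resampling mutation,
    with repair (sort / deduplicate / clamp) after every variation step so
    each individual always encodes a valid strictly increasing edge set.
    Elitism makes the best-score history non-decreasing; a fixed seed makes
    the whole run reproducible. Candidate scores are memoised.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    ws = _Workspace(list(images), mode)
    domain = (np.asarray(cfg.allowed_values, dtype=np.int64)
              if cfg.allowed_values is not None
              else np.arange(_DOMAIN_LO, _DOMAIN_HI + 1, dtype=np.int64))

    cache: dict[tuple[int, ...], float] = {}
    total_skipped = 0

    def fitness(cand: np.ndarray) -> float:
        nonlocal total_skipped
        key = tuple(int(v) for v in cand)
        if key not in cache:
            score, skipped = ws.score(cand)
            total_skipped += skipped
            cache[key] = score
        return cache[key]

    pop = [np.sort(rng.choice(domain, size=_N_INTERIOR, replace=False))
           for _ in range(cfg.population_size)]
    scores = np.array([fitness(c) for c in pop])
    history: list[float] = []

    for _ in range(cfg.generations):
        order = np.argsort(scores)[::-1]
        elites = [pop[i].copy() for i in order[: cfg.elite_count]]
        children: list[np.ndarray] = []
        while len(children) < cfg.population_size - cfg.elite_count:
            idx = rng.integers(len(pop), size=(2, cfg.tournament_size))
            p1 = pop[idx[0][np.argmax(scores[idx[0]])]]
            p2 = pop[idx[1][np.argmax(scores[idx[1]])]]
            if rng.random() < cfg.crossover_rate:
                take = rng.random(_N_INTERIOR) < 0.5
                c1 = np.where(take, p1, p2)
                c2 = np.where(take, p2, p1)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mut = rng.random(_N_INTERIOR) < cfg.mutation_rate
                if mut.any():
                    child = child.copy()
                    child[mut] = rng.choice(domain, size=int(mut.sum()))
                children.append(_repair(child, rng, domain))
        pop = elites + children[: cfg.population_size - cfg.elite_count]
        scores = np.array([fitness(c) for c in pop])
        history.append(float(scores.max()))

    best = int(np.argmax(scores))
    if total_skipped:
        logger.info("ga_optimize: skipped %d zero-variance (pair, window) combinations in total",
                    total_skipped)
    return GAResult(
        best_edges=BinEdges.from_interior(pop[best]),
        best_score=float(scores[best]),
        history=history,
        skipped_pairs=total_skipped,
    )
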