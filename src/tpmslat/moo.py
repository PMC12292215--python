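"""Elitist NSGA-II for maximizing (U, EA, SA/VR) over the design variables.

A from-scratch implementation of Deb's algorithm: fast non-dominated
sorting, crowding-distance diversity preservation, binary tournament
selection (rank then crowding), simulated binary crossover (SBX) and
polynomial mutation, with full elitist environmental selection.  All
comparisons are in the *maximization* sense.

Optimization is stratified by implant size group.  Inside each group the
seven numeric design variables are relaxed to continuous values between the
group's observed minima and maxima; the categorical surface type is handled
by running the optimizer once per type and merging the resulting fronts
through one final non-dominated sort, which avoids pushing a categorical
variable through SBX.  The biologically motivated relative-density window
(20-40 % by default, matching trabecular bone) is enforced by post-hoc
filtering of the merged front, not as an objective or penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .design_space import NUMERIC_FEATURES, SIZE_CLASSES
from .geometry import SURFACE_TYPES

OBJECTIVE_COLUMNS = ["u_mpa", "ea_mj_m3", "savr_per_mm"]


@dataclass
class NSGAConfig:
    population_size: int = 100
    generations: int = 50
    crossover_eta: float = 15.0
    crossover_prob: float = 0.9
    mutation_eta: float = 20.0
    mutation_prob: float | None = None  # default 1 / n_variables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if not 0 < self.crossover_prob <= 1:
            raise ValueError("crossover_prob must lie in (0, 1]")


def dominates(a, b) -> bool:
    """True iff ``a`` dominates ``b`` in the maximization sense."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool((a >= b).all() and (a > b).any())


def fast_non_dominated_sort(F: np.ndarray) -> list[list[int]]:
    """Partition objective rows into fronts F0, F1, ... (Deb's algorithm)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = len(F)
    # vectorized pairwise dominance: dom[i, j] = i dominates j
    ge = (F[:, None, :] >= F[None, :, :]).all(axis=2)
    gt = (F[:, None, :] > F[None, :, :]).any(axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.arange(n)
    counts = n_dominators.copy()
    while remaining.size:
        mask = counts[remaining] == 0
        current = remaining[mask]
        fronts.append(current.tolist())
        remaining = remaining[~mask]
        if remaining.size:
            counts = counts - dom[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distances for one front; boundaries get +inf.

    Interior individuals sum, per objective, the gap between their two
    neighbours normalized by the objective's range; a zero-range objective
    contributes nothing.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def sbx_crossover(p1: np.ndarray, p2: np.ndarray, bounds: np.ndarray,
                  eta: float, prob: float, rng: np.random.Generator):
    """Bounded simulated binary crossover (Deb's operator).

    Per variable (with probability 1/2 once the pair crosses at all) the
    spread factor is drawn from the polynomial distribution with index
    ``eta``, using the bound-aware form so offspring never leave the box;
    each crossed variable is then swapped between the children with
    probability 1/2.  Identical parents yield identical children.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    c1, c2 = p1.copy(), p2.copy()
    lo, hi = bounds[:, 0], bounds[:, 1]
    if rng.random() <= prob:
        for i in range(len(p1)):
            if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
                continue
            y1, y2 = sorted((p1[i], p2[i]))
            u = rng.random()

            def _child(beta_bound: float) -> float:
                alpha = 2.0 - beta_bound ** -(eta + 1.0)
                if u <= 1.0 / alpha:
                    return (u * alpha) ** (1.0 / (eta + 1.0))
                return (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))

            span = y2 - y1
            betaq1 = _child(1.0 + 2.0 * (y1 - lo[i]) / span)
            betaq2 = _child(1.0 + 2.0 * (hi[i] - y2) / span)
            ch1 = 0.5 * ((y1 + y2) - betaq1 * span)
            ch2 = 0.5 * ((y1 + y2) + betaq2 * span)
            ch1 = min(max(ch1, lo[i]), hi[i])
            ch2 = min(max(ch2, lo[i]), hi[i])
            if rng.random() <= 0.5:
                ch1, ch2 = ch2, ch1
            c1[i], c2[i] = ch1, ch2
    return c1, c2


def polynomial_mutation(x: np.ndarray, bounds: np.ndarray, eta: float,
                        prob: float, rng: np.random.Generator) -> np.ndarray:
    """Deb's polynomial mutation, per variable with probability ``prob``."""
    y = np.asarray(x, dtype=float).copy()
    lo, hi = bounds[:, 0], bounds[:, 1]
    for i in range(len(y)):
        if rng.random() >= prob:
            continue
        span = hi[i] - lo[i]
        if span <= 0:
            continue
        u = rng.random()
        delta1 = (y[i] - lo[i]) / span
        delta2 = (hi[i] - y[i]) / span
        mut_pow = 1.0 / (eta + 1.0)
        if u < 0.5:
            xy = 1.0 - delta1
            val = 2.0 * u + (1.0 - 2.0 * u) * xy ** (eta + 1.0)
            deltaq = val ** mut_pow - 1.0
        else:
            xy = 1.0 - delta2
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * xy ** (eta + 1.0)
            deltaq = 1.0 - val ** mut_pow
        y[i] = np.clip(y[i] + deltaq * span, lo[i], hi[i])
    return y


def _binary(i: int, j: int, rank: np.ndarray, crowd: np.ndarray) -> int:
    """Crowded-comparison winner of one binary tournament."""
    if rank[i] < rank[j]:
        return int(i)
    if rank[j] < rank[i]:
        return int(j)
    return int(i) if crowd[i] >= crowd[j] else int(j)


def _tournament(rank: np.ndarray, crowd: np.ndarray,
                rng: np.random.Generator) -> int:
    i, j = rng.integers(0, len(rank), size=2)
    return _binary(i, j, rank, crowd)


def _rank_and_crowd(F: np.ndarray):
    fronts = fast_non_dominated_sort(F)
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return fronts, rank, crowd


@dataclass
class NSGAResult:
    X: np.ndarray              # rank-0 decision vectors
    F: np.ndarray              # their objectives (maximization sense)
    history: pd.DataFrame      # per-generation best of each objective
    config: NSGAConfig


def run_nsga2(evaluator, bounds, config: NSGAConfig) -> NSGAResult:
    """Standard elitist NSGA-II loop; ``evaluator`` maps an (n, d) decision
    matrix to an (n, m) objective matrix to be maximized.

    Deterministic per seed.  Variables with zero-width bounds stay fixed.
    """
    bounds = np.asarray(bounds, dtype=float)
    if (bounds[:, 0] > bounds[:, 1]).any():
        raise ValueError("each bound must satisfy lower <= upper")
    d = len(bounds)
    pm = config.mutation_prob if config.mutation_prob is not None else 1.0 / d
    rng = np.random.default_rng(config.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]

    # Latin-hypercube start: stratified coverage of the box
    sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31)))
    X = lo + sampler.random(config.population_size) * (hi - lo)
    try:
        F = np.atleast_2d(np.asarray(evaluator(X), dtype=float))
    except Exception as exc:
        raise RuntimeError(f"evaluator failed on the initial population: {exc}") from exc
    fronts, rank, crowd = _rank_and_crowd(F)
    hist = [dict(generation=0, **{f"best_{j}": float(F[:, j].max())
                                  for j in range(F.shape[1])})]

    for gen in range(1, config.generations + 1):
        # binary tournaments over two shuffled pairings so every parent
        # competes exactly twice (Deb's mating scheme); duplicate children
        # are perturbed once more to keep the offspring pool diverse
        children = []
        seen = {tuple(row) for row in np.round(X, 12)}
        candidates = []
        for perm in (rng.permutation(len(X)), rng.permutation(len(X))):
            for k in range(0, len(perm) - 1, 2):
                candidates.append(_binary(perm[k], perm[k + 1], rank, crowd))
        ci = 0
        while len(children) < config.population_size:
            if ci + 1 >= len(candidates):
                candidates.extend(
                    [_tournament(rank, crowd, rng) for _ in range(2)])
            a, b = candidates[ci], candidates[ci + 1]
            ci += 2
            c1, c2 = sbx_crossover(X[a], X[b], bounds,
                                   config.crossover_eta,
                                   config.crossover_prob, rng)
            for child in (c1, c2):
                child = polynomial_mutation(child, bounds,
                                            config.mutation_eta, pm, rng)
                key = tuple(np.round(child, 12))
                if key in seen:
                    child = polynomial_mutation(child, bounds,
                                                config.mutation_eta,
                                                max(pm, 0.5), rng)
                    key = tuple(np.round(child, 12))
                seen.add(key)
                children.append(child)
                if len(children) >= config.population_size:
                    break
        Xc = np.asarray(children)
        try:
            Fc = np.atleast_2d(np.asarray(evaluator(Xc), dtype=float))
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed at generation {gen}: {exc}") from exc

        # elitist environmental selection over parents + offspring
        Xall = np.vstack([X, Xc])
        Fall = np.vstack([F, Fc])
        fronts_all, _, _ = _rank_and_crowd(Fall)
        keep = []
        for front in fronts_all:
            if len(keep) + len(front) <= config.population_size:
                keep.extend(front)
            else:
                cd = crowding_distance(Fall[front])
                order = np.argsort(-cd, kind="stable")
                need = config.population_size - len(keep)
                keep.extend(np.asarray(front)[order[:need]].tolist())
                break
        X, F = Xall[keep], Fall[keep]
        fronts, rank, crowd = _rank_and_crowd(F)
        hist.append(dict(generation=gen,
                         **{f"best_{j}": float(F[:, j].max())
                            for j in range(F.shape[1])}))

    first = fronts[0]
    return NSGAResult(X=X[first], F=F[first],
                      history=pd.DataFrame(hist), config=config)


# ---------------------------------------------------------------------------
# design-space front assembly
# ---------------------------------------------------------------------------

def group_bounds(group_df: pd.DataFrame) -> np.ndarray:
    """(lower, upper) per numeric design variable observed in the group."""
    lo = group_df[NUMERIC_FEATURES].min().to_numpy(dtype=float)
    hi = group_df[NUMERIC_FEATURES].max().to_numpy(dtype=float)
    return np.column_stack([lo, hi])


def _surrogate_evaluator(model, surface_type: str):
    """Batch evaluator: decision matrix -> (U, EA, SA/VR), plus RD lookup."""
    def evaluate_batch(X: np.ndarray) -> np.ndarray:
        df = pd.DataFrame(np.atleast_2d(X), columns=NUMERIC_FEATURES)
        df["surface_type"] = surface_type
        pred = model.predict_frame(df)
        return pred[OBJECTIVE_COLUMNS].to_numpy()
    return evaluate_batch


def optimize_group(model, group_df: pd.DataFrame, size_class: str,
                   config: NSGAConfig | None = None,
                   surface_types=SURFACE_TYPES) -> pd.DataFrame:
    """Pareto front for one implant size group.

    Runs NSGA-II once per surface type over the group's variable bounds,
    merges the per-type fronts through a final non-dominated sort, and
    attaches the surrogate's predicted RD to every survivor.  Returns a
    frame with the decision variables, objectives, ``rd_pred`` and
    ``size_class``.
    """
    config = config or NSGAConfig()
    bounds = group_bounds(group_df)
    rows = []
    for k, stype in enumerate(surface_types):
        cfg = NSGAConfig(**{**config.__dict__, "seed": config.seed + k})
        res = run_nsga2(_surrogate_evaluator(model, stype), bounds, cfg)
        df = pd.DataFrame(res.X, columns=NUMERIC_FEATURES)
        df["surface_type"] = stype
        for j, col in enumerate(OBJECTIVE_COLUMNS):
            df[col] = res.F[:, j]
        rows.append(df)
    merged = pd.concat(rows, ignore_index=True)
    fronts = fast_non_dominated_sort(merged[OBJECTIVE_COLUMNS].to_numpy())
    front = merged.iloc[fronts[0]].reset_index(drop=True)
    pred = model.predict_frame(front[NUMERIC_FEATURES + ["surface_type"]])
    front["rd_pred"] = pred["rd_pct"].to_numpy()
    front["size_class"] = size_class
    return front


def rd_filter(front: pd.DataFrame, low: float = 20.0, high: float = 40.0):
    """Inclusive relative-density window filter on a Pareto front.

    Returns (retained, rejected) frames; the RD column is ``rd_pred`` when
    present, else ``rd_pct``.
    """
    col = "rd_pred" if "rd_pred" in front.columns else "rd_pct"
    if len(front) == 0:
        return front.copy(), front.copy()
    keep = (front[col] >= low) & (front[col] <= high)
    return front[keep].copy(), front[~keep].copy()


def optimize_all_groups(model, dataset: pd.DataFrame,
                        config: NSGAConfig | None = None,
                        rd_window: tuple = (20.0, 40.0)) -> dict:
    """Stratified optimization: one merged, filtered front per size group.

    Returns {size_class: {"front", "retained", "rejected"}} plus a
    bookkeeping report of front sizes before/after RD filtering.
    """
    out = {}
    for cls in SIZE_CLASSES:
        group = dataset[dataset["size_class"] == cls]
        if len(group) == 0:
            continue
        front = optimize_group(model, group, cls, config)
        retained, rejected = rd_filter(front, *rd_window)
        out[cls] = {"front": front, "retained": retained,
                    "rejected": rejected}
    report = {cls: {"front_size": len(v["front"]),
                    "retained": len(v["retained"]),
                    "rejected": len(v["rejected"])}
              for cls, v in out.items()}
    out["report"] = report
    return out


__all__ = [
    "OBJECTIVE_COLUMNS", "NSGAConfig", "NSGAResult", "dominates",
    "fast_non_dominated_sort", "crowding_distance", "sbx_crossover",
    "polynomial_mutation", "run_nsga2", "group_bounds", "optimize_group",
    "rd_filter", "optimize_all_groups",
]
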