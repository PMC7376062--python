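"""Multiobjective optimization over the emulator (NSGA-II) and the
Vargha–Delaney A effect size.

The optimizer searches the 13-dimensional simulation-parameter box for the
Pareto-optimal trade-offs between fitting experimentally measured migration
statistics (minimize |prediction − target| for speed, meandering index,
motility coefficient) and maximizing the stromal scanning rate. NSGA-II is
implemented directly: fast nondominated sorting, crowding-distance
selection, simulated-binary crossover and polynomial mutation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Vargha–Delaney A


def vargha_delaney_A(x, y) -> float:
    """Probability that a draw from x exceeds a draw from y (ties count half).

    0.5 means no effect; 0.56 / 0.64 / 0.71 are the customary small /
    medium / large thresholds.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (x.size * y.size))


def a_test_magnitude(a: float) -> str:
    d = abs(a - 0.5)
    if d >= 0.21:
        return "large"
    if d >= 0.14:
        return "medium"
    if d >= 0.06:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# NSGA-II


@dataclass
class ObjectiveSpec:
    """Calibration targets and objective senses.

    Three fit objectives (minimize |emulated − target|) plus scanning-rate
    maximization. Targets are the experimental migration statistics the
    simulator is calibrated to.
    """

    speed_target: float = 6.0  # µm/min
    meandering_target: float = 0.35
    motility_target: float = 15.0  # µm²/min

    def __post_init__(self) -> None:
        for v in (self.speed_target, self.meandering_target, self.motility_target):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("targets must be finite and positive")

    OBJECTIVE_NAMES = ("speed_error", "meandering_error",
                       "motility_error", "scanning_rate")
    SENSES = ("min", "min", "min", "max")

    def evaluate(self, emulators: dict, X: np.ndarray) -> np.ndarray:
        """Objective matrix (n, 4) in natural sense for a batch of parameter sets."""
        X = np.atleast_2d(X)
        return np.column_stack(
            [
                np.sqrt((emulators["speed"].predict(X) - self.speed_target) ** 2),
                np.sqrt(
                    (emulators["meandering_index"].predict(X)
                     - self.meandering_target) ** 2
                ),
                np.sqrt(
                    (emulators["motility_coefficient"].predict(X)
                     - self.motility_target) ** 2
                ),
                emulators["scanning_rate"].predict(X),
            ]
        )


@dataclass
class ParetoResult:
    """Nondominated parameter sets with their objective values (natural sense)."""

    X: np.ndarray  # (n, d)
    F: np.ndarray  # (n, n_obj)
    senses: tuple
    param_names: tuple | None = None
    objective_names: tuple | None = None
    history: list = field(default_factory=list)  # per-generation hypervolume

    def to_frame(self) -> pd.DataFrame:
        pn = self.param_names or tuple(f"x{i}" for i in range(self.X.shape[1]))
        on = self.objective_names or tuple(
            f"f{i}" for i in range(self.F.shape[1])
        )
        return pd.concat(
            [pd.DataFrame(self.X, columns=list(pn)),
             pd.DataFrame(self.F, columns=list(on))],
            axis=1,
        )

    def marginals(self) -> pd.DataFrame:
        return self.to_frame().describe().T


def _minimized(F: np.ndarray, senses) -> np.ndarray:
    """Flip maximized columns so every objective is minimized."""
    F = np.array(F, float)
    for j, s in enumerate(senses):
        if s == "max":
            F[:, j] = -F[:, j]
    return F


def dominates(f: np.ndarray, g: np.ndarray) -> bool:
    """True if minimization-vector f Pareto-dominates g."""
    return bool(np.all(f <= g) and np.any(f < g))


def _dominance_matrix(F: np.ndarray) -> np.ndarray:
    """dom[i, j] True where row i Pareto-dominates row j (minimization)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    return le & lt


def nondominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of nondominated rows of a minimization matrix."""
    return ~_dominance_matrix(np.asarray(F, float)).any(axis=0)


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition rows into nondomination fronts (front 0 first)."""
    dom = _dominance_matrix(np.asarray(F, float))
    counts = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(len(F), bool)
    while remaining.any():
        front = remaining & (counts == 0)
        if not front.any():  # numerical safety; cannot occur for finite F
            front = remaining
        fronts.append(np.flatnonzero(front))
        remaining &= ~front
        counts = counts - dom[front].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j])
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], j] - F[order[0], j]
        if span > 0 and n > 2:
            d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


def hypervolume_2d(F: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume of a 2D minimization front against a reference point."""
    pts = F[nondominated_mask(F)]
    pts = pts[(pts[:, 0] <= ref[0]) & (pts[:, 1] <= ref[1])]
    if len(pts) == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0])]
    hv, prev_y = 0.0, ref[1]
    for x, y in pts:
        hv += (ref[0] - x) * (prev_y - y)
        prev_y = y
    return float(hv)


def _sbx(rng, a, b, lo, hi, eta=15.0, prob=0.9):
    """Simulated binary crossover per variable."""
    c1, c2 = a.copy(), b.copy()
    do = rng.random(len(a)) < prob
    u = rng.random(len(a))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    x1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    x2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    c1[do], c2[do] = x1[do], x2[do]
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(rng, x, lo, hi, eta=20.0, rate=None):
    rate = rate if rate is not None else 1.0 / len(x)
    y = x.copy()
    do = rng.random(len(x)) < rate
    if do.any():
        u = rng.random(do.sum())
        span = (hi - lo)[do]
        delta = np.where(
            u < 0.5,
            (2 * u) ** (1 / (eta + 1)) - 1,
            1 - (2 * (1 - u)) ** (1 / (eta + 1)),
        )
        y[do] = np.clip(y[do] + delta * span, lo[do], hi[do])
    return y


def nsga2(
    objective_fn,
    bounds,
    pop: int = 100,
    gens: int = 250,
    seed: int = 0,
    senses=("min",),
    param_names=None,
    objective_names=None,
    eta_sbx: float = 15.0,
    eta_mut: float = 20.0,
) -> ParetoResult:
    """NSGA-II over a box-bounded parameter space.

    ``objective_fn(X)`` maps an (n, d) batch to an (n, n_obj) matrix of
    objective values in their natural sense; ``senses`` marks each column
    "min" or "max". Returns the final nondominated set.
    """
    bounds = np.asarray(bounds, float).reshape(-1, 2)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if (lo >= hi).any():
        raise ValueError("degenerate bounds")
    if pop < 4 or pop % 2:
        raise ValueError("pop must be even and >= 4")
    rng = np.random.default_rng(seed)
    d = len(bounds)

    X = lo + rng.random((pop, d)) * (hi - lo)
    F_nat = np.atleast_2d(objective_fn(X))
    senses = tuple(senses) if len(senses) == F_nat.shape[1] else \
        tuple(["min"] * F_nat.shape[1])
    F = _minimized(F_nat, senses)
    history = []

    for _ in range(gens):
        # binary tournaments on (rank, -crowding)
        fronts = fast_nondominated_sort(F)
        rank = np.empty(pop, int)
        for r, fr in enumerate(fronts):
            rank[fr] = r
        crowd = np.zeros(pop)
        for fr in fronts:
            crowd[fr] = crowding_distance(F[fr])

        def tourney():
            i, j = rng.integers(0, pop, 2)
            if rank[i] < rank[j] or (rank[i] == rank[j] and crowd[i] > crowd[j]):
                return i
            return j

        children = []
        while len(children) < pop:
            a, b = X[tourney()], X[tourney()]
            c1, c2 = _sbx(rng, a, b, lo, hi, eta=eta_sbx)
            children.append(_poly_mutation(rng, c1, lo, hi, eta=eta_mut))
            children.append(_poly_mutation(rng, c2, lo, hi, eta=eta_mut))
        C = np.array(children[:pop])
        FC = _minimized(np.atleast_2d(objective_fn(C)), senses)

        XA = np.vstack([X, C])
        FA = np.vstack([F, FC])
        fronts = fast_nondominated_sort(FA)
        keep: list[int] = []
        for fr in fronts:
            if len(keep) + len(fr) <= pop:
                keep.extend(fr.tolist())
            else:
                cd = crowding_distance(FA[fr])
                order = fr[np.argsort(-cd)]
                keep.extend(order[: pop - len(keep)].tolist())
                break
        X, F = XA[keep], FA[keep]
        if F.shape[1] == 2:
            history.append(hypervolume_2d(F, ref=np.array([1.1, 1.1])))

    mask = nondominated_mask(F)
    F_final_nat = _minimized(F[mask], senses)  # flip back to natural sense
    return ParetoResult(
        X=X[mask],
        F=F_final_nat,
        senses=senses,
        param_names=param_names,
        objective_names=objective_names,
        history=history,
    )


def conflict_analysis(front: ParetoResult) -> pd.DataFrame:
    """Rank correlation between the scanning objective and each fit objective.

    Negative correlation (better scanning ↔ worse fit) marks the trade-off
    between surveying the stromal network and matching measured migration.
    """
    if len(front.F) < 3:
        import warnings

        warnings.warn("front too small for conflict analysis", stacklevel=2)
        return pd.DataFrame(columns=["objective", "spearman_rho", "p_value"])
    names = front.objective_names or tuple(f"f{i}" for i in range(front.F.shape[1]))
    senses = front.senses
    # correlate in minimization form: negative rho = conflict
    Fm = _minimized(front.F, senses)
    scan_cols = [j for j, s in enumerate(senses) if s == "max"]
    scan_j = scan_cols[-1] if scan_cols else front.F.shape[1] - 1
    rows = []
    for j in range(front.F.shape[1]):
        if j == scan_j:
            continue
        rho, p = sps.spearmanr(Fm[:, scan_j], Fm[:, j])
        rows.append({"objective": names[j], "spearman_rho": float(rho),
                     "p_value": float(p)})
    return pd.DataFrame(rows)
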