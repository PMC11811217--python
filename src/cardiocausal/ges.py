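"""Greedy Equivalence Search with decomposable scores for mixed data.

The search is the classic two-phase procedure over Markov equivalence
classes: a forward sweep that greedily applies the best valid *insert*
operator until no insertion improves the score, then a backward sweep of
*delete* operators.  Operator validity follows the standard formulation
(clique condition on the shared neighbourhood, semi-directed path blocking
for inserts), and after every accepted move the state is re-completed to a
CPDAG via a consistent extension.

Two local scores are provided:

* ``bic`` — Gaussian BIC computed from the covariance matrix.  Fast,
  score-equivalent across Markov-equivalent DAGs, and cheap enough that an
  exhaustive search over all DAGs (:func:`exhaustive_best_dag`) can serve
  as an independent oracle on up to four variables.
* ``kernel`` — a generalized score for mixed continuous/binary data:
  k-fold cross-validated predictive log-likelihood of a kernel-ridge
  regression of the node on its parents (RBF kernel, median-heuristic
  bandwidth).  Binary variables enter through their {0,1} values, so one
  score covers linear, nonlinear, continuous and discrete relationships
  uniformly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import Cpdag, PDag, dag_to_cpdag, pdag_to_dag

__all__ = [
    "MixedDataset",
    "ScoreModel",
    "Scorer",
    "score_local",
    "ges_search",
    "exhaustive_best_dag",
]

_VARIANCE_FLOOR = 1e-12


@dataclass
class MixedDataset:
    """Standardized data matrix plus per-column typing.

    Continuous columns are standardized to zero mean / unit variance so the
    kernel bandwidth is comparable across variables; binary columns are kept
    on their {0,1} coding.
    """

    names: list[str]
    types: list[str]  # "continuous" | "binary"
    X: np.ndarray  # n_samples x n_vars, float
    target: str | None = None

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("data matrix shape does not match variable names")
        if len(self.types) != len(self.names):
            raise ValueError("types must match names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("data contains missing or non-finite values")
        for j, t in enumerate(self.types):
            if t == "binary" and not set(np.unique(self.X[:, j])) <= {0.0, 1.0}:
                raise ValueError(f"binary column {self.names[j]!r} is not 0/1")
        if self.target is not None and self.target not in self.names:
            raise ValueError(f"target {self.target!r} not among variables")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str | None = None,
        binary: set[str] | None = None,
        standardize: bool = True,
    ) -> "MixedDataset":
        if binary is None:
            binary = {
                c
                for c in df.columns
                if set(pd.unique(df[c].dropna())) <= {0, 1, 0.0, 1.0, True, False}
            }
        X = df.to_numpy(dtype=float).copy()
        types = []
        for j, c in enumerate(df.columns):
            if c in binary:
                types.append("binary")
            else:
                types.append("continuous")
                if standardize:
                    mu = X[:, j].mean()
                    sd = X[:, j].std()
                    X[:, j] = (X[:, j] - mu) / (sd if sd > 0 else 1.0)
        return cls(list(df.columns), types, X, target=target)


@dataclass
class ScoreModel:
    """Configuration of the local score.

    Parameters
    ----------
    kind:
        ``"bic"`` or ``"kernel"``.
    penalty:
        BIC penalty multiplier (1.0 is the classic criterion).
    ridge_lambda:
        Ridge regularization of the kernel regression, > 0.
    cv_folds:
        Cross-validation folds for the kernel score, >= 2.
    fold_seed:
        Seed fixing the fold assignment; the score is deterministic given it.
    """

    kind: str = "bic"
    penalty: float = 1.0
    ridge_lambda: float = 0.01
    cv_folds: int = 10
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("bic", "kernel"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.ridge_lambda <= 0:
            raise ValueError("ridge_lambda must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


class Scorer:
    """Decomposable local scorer with a (node, parent-set) cache."""

    def __init__(self, data: MixedDataset, model: ScoreModel):
        self.data = data
        self.model = model
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        n = data.n
        Xc = data.X - data.X.mean(axis=0)
        self._cov = (Xc.T @ Xc) / n  # ML covariance, used by the BIC score
        self._folds: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- public -------------------------------------------------------
    def local(self, node: int, parents: frozenset[int]) -> float:
        if node in parents:
            raise ValueError("a node cannot be its own parent")
        key = (node, parents)
        if key not in self._cache:
            if self.model.kind == "bic":
                val = self._bic_local(node, parents)
            else:
                val = self._kernel_local(node, parents)
            if not math.isfinite(val):
                raise FloatingPointError(
                    f"non-finite local score for node {self.data.names[node]!r} "
                    f"with parents {sorted(self.data.names[p] for p in parents)}"
                )
            self._cache[key] = val
        return self._cache[key]

    def total(self, parent_map: dict[int, frozenset[int]]) -> float:
        return sum(self.local(v, ps) for v, ps in parent_map.items())

    # -- BIC ------------------------------------------------------------
    def _bic_local(self, node: int, parents: frozenset[int]) -> float:
        n = self.data.n
        C = self._cov
        if parents:
            P = sorted(parents)
            cyy = C[node, node]
            cyp = C[node, P]
            cpp = C[np.ix_(P, P)]
            try:
                beta = np.linalg.solve(cpp, cyp)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(cpp, cyp, rcond=None)[0]
            sigma2 = cyy - cyp @ beta
        else:
            sigma2 = C[node, node]
        sigma2 = max(float(sigma2), _VARIANCE_FLOOR)
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = len(parents) + 1  # regression coefficients + residual variance
        return ll - 0.5 * self.model.penalty * k * math.log(n)

    # -- kernel generalized score ---------------------------------------
    def _fold_indices(self) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._folds is None:
            from sklearn.model_selection import KFold

            k = min(self.model.cv_folds, self.data.n)
            kf = KFold(n_splits=k, shuffle=True, random_state=self.model.fold_seed)
            self._folds = [
                (tr, te) for tr, te in kf.split(np.arange(self.data.n))
            ]
        return self._folds

    def _kernel_local(self, node: int, parents: frozenset[int]) -> float:
        y = self.data.X[:, node]
        if float(np.var(y)) < _VARIANCE_FLOOR:
            # degenerate node: constant under any parent set
            import warnings

            warnings.warn(
                f"variable {self.data.names[node]!r} is (near) constant; "
                "its score uses the variance floor",
                RuntimeWarning,
                stacklevel=3,
            )
        total = 0.0
        if not parents:
            for tr, te in self._fold_indices():
                mu = y[tr].mean()
                s2 = max(float(np.var(y[tr])), 1e-6)
                total += float(
                    np.sum(-0.5 * (np.log(2 * np.pi * s2) + (y[te] - mu) ** 2 / s2))
                )
            return total
        from sklearn.metrics.pairwise import euclidean_distances, rbf_kernel

        Z = self.data.X[:, sorted(parents)]
        lam = self.model.ridge_lambda
        for tr, te in self._fold_indices():
            Ztr, Zte = Z[tr], Z[te]
            d2 = euclidean_distances(Ztr, squared=True)
            med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
            gamma = 1.0 / med
            K = rbf_kernel(Ztr, gamma=gamma)
            ntr = len(tr)
            alpha = np.linalg.solve(K + ntr * lam * np.eye(ntr), y[tr])
            fit_tr = K @ alpha
            s2 = max(float(np.mean((y[tr] - fit_tr) ** 2)), 1e-6)
            pred = rbf_kernel(Zte, Ztr, gamma=gamma) @ alpha
            total += float(
                np.sum(-0.5 * (np.log(2 * np.pi * s2) + (y[te] - pred) ** 2 / s2))
            )
        return total


def score_local(
    data: MixedDataset,
    node: str,
    parent_set: set[str] | frozenset[str],
    model: ScoreModel,
    scorer: Scorer | None = None,
) -> float:
    """Local score S(node | parents); see :class:`ScoreModel` for kinds."""
    sc = scorer if scorer is not None else Scorer(data, model)
    return sc.local(data.index(node), frozenset(data.index(p) for p in parent_set))


# ---------------------------------------------------------------------------
# GES proper
# ---------------------------------------------------------------------------


@dataclass
class _Move:
    op: str  # "insert" | "delete"
    x: int
    y: int
    subset: tuple[int, ...]
    delta: float

    def sort_key(self, names: list[str]) -> tuple:
        return (names[self.x], names[self.y], tuple(names[t] for t in self.subset))


def _consistent_parent_map(g: PDag, data: MixedDataset) -> dict[int, frozenset[int]]:
    dag = pdag_to_dag(g)
    idx = {v: data.index(v) for v in data.names}
    return {
        idx[v]: frozenset(idx[p] for p in dag.parents(v)) for v in data.names
    }


def _forward_moves(g: PDag, data: MixedDataset, scorer: Scorer, max_subset: int | None):
    names = data.names
    for y in names:
        yi = data.index(y)
        pa_y = {data.index(p) for p in g.parents(y)}
        for x in names:
            if x == y or g.adjacent(x, y):
                continue
            xi = data.index(x)
            nb_y = g.undirected_neighbors(y)
            na = {t for t in nb_y if g.adjacent(t, x)}
            t0 = sorted((t for t in nb_y if not g.adjacent(t, x)), key=str)
            limit = len(t0) if max_subset is None else min(max_subset, len(t0))
            for r in range(limit + 1):
                for T in itertools.combinations(t0, r):
                    block = na | set(T)
                    if not g.is_clique(block):
                        continue
                    if g.has_semidirected_path(y, x, avoiding=block):
                        continue
                    cond = pa_y | {data.index(t) for t in block}
                    delta = scorer.local(yi, frozenset(cond | {xi})) - scorer.local(
                        yi, frozenset(cond)
                    )
                    yield _Move("insert", xi, yi, tuple(data.index(t) for t in T), delta)


def _backward_moves(g: PDag, data: MixedDataset, scorer: Scorer):
    names = data.names
    for y in names:
        yi = data.index(y)
        pa_y = {data.index(p) for p in g.parents(y)}
        for x in names:
            if x == y:
                continue
            if not (g.has_directed(x, y) or g.has_undirected(x, y)):
                continue
            xi = data.index(x)
            na = sorted(
                (t for t in g.undirected_neighbors(y) if g.adjacent(t, x)), key=str
            )
            for r in range(len(na) + 1):
                for H in itertools.combinations(na, r):
                    keep = set(na) - set(H)
                    if not g.is_clique(keep):
                        continue
                    cond = (pa_y | {data.index(t) for t in keep}) - {xi}
                    delta = scorer.local(yi, frozenset(cond)) - scorer.local(
                        yi, frozenset(cond | {xi})
                    )
                    yield _Move("delete", xi, yi, tuple(data.index(h) for h in H), delta)


def _apply_insert(g: PDag, data: MixedDataset, mv: _Move) -> Cpdag:
    x, y = data.names[mv.x], data.names[mv.y]
    g = g.copy()
    g.add_directed(x, y)
    for ti in mv.subset:
        g.orient(data.names[ti], y)
    return dag_to_cpdag(pdag_to_dag(g))


def _apply_delete(g: PDag, data: MixedDataset, mv: _Move) -> Cpdag:
    x, y = data.names[mv.x], data.names[mv.y]
    g = g.copy()
    g.remove_edge(x, y)
    for hi in mv.subset:
        h = data.names[hi]
        if g.has_undirected(y, h):
            g.orient(y, h)
        if g.has_undirected(x, h):
            g.orient(x, h)
    return dag_to_cpdag(pdag_to_dag(g))


def ges_search(
    data: MixedDataset,
    model: ScoreModel,
    seed: int | None = None,
    max_subset: int | None = None,
    min_improvement: float = 1e-9,
    max_moves: int | None = None,
    trace: list[dict] | None = None,
) -> Cpdag:
    """Two-phase Greedy Equivalence Search.

    Starts from the empty equivalence class, greedily applies the single
    best score-increasing insert operator until none remains, then the best
    delete operator likewise.  Every accepted move strictly increases the
    total decomposable score.  Ties between equal-score moves are broken
    lexicographically on (source, target, subset) node names so the search
    is deterministic.

    Parameters
    ----------
    seed:
        Overrides ``model.fold_seed`` for the kernel score's fold draw.
    max_subset:
        Optional cap on the insert-operator subset size (speed knob).
    trace:
        If a list is supplied, one record per accepted move is appended.

    Returns the completed CPDAG at the local maximum.
    """
    if seed is not None and model.kind == "kernel":
        model = ScoreModel(
            kind=model.kind,
            penalty=model.penalty,
            ridge_lambda=model.ridge_lambda,
            cv_folds=model.cv_folds,
            fold_seed=seed,
        )
    scorer = Scorer(data, model)
    g: Cpdag = Cpdag(data.names)
    budget = max_moves if max_moves is not None else 4 * data.n_vars**2
    n_moves = 0
    for phase, gen, apply in (
        ("forward", _forward_moves, _apply_insert),
        ("backward", _backward_moves, _apply_delete),
    ):
        while True:
            if n_moves >= budget:
                raise RuntimeError("GES exceeded its move budget without converging")
            best: _Move | None = None
            args = (g, data, scorer, max_subset) if phase == "forward" else (g, data, scorer)
            for mv in gen(*args):
                if mv.delta <= min_improvement:
                    continue
                if best is None or mv.delta > best.delta + 1e-12 or (
                    abs(mv.delta - best.delta) <= 1e-12
                    and mv.sort_key(data.names) < best.sort_key(data.names)
                ):
                    best = mv
            if best is None:
                break
            g = apply(g, data, best)
            n_moves += 1
            if trace is not None:
                trace.append(
                    {
                        "phase": phase,
                        "op": best.op,
                        "x": data.names[best.x],
                        "y": data.names[best.y],
                        "subset": [data.names[t] for t in best.subset],
                        "delta": best.delta,
                    }
                )
    g.provenance = {
        "score": model.kind,
        "seed": model.fold_seed if model.kind == "kernel" else None,
        "n": data.n,
        "moves": n_moves,
    }
    return g


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def _all_dags(names: list[str]):
    """Yield every DAG on the given nodes (3 states per unordered pair)."""
    pairs = list(itertools.combinations(names, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = PDag(names)
        for (a, b), s in zip(pairs, states):
            if s == 1:
                g.add_directed(a, b)
            elif s == 2:
                g.add_directed(b, a)
        try:
            g.topological_order()
        except ValueError:
            continue
        yield g


def exhaustive_best_dag(
    data: MixedDataset, model: ScoreModel
) -> tuple[Cpdag, float]:
    """Score every DAG (refused above 4 variables) and return the CPDAG of
    the best-scoring one together with its total score.

    Intended as an independent oracle for :func:`ges_search`: it shares the
    local score but explores the space by brute force rather than greedy
    equivalence-class moves.
    """
    if data.n_vars > 4:
        raise ValueError("exhaustive search is limited to at most 4 variables")
    scorer = Scorer(data, model)
    idx = {v: i for i, v in enumerate(data.names)}
    best_g: PDag | None = None
    best_s = -math.inf
    for g in _all_dags(data.names):
        s = sum(
            scorer.local(idx[v], frozenset(idx[p] for p in g.parents(v)))
            for v in data.names
        )
        if s > best_s + 1e-12:
            best_s = s
            best_g = g
    assert best_g is not None
    return dag_to_cpdag(best_g), best_s
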