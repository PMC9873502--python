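"""Typical/skewed cell classification by trimmed Gaussian clustering.

The cohort's coverage matrix (cells x 100 bins) is reduced to decile means
(``pmean10`` .. ``pmean100``, cells x 10) and a single Gaussian component is
fitted to the best-fitting ``floor(n*(1-alpha))`` cells by classification
trimmed likelihood (TCLUST with k=1).  Retained cells are *typical*; the
trimmed ``alpha`` fraction are *skewed*.  Covariance eigenvalues are
constrained to a maximum ratio (``restr_factor``) which also regularizes the
one exactly-zero eigenvalue induced by the rows-sum-to-one constraint.

The solver is the classical concentration algorithm: initialize from a
random (d+1)-subset, score all points under the current Gaussian, retain the
h highest-density points, refit with eigenvalue clipping, iterate to a fixed
retained set; best of ``n_starts`` restarts wins.  Deterministic given a
seed, and equivariant under row permutation because restarts draw from a
canonical (lexicographic) ordering of the rows.

When no trimming level is given, a classification-trimmed-likelihood curve
is computed over a grid of alphas and the elbow (maximum discrete curvature)
is selected.  On coverage cohorts the curve typically rises while genuine
outliers remain and flattens or falls once trimming starts discarding
well-fitting cells, so the elbow and the curve's peak usually coincide; the
elbow rule handles both shapes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageVector, read_store, write_store_tsv
from .errors import DegenerateDataError, FormatError, InputError, ParameterError

log = logging.getLogger(__name__)

N_BINS = 100
N_DECILES = 10

DEFAULT_ALPHA_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_RESTR_FACTOR = 50.0
DEFAULT_N_STARTS = 64
DEFAULT_MAX_ITER = 100
SELECTION_RULE_ID = "curvature-elbow-v1"

TYPICAL = "typical"
SKEWED = "skewed"


# ---------------------------------------------------------------------------
# Matrices


@dataclass
class CoverageMatrix:
    """Cells x 100-bin coverage values with aligned cell IDs.

    Conceptually 101 columns: the identifier plus 100 bins.
    """

    cell_ids: list[str]
    values: np.ndarray  # n x 100
    degenerate: np.ndarray  # n bools; all-zero rows

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"bin{i}" for i in range(1, N_BINS + 1)])
        df.insert(0, "cell_id", self.cell_ids)
        return df


@dataclass
class MeanCoverageMatrix:
    """Cells x 10 decile means (pmean10..pmean100); degenerate rows removed."""

    cell_ids: list[str]
    means: np.ndarray  # n x 10
    dropped_degenerate: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def columns(self) -> list[str]:
        return [f"pmean{10 * j}" for j in range(1, N_DECILES + 1)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.means, columns=self.columns)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def assemble_coverage_matrix(store: str | Path | list[CoverageVector]) -> CoverageMatrix:
    """Build the coverage matrix from a CoverageStore path (either dialect).

    Rows keep store order; duplicate cell IDs are rejected; all-zero rows are
    carried but flagged degenerate.
    """
    vectors = read_store(store) if isinstance(store, (str, Path)) else store
    ids = [v.cell_id for v in vectors]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise FormatError(f"duplicate cell IDs in store: {sorted(dup)}")
    values = np.vstack([v.values for v in vectors])
    degenerate = np.array([v.values.sum() == 0 for v in vectors])
    return CoverageMatrix(cell_ids=ids, values=values, degenerate=degenerate)


def decile_means(cov: CoverageMatrix) -> MeanCoverageMatrix:
    """Reduce 100 bins to 10 decile means; drop degenerate rows (logged).

    ``means[:, j] = mean(values[:, 10j .. 10j+9])``.  Raises when every row
    is degenerate — there is nothing to cluster.
    """
    if len(cov) == 0:
        raise DegenerateDataError("empty coverage matrix")
    keep = ~cov.degenerate
    dropped = [cid for cid, d in zip(cov.cell_ids, cov.degenerate) if d]
    if dropped:
        log.warning("decile_means: dropping %d degenerate (all-zero) cells: %s",
                    len(dropped), dropped[:5])
    if not keep.any():
        raise DegenerateDataError("no usable cells: all coverage rows are zero")
    vals = cov.values[keep]
    means = vals.reshape(vals.shape[0], N_DECILES, N_BINS // N_DECILES).mean(axis=2)
    ids = [cid for cid, k in zip(cov.cell_ids, keep) if k]
    return MeanCoverageMatrix(cell_ids=ids, means=means, dropped_degenerate=dropped)


# ---------------------------------------------------------------------------
# Trimmed Gaussian fit (TCLUST, k=1)


@dataclass
class ClusterResult:
    """One trimmed-Gaussian fit and its per-cell typical/skewed labels."""

    alpha: float
    k: int
    center: np.ndarray
    covariance: np.ndarray
    objective: float
    labels: list[str]  # per cell, TYPICAL or SKEWED, aligned with input rows
    cell_ids: list[str] = field(default_factory=list)
    restr_factor: float = DEFAULT_RESTR_FACTOR
    seed: int = 1
    n_starts: int = DEFAULT_N_STARTS
    n_iter: int = 0
    degenerate_cells: list[str] = field(default_factory=list)

    @property
    def n_typical(self) -> int:
        return sum(1 for lab in self.labels if lab == TYPICAL)

    @property
    def n_skewed(self) -> int:
        return sum(1 for lab in self.labels if lab == SKEWED)

    def typical_ids(self) -> list[str]:
        return [c for c, lab in zip(self.cell_ids, self.labels) if lab == TYPICAL]

    def skewed_ids(self) -> list[str]:
        return [c for c, lab in zip(self.cell_ids, self.labels) if lab == SKEWED]


def clip_eigenvalues(eigvals: np.ndarray, restr_factor: float) -> np.ndarray:
    """Constrain eigenvalues so max/min <= restr_factor, maximizing likelihood.

    The constrained maximum-likelihood spectrum is ``clip(d_j, m, c*m)`` with
    the truncation point ``m`` minimizing ``sum_j log(d*_j) + d_j/d*_j``; the
    optimum lies among the candidates ``{d_j, d_j/c}``.
    """
    d = np.asarray(eigvals, dtype=float)
    d = np.maximum(d, 0.0)  # numerical negatives from eigh
    if d.max() <= 0:
        raise DegenerateDataError("all covariance eigenvalues are zero "
                                  "(points identical)")
    dmin = d.min()
    if dmin > 0 and d.max() / dmin <= restr_factor:
        return d
    candidates = np.unique(np.concatenate([d, d / restr_factor]))
    candidates = candidates[candidates > 0]
    best_m, best_f = None, np.inf
    for m in candidates:
        dd = np.clip(d, m, restr_factor * m)
        f = float(np.sum(np.log(dd) + d / dd))
        if f < best_f - 1e-15:
            best_f, best_m = f, m
    return np.clip(d, best_m, restr_factor * best_m)


def _constrained_fit(X: np.ndarray, restr_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and ratio-constrained MLE covariance of the rows of X."""
    mu = X.mean(axis=0)
    xc = X - mu
    cov = xc.T @ xc / X.shape[0]
    cov = (cov + cov.T) / 2
    vals, vecs = np.linalg.eigh(cov)
    vals = clip_eigenvalues(vals, restr_factor)
    return mu, (vecs * vals) @ vecs.T


def _gaussian_logpdf(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, (X - mu).T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * math.log(2 * math.pi) + logdet + maha)


def tclust_k1(
    X: np.ndarray,
    alpha: float,
    restr_factor: float = DEFAULT_RESTR_FACTOR,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 1,
    cell_ids: list[str] | None = None,
) -> ClusterResult:
    """Fit one Gaussian to the best floor(n*(1-alpha)) rows of X.

    Concentration steps from ``n_starts`` random (d+1)-subset initializations;
    the restart with the highest trimmed log-likelihood wins.  Retained rows
    are labeled typical, trimmed rows skewed.  Deterministic given ``seed``
    and invariant (up to relabeling of identical rows) under row permutation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError("X must be a 2-D matrix")
    n, d = X.shape
    if not 0 <= alpha < 1:
        raise ParameterError(f"alpha must be in [0, 1), got {alpha}")
    h = math.floor(n * (1 - alpha))
    if h < d + 1:
        raise ParameterError(
            f"floor(n*(1-alpha)) = {h} retained points, need >= d+1 = {d + 1}"
        )
    if restr_factor < 1:
        raise ParameterError("restr_factor must be >= 1")
    if np.allclose(X, X[0]):
        raise DegenerateDataError("all points identical; covariance is singular")

    # canonical row order makes restarts permutation-equivariant
    canon = np.lexsort(X.T[::-1])
    rng = np.random.default_rng(seed)

    best_obj = -np.inf
    best_retained: np.ndarray | None = None
    best_mu = best_cov = None
    best_iters = 0
    for _ in range(max(1, n_starts)):
        init_pos = rng.choice(n, size=d + 1, replace=False)
        subset = X[canon[np.sort(init_pos)]]
        try:
            mu, cov = _constrained_fit(subset, restr_factor)
        except DegenerateDataError:
            continue
        retained_prev: np.ndarray | None = None
        iters = 0
        for iters in range(1, max_iter + 1):
            logpdf = _gaussian_logpdf(X, mu, cov)
            # deterministic tie-break: stable sort on (-logpdf, canonical rank)
            rank = np.empty(n, dtype=int)
            rank[canon] = np.arange(n)
            order = np.lexsort((rank, -logpdf))
            retained = np.sort(order[:h])
            if retained_prev is not None and np.array_equal(retained, retained_prev):
                break
            retained_prev = retained
            mu, cov = _constrained_fit(X[retained], restr_factor)
        obj = float(_gaussian_logpdf(X[retained], mu, cov).sum())
        if obj > best_obj + 1e-12:
            best_obj, best_retained = obj, retained
            best_mu, best_cov, best_iters = mu, cov, iters

    if best_retained is None:
        raise DegenerateDataError("no valid initialization found")
    labels = [SKEWED] * n
    for i in best_retained:
        labels[i] = TYPICAL
    return ClusterResult(
        alpha=alpha,
        k=1,
        center=best_mu,
        covariance=best_cov,
        objective=best_obj,
        labels=labels,
        cell_ids=list(cell_ids) if cell_ids is not None else [str(i) for i in range(n)],
        restr_factor=restr_factor,
        seed=seed,
        n_starts=n_starts,
        n_iter=best_iters,
    )


# ---------------------------------------------------------------------------
# Alpha selection (classification trimmed likelihood curve)


@dataclass
class AlphaCurve:
    alphas: list[float]
    objectives: list[float]
    selected_alpha: float
    selection_rule_id: str = SELECTION_RULE_ID


def select_alpha(
    X: np.ndarray,
    alpha_grid: tuple[float, ...] | list[float] = DEFAULT_ALPHA_GRID,
    seed: int = 1,
    restr_factor: float = DEFAULT_RESTR_FACTOR,
    n_starts: int = DEFAULT_N_STARTS,
) -> AlphaCurve:
    """Choose a trimming level from the trimmed-likelihood curve's elbow.

    The objective of :func:`tclust_k1` is computed at every grid alpha (same
    seed).  The selected alpha maximizes discrete curvature — the drop in
    objective increment — with ties broken toward the smaller alpha.  A
    single-point grid short-circuits to that point.
    """
    grid = sorted(alpha_grid)
    if not grid:
        raise ParameterError("alpha grid must be non-empty")
    objectives = [
        tclust_k1(X, a, restr_factor=restr_factor, n_starts=n_starts, seed=seed).objective
        for a in grid
    ]
    if len(grid) == 1:
        return AlphaCurve(grid, objectives, grid[0])
    if len(grid) == 2:
        # no interior point; prefer the smaller alpha unless the larger gains
        sel = grid[1] if objectives[1] > objectives[0] else grid[0]
        return AlphaCurve(grid, objectives, sel)
    curv = [-np.inf] * len(grid)
    for i in range(1, len(grid) - 1):
        left = (objectives[i] - objectives[i - 1]) / (grid[i] - grid[i - 1])
        right = (objectives[i + 1] - objectives[i]) / (grid[i + 1] - grid[i])
        curv[i] = left - right
    best = max(range(len(grid)), key=lambda i: (curv[i], -grid[i]))
    return AlphaCurve(grid, objectives, grid[best])


# ---------------------------------------------------------------------------
# Pipeline-facing classification and filtering


def classify_cells(
    meanmat: MeanCoverageMatrix,
    alphas: list[float] | None = None,
    prjname: str = "COV",
    seed: int = 1,
    restr_factor: float = DEFAULT_RESTR_FACTOR,
    n_starts: int = DEFAULT_N_STARTS,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
) -> list[tuple[float, ClusterResult]]:
    """Run trimmed clustering in one of three alpha modes.

    * ``alphas`` empty/None — auto: pick alpha from the trimmed-likelihood
      curve elbow, then one run at the selected value;
    * one value — a single run;
    * several values — one independent run per value.

    Degenerate cells were already removed upstream; their IDs ride along on
    each result so reports can list them as unscorable.
    """
    if len(meanmat) == 0:
        raise ParameterError("empty mean coverage matrix")
    X = meanmat.means
    n, d = X.shape
    requested = list(alphas or [])
    for a in requested:
        if not 0 <= a < 1:
            raise ParameterError(f"alpha must be in [0, 1), got {a}")
        if math.floor(n * (1 - a)) < d + 1:
            raise ParameterError(
                f"alpha={a} leaves {math.floor(n * (1 - a))} cells, need >= {d + 1}"
            )
    if not requested:
        curve = select_alpha(X, alpha_grid, seed=seed, restr_factor=restr_factor,
                             n_starts=n_starts)
        log.info("%s: auto-selected alpha = %g (rule %s)", prjname,
                 curve.selected_alpha, curve.selection_rule_id)
        requested = [curve.selected_alpha]
    results = []
    for a in requested:
        res = tclust_k1(X, a, restr_factor=restr_factor, n_starts=n_starts,
                        seed=seed, cell_ids=meanmat.cell_ids)
        res.degenerate_cells = list(meanmat.dropped_degenerate)
        results.append((a, res))
    return results


def write_annotation_tables(result: ClusterResult, outdir: str | Path,
                            prjname: str = "COV") -> dict[str, Path]:
    """Write TypicalCells.tsv / SkewedCells.tsv and the JSON annotation twin."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = f"_alpha{result.alpha:g}" if result.alpha else "_alpha0"
    paths = {}
    for label, ids, fname in (
        (TYPICAL, result.typical_ids(), f"TypicalCells{suffix}.tsv"),
        (SKEWED, result.skewed_ids(), f"SkewedCells{suffix}.tsv"),
    ):
        path = outdir / fname
        pd.DataFrame(
            {"cell_id": ids, "annotation": label, "alpha": result.alpha}
        ).to_csv(path, sep="\t", index=False)
        paths[label] = path
    ann = {
        "prjname": prjname,
        "alpha": result.alpha,
        "k": result.k,
        "restr_factor": result.restr_factor,
        "seed": result.seed,
        "objective": result.objective,
        "center": [float(v) for v in result.center],
        "n_typical": result.n_typical,
        "n_skewed": result.n_skewed,
        "typical_cells": result.typical_ids(),
        "skewed_cells": result.skewed_ids(),
        "degenerate_cells": result.degenerate_cells,
    }
    jpath = outdir / f"annotation{suffix}.json"
    with open(jpath, "w") as fh:
        json.dump(ann, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["json"] = jpath
    return paths


def filter_cells(
    store: str | Path,
    filter_list: str | Path,
    matchdir: str | Path = "match",
    unmatchdir: str | Path = "unmatch",
) -> tuple[int, int]:
    """Split a CoverageStore by an ID list; the unmatched store is re-clustered.

    Cells whose ID appears in ``filter_list`` (one ID per line) go to
    ``matchdir``'s store, the rest to ``unmatchdir``'s.  Listed IDs absent
    from the store are reported.  Returns (n_matched, n_unmatched).
    """
    filter_list = Path(filter_list)
    if not filter_list.exists():
        raise InputError(f"filter file not found: {filter_list}")
    wanted = [line.strip() for line in filter_list.read_text().splitlines()
              if line.strip()]
    if not wanted:
        raise FormatError(f"{filter_list}: empty filter file")
    wanted_set = set(wanted)
    vectors = read_store(store)
    present = {v.cell_id for v in vectors}
    missing = sorted(wanted_set - present)
    if missing:
        log.warning("filter_cells: %d listed IDs absent from store: %s",
                    len(missing), missing[:5])
    matched = [v for v in vectors if v.cell_id in wanted_set]
    unmatched = [v for v in vectors if v.cell_id not in wanted_set]
    for sub, d in ((matched, Path(matchdir)), (unmatched, Path(unmatchdir))):
        d.mkdir(parents=True, exist_ok=True)
        write_store_tsv(sub, d / "coverage.tsv")
    return len(matched), len(unmatched)
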