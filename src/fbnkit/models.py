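"""Functional-connectivity network models.

Three estimators of an m x m connectivity matrix from one subject's t x m
time-series matrix, in a statsmodels-like shape: construct a model object
around the data, call ``fit()``, get a :class:`ConnectivityResults` carrying
the weights, solver diagnostics and a ``summary()`` table.

* :class:`PearsonFBN` — pairwise Pearson correlation between regions.
* :class:`SparseFBN` — l1-penalised regression of each region on all
  others (sparse representation), fitted jointly with a zero-diagonal
  constraint.
* :class:`SparseLowRankFBN` — adds a trace-norm penalty to the sparse model
  so the coefficient matrix is pushed toward low rank, i.e. a modular
  network organisation.

Module-level convenience wrappers (:func:`pearson_fbn`, :func:`sparse_fbn`,
:func:`sparse_lowrank_fbn`) cover the common one-call use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SubjectTimeSeries
from .solvers import SolverReport, admm_sparse_lowrank

__all__ = [
    "zscore_columns",
    "PearsonFBN",
    "SparseFBN",
    "SparseLowRankFBN",
    "ConnectivityResults",
    "BinaryNetwork",
    "pearson_fbn",
    "sparse_fbn",
    "sparse_lowrank_fbn",
    "symmetrize",
    "binarize",
]

_ZERO_TOL = 1e-10


def zscore_columns(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Standardise each region's series to mean 0, population sd 1."""
    sd = ts.data.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.region_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    data = (ts.data - ts.data.mean(axis=0)) / sd
    return SubjectTimeSeries(
        data=data, region_labels=ts.region_labels, subject_id=ts.subject_id, group=ts.group
    )


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0


class ConnectivityResults:
    """Fitted connectivity estimate plus provenance and diagnostics."""

    def __init__(
        self,
        weights: np.ndarray,
        model_tag: str,
        params: dict,
        region_labels: tuple[str, ...],
        subject_id: str,
        solver_report: SolverReport | None = None,
        symmetrized: bool = False,
    ) -> None:
        weights = np.array(weights, dtype=float)
        np.fill_diagonal(weights, 0.0)
        self.weights = weights
        self.model_tag = model_tag
        self.params = dict(params)
        self.region_labels = tuple(region_labels)
        self.subject_id = subject_id
        self.solver_report = solver_report
        self.symmetrized = symmetrized
        if symmetrized and not np.allclose(weights, weights.T, atol=0, rtol=0):
            raise ValueError("symmetrized flag set on an asymmetric matrix")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    def symmetrize(self) -> "ConnectivityResults":
        """Replace A by (A + A.T)/2; the asymmetric part carries no signal."""
        sym = 0.5 * (self.weights + self.weights.T)
        np.fill_diagonal(sym, 0.0)
        return ConnectivityResults(
            weights=sym,
            model_tag=self.model_tag,
            params=self.params,
            region_labels=self.region_labels,
            subject_id=self.subject_id,
            solver_report=self.solver_report,
            symmetrized=True,
        )

    def binarize(self, method: str = "nonzero", p: float | None = None) -> BinaryNetwork:
        """Convert to a 0/1 network.

        ``nonzero``: edge wherever |weight| exceeds a small numeric
        tolerance (the natural reading for sparse estimates with exact
        zeros).  ``proportional``: keep the strongest fraction ``p`` of
        possible edges by |weight|, ties broken by ascending (row, col)
        index (the usual convention for dense correlation networks).
        """
        if not self.symmetrized and not np.allclose(self.weights, self.weights.T):
            raise ValueError("binarize requires a symmetric matrix; call symmetrize() first")
        w = self.weights
        m = self.m
        adj = np.zeros((m, m), dtype=np.int8)
        if method == "nonzero":
            mask = np.abs(w) > _ZERO_TOL
            adj[mask] = 1
            np.fill_diagonal(adj, 0)
        elif method == "proportional":
            if p is None or not (0 < p <= 1):
                raise ValueError("proportional binarization needs density p in (0, 1]")
            iu, ju = np.triu_indices(m, k=1)
            k = int(np.floor(p * m * (m - 1) / 2))
            order = np.lexsort((ju, iu, -np.abs(w[iu, ju])))
            keep = order[:k]
            adj[iu[keep], ju[keep]] = 1
            adj |= adj.T
        else:
            raise ValueError(f"unknown binarization method {method!r}")
        return BinaryNetwork(adjacency=adj)

    def summary(self) -> str:
        m = self.m
        off = ~np.eye(m, dtype=bool)
        nnz = int((np.abs(self.weights[off]) > _ZERO_TOL).sum())
        lines = [
            f"Connectivity results  [{self.model_tag}]",
            f"  subject:        {self.subject_id}",
            f"  regions:        {m}",
            f"  params:         {self.params}",
            f"  symmetrized:    {self.symmetrized}",
            f"  nonzero off-diag: {nnz} / {m * (m - 1)}"
            f" ({nnz / (m * (m - 1)):.3f})",
        ]
        if self.solver_report is not None:
            rep = self.solver_report
            lines += [
                f"  solver iters:   {rep.iterations} (converged={rep.converged})",
                f"  objective:      {rep.final_objective:.6g}",
                f"  residuals:      primal={rep.primal_residual:.3g}, "
                f"dual={rep.dual_residual:.3g}",
            ]
        return "\n".join(lines)


class _FBNModel:
    """Shared scaffolding: hold the (z-scored) subject, fit on demand."""

    model_tag = "base"

    def __init__(self, ts: SubjectTimeSeries, standardize: bool = True) -> None:
        self.ts = zscore_columns(ts) if standardize else ts

    @classmethod
    def from_dataframe(cls, df, subject_id: str = "S000", group: int = 0, **kwargs):
        """Build from a t x m DataFrame whose columns are region labels."""
        ts = SubjectTimeSeries(
            data=df.to_numpy(dtype=float),
            region_labels=tuple(map(str, df.columns)),
            subject_id=subject_id,
            group=group,
        )
        return cls(ts, **kwargs)

    def fit(self) -> ConnectivityResults:  # pragma: no cover - abstract
        raise NotImplementedError


class PearsonFBN(_FBNModel):
    """Pairwise Pearson-correlation connectivity."""

    model_tag = "pearson"

    def fit(self) -> ConnectivityResults:
        if self.ts.n_timepoints < 3:
            raise ValueError("Pearson correlation needs t >= 3")
        corr = np.corrcoef(self.ts.data, rowvar=False)
        corr = 0.5 * (corr + corr.T)  # exact symmetry despite fp rounding order
        np.fill_diagonal(corr, 0.0)
        return ConnectivityResults(
            weights=corr,
            model_tag=self.model_tag,
            params={},
            region_labels=self.ts.region_labels,
            subject_id=self.ts.subject_id,
            symmetrized=True,
        )


class SparseLowRankFBN(_FBNModel):
    """Sparse low-rank regression connectivity.

    Each region's series is represented as a linear combination of all the
    other regions' series; the coefficient matrix is penalised by lam1 * l1
    (few direct interactions per region) and lam2 * trace norm (low rank,
    i.e. modular community structure), with a hard zero diagonal to forbid
    self-connections.
    """

    model_tag = "sparse_lowrank"

    def __init__(
        self,
        ts: SubjectTimeSeries,
        lam1: float = 1.0,
        lam2: float = 1.0,
        standardize: bool = True,
        rho: float = 1.0,
        max_iter: int = 2000,
        eps_abs: float = 1e-6,
        eps_rel: float = 1e-6,
    ) -> None:
        super().__init__(ts, standardize=standardize)
        if lam1 < 0 or lam2 < 0:
            raise ValueError("penalties must be >= 0")
        self.lam1 = float(lam1)
        self.lam2 = float(lam2)
        self.rho = rho
        self.max_iter = max_iter
        self.eps_abs = eps_abs
        self.eps_rel = eps_rel

    def _params(self) -> dict:
        return {"lam1": self.lam1, "lam2": self.lam2}

    def fit(self) -> ConnectivityResults:
        import warnings

        A, report = admm_sparse_lowrank(
            self.ts.data,
            self.lam1,
            self.lam2,
            rho=self.rho,
            max_iter=self.max_iter,
            eps_abs=self.eps_abs,
            eps_rel=self.eps_rel,
        )
        if not report.converged:
            warnings.warn(
                f"solver hit the iteration cap ({self.max_iter}) for subject "
                f"{self.ts.subject_id}; returning the best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
        return ConnectivityResults(
            weights=A,
            model_tag=self.model_tag,
            params=self._params(),
            region_labels=self.ts.region_labels,
            subject_id=self.ts.subject_id,
            solver_report=report,
        )


class SparseFBN(SparseLowRankFBN):
    """Sparse-representation connectivity: the lam2 = 0 special case."""

    model_tag = "sparse"

    def __init__(self, ts: SubjectTimeSeries, lam: float = 1.0, **kwargs) -> None:
        super().__init__(ts, lam1=lam, lam2=0.0, **kwargs)

    def _params(self) -> dict:
        return {"lam": self.lam1}


# -- functional wrappers ----------------------------------------------------


def pearson_fbn(ts: SubjectTimeSeries) -> ConnectivityResults:
    return PearsonFBN(ts).fit()


def sparse_fbn(ts: SubjectTimeSeries, lam: float, **kwargs) -> tuple[ConnectivityResults, SolverReport]:
    res = SparseFBN(ts, lam=lam, **kwargs).fit()
    return res, res.solver_report


def sparse_lowrank_fbn(
    ts: SubjectTimeSeries, lam1: float, lam2: float, **kwargs
) -> tuple[ConnectivityResults, SolverReport]:
    res = SparseLowRankFBN(ts, lam1=lam1, lam2=lam2, **kwargs).fit()
    return res, res.solver_report


def symmetrize(res: ConnectivityResults) -> ConnectivityResults:
    return res.symmetrize()


def binarize(res: ConnectivityResults, method: str = "nonzero", p: float | None = None) -> BinaryNetwork:
    return res.binarize(method=method, p=p)
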