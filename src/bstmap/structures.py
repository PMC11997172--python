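"""Precision structures for Gaussian Markov random fields on areas and years.

Every random-effect family used by the space-time model is specified through
an unscaled, symmetric positive-semidefinite structure matrix Q: exchangeable
(identity), intrinsic CAR on the contiguity graph (degree − adjacency),
random-walk penalties of order 1 or 2 on the time axis, and the four
space-time interaction structures obtained as Kronecker products of the
spatial and temporal factors over the area-major interaction vector:

    type I   = I_S ⊗ I_T        (unstructured × unstructured)
    type II  = I_S ⊗ Q_time     (unstructured space × structured time)
    type III = Q_space ⊗ I_T    (structured space × unstructured time)
    type IV  = Q_space ⊗ Q_time (structured × structured)

Intrinsic structures are rank-deficient; each structure carries its rank
deficiency and an orthonormal basis of its null space, which doubles as the
sum-to-zero (and, for RW2, detrending) constraint basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp

__all__ = [
    "AreaGraph",
    "PrecisionStructure",
    "iid_precision",
    "icar_precision",
    "rw_precision",
    "interaction_precision",
    "scale_structure",
    "sample_structured_effect",
]

#: eigenvalues below RANK_TOL × λ_max count as numerically zero
RANK_TOL = 1e-8


@dataclass
class AreaGraph:
    """Undirected contiguity graph over areas.

    Edges are stored as unordered id pairs; ``component_labels`` assigns each
    area a connected-component index, contiguous from 0 in order of the first
    member area.
    """

    area_ids: list[str]
    edges: set[frozenset[str]]
    component_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            for node in e:
                if node not in self.area_ids:
                    raise ValueError(f"edge references unknown area {node!r}")
        if self.component_labels is None:
            self.component_labels = self._label_components()
        self.component_labels = np.asarray(self.component_labels, dtype=int)

    def _label_components(self) -> np.ndarray:
        g = self.to_networkx()
        labels = np.full(len(self.area_ids), -1, dtype=int)
        index = {a: i for i, a in enumerate(self.area_ids)}
        next_label = 0
        for a in self.area_ids:
            if labels[index[a]] == -1:
                for member in nx.node_connected_component(g, a):
                    labels[index[member]] = next_label
                next_label += 1
        return labels

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if len(self.area_ids) else 0

    def adjacency_matrix(self) -> sp.csr_matrix:
        index = {a: i for i, a in enumerate(self.area_ids)}
        rows, cols = [], []
        for e in self.edges:
            a, b = tuple(e)
            rows += [index[a], index[b]]
            cols += [index[b], index[a]]
        data = np.ones(len(rows))
        n = len(self.area_ids)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency_matrix().sum(axis=1)).ravel()

    def subgraph(self, area_ids: list[str]) -> "AreaGraph":
        keep = set(area_ids)
        edges = {e for e in self.edges if e <= keep}
        return AreaGraph(area_ids=list(area_ids), edges=edges)


@dataclass
class PrecisionStructure:
    """An unscaled GMRF structure matrix with its null-space bookkeeping.

    The matrix is precision-parameter-free: the modelled precision of the
    effect is Q / τ². ``constraint_basis`` has one orthonormal column per
    null-space dimension; structured effects are kept orthogonal to it.
    """

    matrix: sp.csr_matrix
    size: int
    rank_deficiency: int
    constraint_basis: np.ndarray  # (size, rank_deficiency)
    label: str

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (self.size, self.size):
            raise ValueError("matrix shape does not match size")
        if self.constraint_basis.shape != (self.size, self.rank_deficiency):
            raise ValueError("constraint basis shape mismatch")

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) of the dense structure, ascending."""
        return np.linalg.eigh(self.dense())

    def numerical_rank(self) -> int:
        evals = np.linalg.eigvalsh(self.dense())
        scale = max(float(evals.max()), 1.0)
        return int(np.sum(evals > RANK_TOL * scale))

    def to_mtx(self, path) -> None:
        """Export as a MatrixMarket sparse file for debugging."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.matrix.tocoo())


def _orthonormal(columns: np.ndarray) -> np.ndarray:
    """Orthonormalize the columns (QR); empty input passes through."""
    if columns.size == 0:
        return columns.reshape(columns.shape[0], 0)
    q, _ = np.linalg.qr(columns)
    return q


def iid_precision(n: int) -> PrecisionStructure:
    """Exchangeable (identity) structure: full rank, no constraints."""
    if n < 1:
        raise ValueError(f"dimension must be >= 1, got {n}")
    return PrecisionStructure(
        matrix=sp.identity(n, format="csr"),
        size=n,
        rank_deficiency=0,
        constraint_basis=np.empty((n, 0)),
        label="iid",
    )


def icar_precision(graph: AreaGraph) -> PrecisionStructure:
    """Intrinsic CAR (Besag) structure: Q = diag(degree) − adjacency.

    Rank deficiency equals the number of connected components; the constraint
    basis spans the per-component indicator vectors (one sum-to-zero
    constraint per component).
    """
    n = graph.n_areas
    if n == 0:
        raise ValueError("graph has no areas")
    adj = graph.adjacency_matrix()
    deg = sp.diags(np.asarray(adj.sum(axis=1)).ravel())
    q = sp.csr_matrix(deg - adj)
    labels = graph.component_labels
    n_comp = graph.n_components
    basis = np.zeros((n, n_comp))
    for c in range(n_comp):
        members = labels == c
        basis[members, c] = 1.0 / np.sqrt(members.sum())
    return PrecisionStructure(
        matrix=q, size=n, rank_deficiency=n_comp, constraint_basis=basis, label="icar"
    )


def rw_precision(T: int, order: int) -> PrecisionStructure:
    """Random-walk structure of order 1 or 2: Q = Dᵀ D for the difference operator D.

    RW1 penalizes first differences (deficiency 1, constant null vector); RW2
    penalizes second differences (deficiency 2, constant + linear null space).
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if T <= order:
        raise ValueError(f"need more than {order} time points, got {T}")
    d = np.diff(np.eye(T), n=order, axis=0)  # (T-order, T)
    q = sp.csr_matrix(d.T @ d)
    t = np.arange(T, dtype=float)
    null_cols = [np.ones(T)]
    if order == 2:
        null_cols.append(t - t.mean())
    basis = _orthonormal(np.column_stack(null_cols))
    return PrecisionStructure(
        matrix=q, size=T, rank_deficiency=order, constraint_basis=basis, label=f"rw{order}"
    )


_SPATIAL_LABELS = {"iid", "icar"}
_TEMPORAL_LABELS = {"iid", "rw1", "rw2"}


def interaction_precision(
    spatial: PrecisionStructure, temporal: PrecisionStructure, type: str
) -> PrecisionStructure:
    """Knorr-Held interaction structure over the area-major S·T vector.

    ``type`` selects which factors contribute structure: "I" uses identity in
    both directions, "II" structures time within each area, "III" structures
    space within each year, "IV" structures both. Rank deficiencies follow the
    Kronecker rank rule: rank(A ⊗ B) = rank(A)·rank(B).
    """
    if spatial.label not in _SPATIAL_LABELS:
        raise ValueError(
            f"spatial factor must be one of {_SPATIAL_LABELS}, got {spatial.label!r}"
        )
    if temporal.label not in _TEMPORAL_LABELS:
        raise ValueError(
            f"temporal factor must be one of {_TEMPORAL_LABELS}, got {temporal.label!r}"
        )
    s, t = spatial.size, temporal.size
    d_s, d_t = spatial.rank_deficiency, temporal.rank_deficiency
    eye_s, eye_t = sp.identity(s), sp.identity(t)
    if type == "I":
        q = sp.kron(eye_s, eye_t, format="csr")
        deficiency = 0
        basis = np.empty((s * t, 0))
    elif type == "II":
        q = sp.kron(eye_s, temporal.matrix, format="csr")
        deficiency = s * d_t
        # null space: every area's copy of the temporal null vectors
        basis = np.kron(np.eye(s), temporal.constraint_basis)
    elif type == "III":
        q = sp.kron(spatial.matrix, eye_t, format="csr")
        deficiency = d_s * t
        basis = np.kron(spatial.constraint_basis, np.eye(t))
    elif type == "IV":
        q = sp.kron(spatial.matrix, temporal.matrix, format="csr")
        deficiency = s * t - (s - d_s) * (t - d_t)
        # null(A⊗B) = span{ a⊗y, x⊗b : a ∈ null(A) or b ∈ null(B) }
        cols = []
        evals_s, evecs_s = spatial.eigendecomposition()
        evals_t, evecs_t = temporal.eigendecomposition()
        tol_s = RANK_TOL * max(float(evals_s.max()), 1.0)
        tol_t = RANK_TOL * max(float(evals_t.max()), 1.0)
        for k in range(s):
            for l in range(t):
                if evals_s[k] <= tol_s or evals_t[l] <= tol_t:
                    cols.append(np.kron(evecs_s[:, k], evecs_t[:, l]))
        basis = np.column_stack(cols) if cols else np.empty((s * t, 0))
    else:
        raise ValueError(f"interaction type must be I..IV, got {type!r}")
    basis = _orthonormal(basis)
    if basis.shape[1] != deficiency:
        raise AssertionError(
            f"constraint basis dimension {basis.shape[1]} != deficiency {deficiency}"
        )
    return PrecisionStructure(
        matrix=q,
        size=s * t,
        rank_deficiency=deficiency,
        constraint_basis=basis,
        label=f"interaction:{type}",
    )


def scale_structure(structure: PrecisionStructure) -> PrecisionStructure:
    """Rescale an intrinsic structure so its variance parameter is marginal.

    The raw structure's conditional variance parameter means different things
    on different graphs and series lengths (an unscaled RW2 over 20 points
    has a smallest positive eigenvalue of order 1e-5, so draws dwarf their
    nominal variance). Multiplying Q by the generalized variance — the
    geometric mean of the marginal variances under Q's pseudo-inverse —
    standardizes the typical marginal variance of a unit-variance draw to 1,
    making variance parameters comparable across structures. Exchangeable
    (diagonal identity) structures are unchanged.
    """
    evals, evecs = structure.eigendecomposition()
    tol = RANK_TOL * max(float(evals.max()), 1.0)
    pos = evals > tol
    marginal = (evecs[:, pos] ** 2 / evals[pos][None, :]).sum(axis=1)
    kappa = float(np.exp(np.mean(np.log(marginal))))
    return PrecisionStructure(
        matrix=sp.csr_matrix(structure.matrix * kappa),
        size=structure.size,
        rank_deficiency=structure.rank_deficiency,
        constraint_basis=structure.constraint_basis,
        label=structure.label,
    )


def sample_structured_effect(
    structure: PrecisionStructure, variance: float, rng_seed
) -> np.ndarray:
    """Draw one effect vector from the intrinsic Gaussian with the given structure.

    The draw lives in the proper subspace: along each eigenvector with
    eigenvalue λ above the rank tolerance the coordinate is N(0, variance/λ);
    null-space coordinates are zero, so the draw is exactly orthogonal to the
    constraint basis.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    offdiag = structure.matrix - sp.diags(structure.matrix.diagonal())
    if offdiag.count_nonzero() == 0:  # diagonal structure: sample directly
        lam = structure.matrix.diagonal()
        tol = RANK_TOL * max(float(lam.max()), 1.0)
        draw = np.zeros(structure.size)
        keep = lam > tol
        draw[keep] = rng.standard_normal(int(keep.sum())) * np.sqrt(variance / lam[keep])
        return draw
    evals, evecs = structure.eigendecomposition()
    tol = RANK_TOL * max(float(evals.max()), 1.0)
    keep = evals > tol
    coords = np.zeros(structure.size)
    coords[keep] = rng.standard_normal(int(keep.sum())) * np.sqrt(variance / evals[keep])
    return evecs @ coords
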