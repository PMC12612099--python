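"""Conditional random field over thalamic voxels: the HQ-augmentation core.

The label field ``y`` follows a Gibbs distribution

    P(y | X) = exp(-E(y | X)) / Z(X),
    E(y | X) = sum_i psi_u(y_i | x_i) + sum_{(i,j) in edges} psi_p(y_i, y_j),

with a linear unary cost on the expanded features, ``psi_u(k | x_i)
= w_k . phi(x_i)``, and a kernel-weighted Potts pairwise cost
``psi_p = rho * mu(y_i, y_j) * k(phi_i, phi_j)`` where
``k(a, b) = exp(-gamma * ||a - b||^2)`` and ``mu`` is 0 for equal labels
and 1 otherwise.  The edge set pairs each mask voxel with its 6/18/26
neighbours; each unordered pair contributes once to the energy, so the
mean-field update below is the exact variational fixed point for this
Gibbs measure.

Marginals are approximated by mean-field iteration

    Q_i(k) ∝ exp(-psi_u(k | x_i)
                 - sum_{j in N(i)} sum_l Q_j(l) * rho * mu(k, l) * k_ij),

initialised from the unary-only softmax.  Training minimises the
regularised cross-entropy (negative log-likelihood) of the one-hot
reference labels under the mean-field marginals,

    L = sum_subjects sum_i sum_k -t_ik log Q_i(k)
        + lambda1 ||W||_1 + lambda2 ||W||_2^2,

by gradient descent in which each subject's (standardised) feature matrix
is one mini-batch.  Gradients are obtained by reverse-mode differentiation
through a fixed number of unrolled mean-field sweeps; ``rho`` is trained
in log-space to stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.special import logsumexp, softmax

from .core import CRFParams, K_CLASSES, ProbabilityField, VoxelGrid

LOG_FLOOR = 1e-12  # clamp inside the cross-entropy to keep the loss finite

__all__ = [
    "NeighborGraph",
    "TrainingConfig",
    "CRFSubject",
    "build_neighbor_graph",
    "unary_cost",
    "pairwise_kernel",
    "kernel_matrix",
    "median_heuristic_gamma",
    "energy",
    "exact_posterior",
    "mean_field_infer",
    "loss",
    "loss_and_gradients",
    "fit",
    "predict",
    "select_gamma",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric voxel adjacency restricted to the thalamic mask.

    ``edges`` lists each unordered neighbouring pair once (i < j, flat mask
    indices).  ``neighbor_lists`` gives, per voxel, all its neighbours.
    """

    grid: VoxelGrid
    edges: np.ndarray
    connectivity: int

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def neighbor_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.grid.n_voxels)]
        for i, j in self.edges:
            adj[i].append(int(j))
            adj[j].append(int(i))
        return adj


_OFFSETS = {
    6: [o for o in _iterproduct((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
    18: [o for o in _iterproduct((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2],
    26: [o for o in _iterproduct((-1, 0, 1), repeat=3) if any(o)],
}


def build_neighbor_graph(grid: VoxelGrid, connectivity: int = 26) -> NeighborGraph:
    """Adjacency between mask voxels under a 6/18/26 neighbourhood."""
    if connectivity not in _OFFSETS:
        raise ValueError("connectivity must be 6, 18 or 26")
    index_of = {tuple(v): i for i, v in enumerate(grid.mask_indices)}
    edges = []
    for i, v in enumerate(grid.mask_indices):
        for off in _OFFSETS[connectivity]:
            j = index_of.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None and j > i:
                edges.append((i, j))
    edges_arr = (
        np.asarray(edges, dtype=np.intp) if edges else np.empty((0, 2), dtype=np.intp)
    )
    return NeighborGraph(grid, edges_arr, connectivity)


def unary_cost(params: CRFParams, Phi: np.ndarray) -> np.ndarray:
    """Unary cost table ``U[i, k] = w_k . phi(x_i)`` of shape (V, K)."""
    Phi = np.asarray(Phi, dtype=float)
    if Phi.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"feature dimension {Phi.shape[1]} != W rows {params.W.shape[0]}"
        )
    return Phi @ params.W


def pairwise_kernel(phi_i: np.ndarray, phi_j: np.ndarray, gamma: float) -> float:
    """Gaussian similarity ``exp(-gamma * ||phi_i - phi_j||^2)`` in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = float(np.sum((np.asarray(phi_i, float) - np.asarray(phi_j, float)) ** 2))
    return float(np.exp(-gamma * d2))


def kernel_matrix(
    Phi: np.ndarray, graph: NeighborGraph, gamma: float
) -> sparse.csr_matrix:
    """Sparse symmetric matrix of edge kernel values (zero elsewhere).

    Precomputed once per subject: inference never mutates features, so the
    kernel is a pure function of ``Phi`` and ``gamma``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    V = Phi.shape[0]
    if graph.n_edges == 0:
        return sparse.csr_matrix((V, V))
    i, j = graph.edges.T
    d2 = np.sum((Phi[i] - Phi[j]) ** 2, axis=1)
    k = np.exp(-gamma * d2)
    K = sparse.coo_matrix(
        (np.r_[k, k], (np.r_[i, j], np.r_[j, i])), shape=(V, V)
    )
    return K.tocsr()


def median_heuristic_gamma(Phi: np.ndarray, graph: NeighborGraph) -> float:
    """Kernel length scale giving a median edge similarity of 0.5.

    ``gamma = ln 2 / median(||phi_i - phi_j||^2)`` over graph edges — a
    deterministic default when no cross-validated value is supplied.
    """
    if graph.n_edges == 0:
        return 1.0
    i, j = graph.edges.T
    d2 = np.sum((Phi[i] - Phi[j]) ** 2, axis=1)
    med = float(np.median(d2))
    if med <= 0:
        return 1.0
    return float(np.log(2.0) / med)


def energy(
    params: CRFParams,
    Phi: np.ndarray,
    labels: np.ndarray,
    graph: NeighborGraph,
    K: sparse.spmatrix | None = None,
) -> float:
    """Cost ``E(y | X)`` of a full label assignment."""
    labels = np.asarray(labels)
    U = unary_cost(params, Phi)
    e = float(U[np.arange(len(labels)), labels].sum())
    if graph.n_edges and params.rho > 0:
        i, j = graph.edges.T
        if K is not None:
            k = np.asarray(K[i, j]).ravel()
        else:
            d2 = np.sum((Phi[i] - Phi[j]) ** 2, axis=1)
            k = np.exp(-params.gamma * d2)
        e += float(params.rho * (k * (labels[i] != labels[j])).sum())
    return e


def exact_posterior(
    params: CRFParams,
    Phi: np.ndarray,
    graph: NeighborGraph,
    max_voxels: int = 15,
) -> np.ndarray:
    """Exact marginals by enumerating all 2^V labelings (test oracle).

    Tractable only for tiny instances; refuses ``V`` beyond ``max_voxels``.
    Returns the (V, 2) marginal table.
    """
    V = Phi.shape[0]
    if V > max_voxels:
        raise ValueError(f"enumeration refused for V={V} > {max_voxels}")
    U = unary_cost(params, Phi)
    if graph.n_edges:
        i, j = graph.edges.T
        d2 = np.sum((Phi[i] - Phi[j]) ** 2, axis=1)
        kvals = np.exp(-params.gamma * d2)
    # all assignments as a (2^V, V) bit table
    codes = np.arange(2**V)
    Y = (codes[:, None] >> np.arange(V)) & 1
    E = U[np.arange(V), Y].sum(axis=1).astype(float)
    if graph.n_edges and params.rho > 0:
        E += params.rho * ((Y[:, i] != Y[:, j]) * kvals).sum(axis=1)
    logp = -E - logsumexp(-E)
    p = np.exp(logp)
    Q = np.empty((V, K_CLASSES))
    Q[:, 1] = p @ Y
    Q[:, 0] = 1.0 - Q[:, 1]
    return Q


def _softmax_rows(neg_cost: np.ndarray) -> np.ndarray:
    return softmax(neg_cost, axis=1)


def _mean_field_sweeps(
    U: np.ndarray,
    K: sparse.spmatrix,
    rho: float,
    n_iters: int,
    tol: float = 0.0,
) -> list[np.ndarray]:
    """Run mean-field and return all iterates (needed for backprop).

    ``Q^0 = softmax(-U)``; each sweep recomputes every voxel's update from
    the previous sweep's marginals (parallel/Jacobi update), which is the
    scheme the unrolled gradient differentiates.
    """
    Q = _softmax_rows(-U)
    iterates = [Q]
    for _ in range(n_iters):
        pair = rho * (K @ Q[:, ::-1]) if rho != 0 else 0.0
        Qn = _softmax_rows(-(U + pair))
        iterates.append(Qn)
        if tol > 0 and np.abs(Qn - Q).max() < tol:
            break
        Q = Qn
    return iterates


def mean_field_infer(
    params: CRFParams,
    Phi: np.ndarray,
    graph: NeighborGraph,
    n_iters: int = 10,
    tol: float = 1e-6,
    K: sparse.spmatrix | None = None,
) -> np.ndarray:
    """Approximate CRF marginals by mean-field iteration; returns (V, 2).

    With ``rho = 0`` the voxels decouple and the first iterate is already
    the exact closed-form softmax posterior.
    """
    if not (np.isfinite(Phi).all() and np.isfinite(params.W).all()):
        raise ValueError("non-finite inputs to mean-field inference")
    U = unary_cost(params, Phi)
    if params.rho == 0:
        return _softmax_rows(-U)
    if K is None:
        K = kernel_matrix(Phi, graph, params.gamma)
    return _mean_field_sweeps(U, K, params.rho, n_iters, tol)[-1]


@dataclass
class CRFSubject:
    """Prepared training/inference inputs for one subject.

    ``Phi`` is the standardised expanded design matrix; ``T`` the one-hot
    labels (may be None at prediction time); ``K`` the cached edge-kernel
    matrix for the subject's graph.
    """

    Phi: np.ndarray
    graph: NeighborGraph
    T: np.ndarray | None = None
    K: sparse.spmatrix | None = None
    subject_id: str = ""

    def kernel(self, gamma: float) -> sparse.spmatrix:
        if self.K is None:
            self.K = kernel_matrix(self.Phi, self.graph, gamma)
        return self.K


@dataclass
class TrainingConfig:
    """Optimisation settings for :func:`fit`.

    Defaults were set by convergence checks on the synthetic cohorts; none
    of them is dictated by the model itself.  ``gamma=None`` selects the
    median-heuristic length scale from the training edges (use
    :func:`select_gamma` for a cross-validated choice).
    """

    n_mf_iters: int = 10
    n_epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 0.05
    lr_decay: float = 0.97
    momentum: float = 0.9
    lambda1: float = 1e-4
    lambda2: float = 1e-3
    gamma: float | None = None
    rho_init: float = 0.1
    rho_max: float = 1.0
    train_rho: bool = True
    seed: int = 0
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_mf_iters < 1:
            raise ValueError("n_mf_iters must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.rho_init < 0:
            raise ValueError("rho_init must be nonnegative")


def _subject_forward(
    subject: CRFSubject, W: np.ndarray, rho: float, gamma: float, n_iters: int
) -> tuple[float, list[np.ndarray], np.ndarray]:
    U = subject.Phi @ W
    if rho == 0:
        iterates = [_softmax_rows(-U)]
    else:
        iterates = _mean_field_sweeps(U, subject.kernel(gamma), rho, n_iters)
    Q = iterates[-1]
    ce = float(-(subject.T * np.log(np.maximum(Q, LOG_FLOOR))).sum())
    return ce, iterates, U


def _subject_backward(
    subject: CRFSubject,
    iterates: list[np.ndarray],
    rho: float,
    gamma: float,
) -> tuple[np.ndarray, float]:
    """Reverse-mode gradient of the subject cross-entropy.

    Returns ``(dL/dU, dL/drho)``; ``dL/dW = Phi.T @ dL/dU`` is assembled by
    the caller.  Differentiates through every stored mean-field iterate.
    """
    Qf = iterates[-1]
    Qc = np.maximum(Qf, LOG_FLOOR)
    g = np.where(Qf >= LOG_FLOOR, -subject.T / Qc, 0.0)

    dU = np.zeros_like(Qf)
    drho = 0.0
    Ksp = subject.kernel(gamma) if len(iterates) > 1 else None
    for t in range(len(iterates) - 1, 0, -1):
        Q = iterates[t]
        dM = -(Q * (g - (g * Q).sum(axis=1, keepdims=True)))
        dU += dM
        P = Ksp @ iterates[t - 1][:, ::-1]
        drho += float((dM * P).sum())
        g = rho * ((Ksp @ dM)[:, ::-1])  # kernel matrix is symmetric
    Q0 = iterates[0]
    dM0 = -(Q0 * (g - (g * Q0).sum(axis=1, keepdims=True)))
    dU += dM0
    return dU, drho


def loss(
    params: CRFParams,
    cohort: Sequence[CRFSubject],
    n_mf_iters: int = 10,
) -> float:
    """Regularised cross-entropy of the cohort under mean-field marginals."""
    total = 0.0
    for s in cohort:
        if s.T is None:
            raise ValueError("loss requires labelled subjects")
        ce, _, _ = _subject_forward(s, params.W, params.rho, params.gamma, n_mf_iters)
        total += ce
    total += params.lambda1 * np.abs(params.W).sum()
    total += params.lambda2 * float((params.W**2).sum())
    return total


def loss_and_gradients(
    params: CRFParams,
    cohort: Sequence[CRFSubject],
    n_mf_iters: int = 10,
) -> tuple[float, np.ndarray, float]:
    """Full-cohort loss with gradients w.r.t. ``W`` and ``rho``.

    The L1 term uses the sign subgradient (``sign(0) = 0``).  Used by the
    finite-difference gradient checks and available for batch optimisers.
    """
    total = 0.0
    dW = np.zeros_like(params.W)
    drho = 0.0
    for s in cohort:
        ce, iterates, _ = _subject_forward(
            s, params.W, params.rho, params.gamma, n_mf_iters
        )
        total += ce
        dU, drho_s = _subject_backward(s, iterates, params.rho, params.gamma)
        dW += s.Phi.T @ dU
        drho += drho_s
    total += params.lambda1 * np.abs(params.W).sum()
    total += params.lambda2 * float((params.W**2).sum())
    dW += params.lambda1 * np.sign(params.W) + 2.0 * params.lambda2 * params.W
    return total, dW, drho


def fit(
    cohort: Sequence[CRFSubject],
    config: TrainingConfig,
    feature_names: Sequence[str] = (),
    powers: tuple[float, float, float] = (2.0, 0.5, 0.2),
    verbose: bool = False,
) -> tuple[CRFParams, list[float]]:
    """Train the CRF by per-subject mini-batch gradient descent.

    Each subject's standardised feature matrix is one mini-batch; subject
    order is reshuffled every epoch by a seeded generator, so two runs with
    the same seed are identical.  Gradients are scaled by the subject's
    voxel count so the learning rate is in per-voxel units; penalty
    gradients are split evenly across the subjects of an epoch.

    The default optimiser applies a diagonal (Adam-style) preconditioner to
    the mini-batch steps: the polynomial power blocks of the expanded
    design are strongly collinear, and unpreconditioned descent crawls
    along the resulting narrow valleys.  ``optimizer="sgd"`` gives plain
    constant-step descent with momentum.  ``rho`` is updated in log-space.
    Returns the fitted parameters and the per-epoch loss trace.
    """
    if not cohort:
        raise ValueError("need at least one training subject")
    for s in cohort:
        if s.T is None:
            raise ValueError("training subjects must carry one-hot labels")
    if config.optimizer not in ("adam", "sgd"):
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    dprime = cohort[0].Phi.shape[1]
    if config.gamma is None:
        gamma = float(
            np.median([median_heuristic_gamma(s.Phi, s.graph) for s in cohort])
        )
    else:
        gamma = config.gamma

    rng = np.random.default_rng(config.seed)
    W = np.zeros((dprime, K_CLASSES))
    theta = np.log(max(config.rho_init, 1e-12))
    vel_W = np.zeros_like(W)
    vel_theta = 0.0
    m_W = np.zeros_like(W)
    v_W = np.zeros_like(W)
    m_th = 0.0
    v_th = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(cohort)
    trace: list[float] = []

    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        lr = config.learning_rate * config.lr_decay**epoch
        epoch_loss = 0.0
        for si in order:
            s = cohort[si]
            rho = float(np.exp(theta)) if config.rho_init > 0 else 0.0
            ce, iterates, _ = _subject_forward(s, W, rho, gamma, config.n_mf_iters)
            if not np.isfinite(ce):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} "
                    f"(learning_rate={config.learning_rate})"
                )
            epoch_loss += ce
            if rho > 0:
                dU, drho = _subject_backward(s, iterates, rho, gamma)
            else:
                Q0 = iterates[0]
                dU = s.T - Q0  # softmax(-U) cross-entropy shortcut
                drho = 0.0
            dW = s.Phi.T @ dU
            dW += (config.lambda1 * np.sign(W) + 2.0 * config.lambda2 * W) / n
            V = s.Phi.shape[0]
            dW /= V
            dtheta = drho * rho / V
            step += 1
            if config.optimizer == "adam":
                m_W = beta1 * m_W + (1 - beta1) * dW
                v_W = beta2 * v_W + (1 - beta2) * dW**2
                mhat = m_W / (1 - beta1**step)
                vhat = v_W / (1 - beta2**step)
                W = W - lr * mhat / (np.sqrt(vhat) + eps)
            else:
                vel_W = config.momentum * vel_W - lr * dW
                W = W + vel_W
            if config.train_rho and rho > 0:
                if config.optimizer == "adam":
                    m_th = beta1 * m_th + (1 - beta1) * dtheta
                    v_th = beta2 * v_th + (1 - beta2) * dtheta**2
                    d_step = -lr * (m_th / (1 - beta1**step)) / (
                        np.sqrt(v_th / (1 - beta2**step)) + eps
                    )
                else:
                    vel_theta = config.momentum * vel_theta - lr * dtheta
                    d_step = vel_theta
                # clip the log-space step and bound rho itself: beyond the
                # weak-coupling regime mean-field floods whole components,
                # the marginals saturate and every gradient dies
                theta = float(np.clip(theta + np.clip(d_step, -0.1, 0.1),
                                      np.log(1e-6), np.log(config.rho_max)))
        epoch_loss += config.lambda1 * np.abs(W).sum() + config.lambda2 * (W**2).sum()
        trace.append(float(epoch_loss))
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}")

    rho_final = float(np.exp(theta)) if config.rho_init > 0 else 0.0
    params = CRFParams(
        W=W,
        rho=rho_final,
        gamma=gamma,
        powers=powers,
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        feature_names=list(feature_names),
    )
    return params, trace


def predict(
    params: CRFParams,
    Phi: np.ndarray,
    graph: NeighborGraph,
    n_mf_iters: int = 10,
    K: sparse.spmatrix | None = None,
) -> ProbabilityField:
    """Posterior Vim probability map for one subject (deterministic)."""
    Q = mean_field_infer(params, Phi, graph, n_iters=n_mf_iters, K=K)
    return ProbabilityField(graph.grid, Q)


def select_gamma(
    cohort: Sequence[CRFSubject],
    config: TrainingConfig,
    grid: Sequence[float] = (0.001, 0.01, 0.1, 1.0),
    n_folds: int = 3,
) -> float:
    """Choose the kernel length scale by cross-validated held-out loss.

    Splits the cohort into ``n_folds`` subject folds, trains on the rest at
    each candidate ``gamma`` from a log grid, and returns the candidate with
    the lowest mean held-out cross-entropy.
    """
    if len(cohort) < n_folds:
        raise ValueError("need at least one subject per fold")
    folds = np.array_split(np.arange(len(cohort)), n_folds)
    best_gamma, best_score = None, np.inf
    from dataclasses import replace as _replace

    for g in grid:
        scores = []
        for f in folds:
            train = [s for i, s in enumerate(cohort) if i not in set(f.tolist())]
            val = [cohort[i] for i in f]
            cfg = _replace(config, gamma=float(g))
            # fresh kernel caches: gamma changes invalidate them
            train = [CRFSubject(s.Phi, s.graph, s.T, subject_id=s.subject_id) for s in train]
            val = [CRFSubject(s.Phi, s.graph, s.T, subject_id=s.subject_id) for s in val]
            params, _ = fit(train, cfg)
            scores.append(loss(params, val, n_mf_iters=cfg.n_mf_iters))
        score = float(np.mean(scores))
        if score < best_score:
            best_gamma, best_score = float(g), score
    return best_gamma
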