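"""Fisher-criterion feature fusion and K-SVD subdictionary learning.

Each training patch is a p x K feature stack X_i (p = 121 pixels, K = 8
feature channels). The fusion matrix W (K x M, M = 3 by default) projects
the K channels down to M fused channels, y_i = X_i W, chosen to maximize the
Fisher criterion: the generalized eigenvectors of

    S_b phi = lambda * S_w phi,

where the between-class scatter S_b = sum_c N_c (Xbar_c - Xbar)^T (Xbar_c - Xbar)
and within-class scatter S_w = sum_c sum_{X_i in c} (X_i - Xbar_c)^T (X_i - Xbar_c)
are K x K matrices accumulated over the feature axis.

For every class c (1 = MA, 2 = non-MA) and fused channel m, a p x d
subdictionary Q_m^c with unit-norm atoms is learned by K-SVD: alternate OMP
sparse coding (sparsity T) with sequential rank-1 SVD atom updates. A query
is later labeled by the class whose subdictionaries reconstruct its fused
channels with the smallest accumulated error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .config import PipelineConfig
from .errors import ShapeError
from .sparse import omp_batch

logger = logging.getLogger(__name__)

MA_CLASS = 1
NON_MA_CLASS = 2


@dataclass
class LabeledTrainingSet:
    """Feature stacks (N, p, K) with class labels (1 = MA, 2 = non-MA)."""

    stacks: np.ndarray
    labels: np.ndarray
    coords: np.ndarray | None = None      # (N, 2) source (row, col), if known
    image_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.stacks = np.asarray(self.stacks, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.stacks.ndim != 3:
            raise ShapeError("stacks must be (N, p, K)")
        if len(self.labels) != len(self.stacks):
            raise ShapeError("labels/stacks length mismatch")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_stacks(self, c: int) -> np.ndarray:
        return self.stacks[self.labels == c]


@dataclass
class FusionMatrix:
    """K x M Fisher projection, columns ordered by decreasing eigenvalue."""

    W: np.ndarray
    eigenvalues: np.ndarray


def scatter_matrices(train: LabeledTrainingSet) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-class K x K scatter of the feature stacks."""
    classes = train.classes
    if len(classes) < 2:
        raise ShapeError("scatter matrices require at least two classes")
    xbar = train.stacks.mean(axis=0)                       # p x K
    K = train.stacks.shape[2]
    sb = np.zeros((K, K))
    sw = np.zeros((K, K))
    for c in classes:
        xc = train.class_stacks(c)
        xbar_c = xc.mean(axis=0)
        d = xbar_c - xbar
        sb += len(xc) * (d.T @ d)
        centered = xc - xbar_c                              # N_c x p x K
        sw += np.einsum("npk,npl->kl", centered, centered)
    return sb, sw


def fisher_fusion(sb: np.ndarray, sw: np.ndarray, M: int) -> FusionMatrix:
    """Top-M generalized eigenvectors of (S_b, S_w + eps*I).

    A small ridge on S_w guarantees invertibility. Columns are normalized so
    phi^T (S_w + eps I) phi = 1, and signed so the largest-magnitude entry is
    positive.
    """
    K = sb.shape[0]
    if M > K:
        raise ShapeError(f"fused dimension M={M} exceeds feature count K={K}")
    eps = 1e-6 * np.trace(sw) / K if np.trace(sw) > 0 else 1e-6
    sw_r = sw + eps * np.eye(K)
    eigvals, eigvecs = linalg.eigh(sb, sw_r)
    order = np.argsort(eigvals)[::-1][:M]
    W = eigvecs[:, order]
    vals = eigvals[order]
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return FusionMatrix(W=W, eigenvalues=vals)


def fuse(X: np.ndarray, W: np.ndarray | FusionMatrix) -> np.ndarray:
    """Fused representation y = X W (p x M)."""
    if isinstance(W, FusionMatrix):
        W = W.W
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != W.shape[0]:
        raise ShapeError(f"cannot fuse: X has K={X.shape[-1]}, W expects {W.shape[0]}")
    return X @ W


def ksvd_learn(vectors: np.ndarray, d: int, sparsity: int, iterations: int,
               rng: np.random.Generator | None = None,
               return_trace: bool = False):
    """Learn a p x d unit-norm-atom dictionary by K-SVD.

    ``vectors`` is (n, p), one training vector per row. Alternates batch OMP
    coding with sequential SVD atom updates. An atom used by no signal is
    replaced by the worst-represented training vector. A signal keeps its
    previous code whenever fresh OMP coding would increase its residual, so
    the total representation error is non-increasing across iterations.
    """
    rng = rng or np.random.default_rng()
    Y = np.asarray(vectors, dtype=np.float64).T          # p x n
    p, n = Y.shape
    if n < d:
        warnings.warn(f"only {n} training vectors for {d} atoms; reducing d to {n}")
        d = n
    sparsity = min(sparsity, d)
    # init from distinct training vectors (zero-norm columns get noise)
    sel = rng.choice(n, size=d, replace=False)
    Q = Y[:, sel].copy()
    norms = np.linalg.norm(Q, axis=0)
    dead = norms <= 1e-12
    if np.any(dead):
        Q[:, dead] = rng.standard_normal((p, int(dead.sum())))
        norms = np.linalg.norm(Q, axis=0)
    Q /= norms
    B = np.zeros((d, n))
    trace = []
    for _ in range(iterations):
        new_B = omp_batch(Q, Y, sparsity)
        old_res = np.sum((Y - Q @ B) ** 2, axis=0)
        new_res = np.sum((Y - Q @ new_B) ** 2, axis=0)
        keep_old = old_res < new_res
        new_B[:, keep_old] = B[:, keep_old]
        B = new_B
        # sequential atom updates
        R = Y - Q @ B
        for k in range(d):
            users = np.nonzero(B[k] != 0)[0]
            if users.size == 0:
                worst = int(np.argmax(np.sum(R ** 2, axis=0)))
                atom = Y[:, worst]
                nrm = np.linalg.norm(atom)
                if nrm > 1e-12:
                    Q[:, k] = atom / nrm
                continue
            Ek = R[:, users] + np.outer(Q[:, k], B[k, users])
            U, s, Vt = np.linalg.svd(Ek, full_matrices=False)
            atom = U[:, 0]
            i = np.argmax(np.abs(atom))
            sign = 1.0 if atom[i] >= 0 else -1.0
            Q[:, k] = sign * atom
            B[k, users] = sign * s[0] * Vt[0]
            R[:, users] = Ek - np.outer(Q[:, k], B[k, users])
        trace.append(float(np.sum((Y - Q @ B) ** 2)))
    if return_trace:
        return Q, np.asarray(trace)
    return Q


@dataclass
class FusionDictionaryModel:
    """Trained fusion matrix plus the M x C grid of subdictionaries.

    ``subdictionaries`` maps (m, c) — fused channel index (0-based) and class
    label (1 = MA, 2 = non-MA) — to a p x d unit-norm-atom dictionary.
    """

    fusion: FusionMatrix
    subdictionaries: dict[tuple[int, int], np.ndarray]
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def classes(self) -> list[int]:
        return sorted({c for (_, c) in self.subdictionaries})

    @property
    def fused_dim(self) -> int:
        return self.fusion.W.shape[1]

    def save(self, path) -> None:
        from .io import save_model

        save_model(self, path)

    @classmethod
    def load(cls, path) -> "FusionDictionaryModel":
        from .io import load_model

        return load_model(path)


def train_model(train: LabeledTrainingSet,
                config: PipelineConfig | None = None) -> FusionDictionaryModel:
    """Learn W by Fisher fusion, then one K-SVD subdictionary per
    (fused channel, class)."""
    config = config or PipelineConfig()
    classes = train.classes
    if len(classes) < 2:
        raise ShapeError("training requires both MA and non-MA samples")
    counts = {int(c): int(np.sum(train.labels == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ShapeError(f"too few samples per class: {counts}")
    sb, sw = scatter_matrices(train)
    fusion = fisher_fusion(sb, sw, config.fused_dim)
    rng = config.rng("ksvd")
    subs: dict[tuple[int, int], np.ndarray] = {}
    for c in classes:
        fused = fuse(train.class_stacks(c), fusion.W)      # N_c x p x M
        for m in range(config.fused_dim):
            logger.info("stage=train class=%d fused_channel=%d n=%d",
                        c, m, fused.shape[0])
            subs[(m, int(c))] = ksvd_learn(
                fused[:, :, m], config.atoms_per_subdictionary,
                config.omp_sparsity, config.ksvd_iterations, rng,
            )
    return FusionDictionaryModel(fusion=fusion, subdictionaries=subs,
                                 config=config)
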