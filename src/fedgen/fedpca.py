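"""Exact federated PCA by eigenvector stacking, plus projection and
communication accounting.

Each client eigendecomposes its *locally centered* scatter matrix (rank at
most ``n_k - 1``, so ``n_k - 1`` components are the maximum available) and
uploads the square-root-eigenvalue-scaled eigenvectors together with its
mean offset from the shared global center and its sample count. The server
stacks all scaled eigenvector rows plus one ``sqrt(n_k) * (mu_k - mu)`` row
per client; the Gram matrix of that stack equals the pooled globally
centered scatter *exactly*, so an SVD of the stack recovers the centralized
principal axes up to floating-point error whenever the trailing retained
singular value is separated from the first discarded one.

The global center itself comes from one aggregation round of per-client
(observed-dosage sum, observed count) pairs; missing calls are imputed with
the global center, i.e. they contribute nothing after centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeBlock

__all__ = [
    "LocalPCAPacket",
    "PCAModel",
    "global_center",
    "local_pca",
    "pstack_aggregate",
    "centralized_pca",
    "project",
    "pca_comm_cost",
    "FederatedPCA",
    "PCAResults",
]


@dataclass
class LocalPCAPacket:
    """One client's upload: top ``d_k`` eigenpairs of the locally centered
    scatter, the client mean offset from the global center, and ``n_k``."""

    node_id: str
    eigenvalues: np.ndarray  # (d_k,), nonincreasing
    eigenvectors: np.ndarray  # (d_k, m), orthonormal rows
    mean_offset: np.ndarray  # (m,), sqrt(n_k) * (local mean - global center)
    n_samples: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        self.mean_offset = np.asarray(self.mean_offset, dtype=np.float64)
        d, m = self.eigenvectors.shape
        if self.eigenvalues.shape != (d,):
            raise ValueError("eigenvalue/eigenvector shape mismatch")
        if self.mean_offset.shape != (m,):
            raise ValueError("mean offset length must equal variant count")
        if d > self.n_samples - 1:
            raise ValueError("at most n_k - 1 local components are available")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be nonincreasing")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class PCAModel:
    """Shared principal-axis model: loadings (n_pcs x m, orthonormal rows),
    the global center, optional per-variant scale, and singular values."""

    loadings: np.ndarray
    center: np.ndarray
    explained: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]


def global_center(blocks: list[GenotypeBlock]) -> np.ndarray:
    """Global per-variant mean dosage from per-client (sum, count) pairs."""
    total = np.zeros(blocks[0].n_variants)
    count = np.zeros(blocks[0].n_variants)
    for b in blocks:
        obs = b.dosages != -1
        total += np.where(obs, b.dosages, 0).sum(axis=0)
        count += obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, 0.0)


def _centered(block: GenotypeBlock, center: np.ndarray, scale: np.ndarray | None) -> np.ndarray:
    x = block.dosages_float(impute=center) - center
    if scale is not None:
        x = x * scale
    return x


def genotype_scale(center: np.ndarray) -> np.ndarray:
    """1/sqrt(2 p (1-p)) standardization weights from the global mean dosage."""
    p = np.clip(center / 2.0, 1e-6, 1 - 1e-6)
    return 1.0 / np.sqrt(2.0 * p * (1.0 - p))


def local_pca(
    block: GenotypeBlock,
    center: np.ndarray,
    d: int,
    node_id: str = "",
    scale: np.ndarray | None = None,
) -> LocalPCAPacket:
    """One client's PCA packet: ``d`` top eigenpairs of its local scatter.

    ``d`` may not exceed ``n_k - 1``. Missing dosages are imputed with the
    shared global center before centering.
    """
    n = block.n_samples
    if d > n - 1:
        raise ValueError(f"d={d} exceeds n_k - 1 = {n - 1}")
    x = _centered(block, center, scale)
    mu_local = x.mean(axis=0)
    xc = x - mu_local
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    return LocalPCAPacket(
        node_id=node_id,
        eigenvalues=(s**2)[:d],
        eigenvectors=vt[:d],
        mean_offset=mu_local * np.sqrt(n),
        n_samples=n,
    )


def _stack(packets: list[LocalPCAPacket]) -> np.ndarray:
    m = packets[0].eigenvectors.shape[1]
    rows = []
    for p in packets:
        if p.eigenvectors.shape[1] != m:
            raise ValueError("packets disagree on variant count")
        rows.append(np.sqrt(np.maximum(p.eigenvalues, 0.0))[:, None] * p.eigenvectors)
        rows.append(p.mean_offset[None, :])  # already sqrt(n_k)-scaled
    return np.vstack(rows)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(len(idx)), idx])
    signs[signs == 0] = 1.0
    return loadings * signs[:, None]


def pstack_aggregate(
    packets: list[LocalPCAPacket], n_pcs: int, center: np.ndarray, scale: np.ndarray | None = None
) -> PCAModel:
    """Server aggregation: stack scaled client rows, SVD, keep top axes."""
    if not packets:
        raise ValueError("need at least one packet")
    stacked = _stack(packets)
    _, s, vt = np.linalg.svd(stacked, full_matrices=False)
    n_pcs = min(n_pcs, vt.shape[0])
    return PCAModel(
        loadings=_fix_signs(vt[:n_pcs]),
        center=np.asarray(center, dtype=np.float64),
        explained=s[:n_pcs],
        scale=scale,
    )


def centralized_pca(
    blocks: list[GenotypeBlock],
    n_pcs: int,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> PCAModel:
    """Reference PCA on the pooled centered data (same center convention)."""
    if center is None:
        center = global_center(blocks)
    pooled = np.vstack([_centered(b, center, scale) for b in blocks])
    _, s, vt = np.linalg.svd(pooled, full_matrices=False)
    n_pcs = min(n_pcs, vt.shape[0])
    return PCAModel(
        loadings=_fix_signs(vt[:n_pcs]),
        center=np.asarray(center, dtype=np.float64),
        explained=s[:n_pcs],
        scale=scale,
    )


def project(model: PCAModel, block: GenotypeBlock) -> np.ndarray:
    """PC scores: (dosages - center) @ loadings', missing imputed with the
    model center (contributing zero after centering)."""
    if block.n_variants != model.loadings.shape[1]:
        raise ValueError("variant count does not match the PCA model")
    x = _centered(block, model.center, model.scale)
    return x @ model.loadings.T


def pca_comm_cost(
    m_variants: int,
    packets: list[LocalPCAPacket],
    bytes_per_value: int = 8,
    n_pcs: int = 20,
) -> int:
    """Bytes moved: per-client upload of d_k eigenvectors (d_k * m) plus
    eigenvalues (d_k), and a broadcast of n_pcs * m loadings per client.
    Linear in the number of variants."""
    upload = sum(
        (p.n_components * m_variants + p.n_components) * bytes_per_value
        for p in packets
    )
    broadcast = len(packets) * n_pcs * m_variants * bytes_per_value
    return upload + broadcast


# ---------------------------------------------------------------------------
# Model-style wrapper


class FederatedPCA:
    """Federated PCA over a set of client genotype blocks.

    Parameters
    ----------
    blocks : list of GenotypeBlock
        Client data restricted to the shared variant union, identical order.
    n_pcs : int
        Number of shared principal axes to retain (default 20).
    standardize : bool
        Scale centered dosages by 1/sqrt(2p(1-p)); off by default.
    d_k : "full" or int
        Local components per client; "full" means n_k - 1 (exact mode).
    """

    def __init__(
        self,
        blocks: list[GenotypeBlock],
        n_pcs: int = 20,
        standardize: bool = False,
        d_k: int | str = "full",
        node_ids: list[str] | None = None,
    ) -> None:
        if not blocks:
            raise ValueError("need at least one client block")
        self.blocks = blocks
        self.n_pcs = n_pcs
        self.standardize = standardize
        self.d_k = d_k
        self.node_ids = node_ids or [f"client{i}" for i in range(len(blocks))]

    def fit(self) -> "PCAResults":
        center = global_center(self.blocks)
        scale = genotype_scale(center) if self.standardize else None
        packets = []
        for node_id, b in zip(self.node_ids, self.blocks):
            d = b.n_samples - 1 if self.d_k == "full" else min(self.d_k, b.n_samples - 1)
            packets.append(local_pca(b, center, d, node_id=node_id, scale=scale))
        model = pstack_aggregate(packets, self.n_pcs, center, scale=scale)
        cost = pca_comm_cost(self.blocks[0].n_variants, packets, 8, self.n_pcs)
        return PCAResults(model=model, packets=packets, comm_bytes=cost)


@dataclass
class PCAResults:
    """Fitted federated PCA: the shared model, the client packets that built
    it, and the communication bill."""

    model: PCAModel
    packets: list[LocalPCAPacket]
    comm_bytes: int

    def project(self, block: GenotypeBlock) -> np.ndarray:
        return project(self.model, block)

    @property
    def loadings(self) -> np.ndarray:
        return self.model.loadings

    @property
    def explained(self) -> np.ndarray:
        return self.model.explained
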