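"""Kronecker composite kernels over (genotype, environment, trait) cells.

The training-set optimization works on the covariance of the full grid of
phenotyping cells.  Under separability this covariance is a Kronecker product

    K = Sigma_G (x) Sigma_E (x) Sigma_T        ("GET", Sigma_E = I_q)
    K = Sigma_G (x) K_E     (x) Sigma_T        ("GWT", enviromic kernel)

which is never materialized unless asked: entries are factor-product lookups
and the spectrum is the outer product of factor spectra.  Cells are ordered
genotype-major, environment next, trait fastest, and addressed by id tuples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enviro import EnvKernel
from .markers import GenomicRelationship

__all__ = ["CompositeKernel", "KernelSpectrum", "build_composite_kernel", "kernel_spectrum"]

_PSD_TOL = 1e-8


def _check_factor(name: str, mat: np.ndarray) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"factor {name} must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"factor {name} must be symmetric")
    m = (m + m.T) / 2.0
    w = np.linalg.eigvalsh(m)
    if w.min() < -_PSD_TOL * max(1.0, abs(w.max())):
        raise ValueError(f"factor {name} is not PSD (min eigenvalue {w.min():.3g})")
    return m


@dataclass
class CompositeKernel:
    """Ordered Kronecker factors [(name, matrix, ids)]; cells are id tuples."""

    factors: list[tuple[str, np.ndarray, list[str]]]
    kind: str = "custom"  # "GET" | "GWT" | "custom"

    def __post_init__(self) -> None:
        checked = []
        for name, mat, ids in self.factors:
            m = _check_factor(name, mat)
            if m.shape[0] != len(ids):
                raise ValueError(f"factor {name}: ids do not match dimension")
            checked.append((name, m, list(ids)))
        self.factors = checked
        self._id_maps = [{i: k for k, i in enumerate(ids)} for _, _, ids in self.factors]

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(len(ids) for _, _, ids in self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    def cell_ids(self) -> list[tuple[str, ...]]:
        """All cells in flat order (first factor major, last factor fastest)."""
        out = [()]
        for _, _, ids in self.factors:
            out = [c + (i,) for c in out for i in ids]
        return out

    def flat_index(self, cell: tuple[str, ...]) -> int:
        if len(cell) != len(self.factors):
            raise KeyError(f"cell {cell!r} has wrong arity")
        idx = 0
        for coord, m, d in zip(cell, self._id_maps, self.dims):
            if coord not in m:
                raise KeyError(f"unknown id {coord!r} in cell {cell!r}")
            idx = idx * d + m[coord]
        return idx

    def entry(self, cell_a: tuple[str, ...], cell_b: tuple[str, ...]) -> float:
        """K[a, b] as the product of factor entries — no materialization."""
        v = 1.0
        for (name, mat, _), m, a, b in zip(self.factors, self._id_maps, cell_a, cell_b):
            v *= mat[m[a], m[b]]
        return float(v)

    def submatrix(self, cells_a: list[tuple[str, ...]], cells_b: list[tuple[str, ...]] | None = None) -> np.ndarray:
        """Cross-covariance block between two cell lists (len_a x len_b)."""
        if cells_b is None:
            cells_b = cells_a
        idx_a = np.array([[m[c[k]] for k, m in enumerate(self._id_maps)] for c in cells_a])
        idx_b = np.array([[m[c[k]] for k, m in enumerate(self._id_maps)] for c in cells_b])
        out = np.ones((len(cells_a), len(cells_b)))
        for k, (_, mat, _) in enumerate(self.factors):
            out *= mat[np.ix_(idx_a[:, k], idx_b[:, k])]
        return out

    def materialize(self) -> np.ndarray:
        """Dense Kronecker product (tests and tiny panels only)."""
        out = np.ones((1, 1))
        for _, mat, _ in self.factors:
            out = np.kron(out, mat)
        return out

    def to_hdf5(self, path) -> None:
        """Store factor matrices and id lists (never the dense cells^2 matrix)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["kind"] = self.kind
            for i, (name, mat, ids) in enumerate(self.factors):
                grp = f.create_group(f"factor{i}")
                grp.attrs["name"] = name
                grp.create_dataset("matrix", data=mat)
                grp.create_dataset("ids", data=np.array(ids, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "CompositeKernel":
        import h5py

        factors = []
        with h5py.File(path, "r") as f:
            kind = f.attrs["kind"]
            for i in range(len(f)):
                grp = f[f"factor{i}"]
                ids = [s.decode() for s in grp["ids"][()]]
                factors.append((str(grp.attrs["name"]), grp["matrix"][()], ids))
        return cls(factors, kind=str(kind))


@dataclass
class KernelSpectrum:
    eigenvalues: np.ndarray  # descending
    factor_eigenvalues: list[np.ndarray]

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if ev.min(initial=0.0) < -_PSD_TOL * max(1.0, abs(ev.max(initial=1.0))):
            raise ValueError("negative composite eigenvalue")
        self.eigenvalues = ev


def build_composite_kernel(
    g: GenomicRelationship | np.ndarray,
    env_part: EnvKernel | np.ndarray | int,
    t: np.ndarray,
    kind: str = "custom",
    genotype_ids: list[str] | None = None,
    environment_ids: list[str] | None = None,
    trait_ids: list[str] | None = None,
) -> CompositeKernel:
    """Assemble the (genotype, environment, trait) kernel.

    ``kind='GET'`` expects ``env_part`` to be the number of environments (an
    identity factor: environments treated as unrelated); ``kind='GWT'`` expects
    the enviromic kernel K_E.  ``t`` is the trait covariance of the
    standardized BLUEs.
    """
    if isinstance(g, GenomicRelationship):
        g_mat, g_ids = g.matrix, g.individual_ids
    else:
        g_mat = np.asarray(g, dtype=float)
        g_ids = genotype_ids or [f"G{i}" for i in range(g_mat.shape[0])]
    if isinstance(env_part, EnvKernel):
        e_mat, e_ids = env_part.matrix, env_part.environment_ids
    elif isinstance(env_part, (int, np.integer)):
        e_mat = np.eye(int(env_part))
        e_ids = environment_ids or [f"E{i}" for i in range(int(env_part))]
    else:
        e_mat = np.asarray(env_part, dtype=float)
        e_ids = environment_ids or [f"E{i}" for i in range(e_mat.shape[0])]
    t_mat = np.asarray(t, dtype=float)
    t_ids = trait_ids or [f"T{i}" for i in range(t_mat.shape[0])]
    if kind == "GET" and not np.allclose(e_mat, np.eye(e_mat.shape[0])):
        raise ValueError("GET kernel uses an identity environment factor")
    return CompositeKernel(
        factors=[("Sigma_G", g_mat, list(g_ids)), ("Sigma_E", e_mat, list(e_ids)),
                 ("Sigma_T", t_mat, list(t_ids))],
        kind=kind,
    )


def kernel_spectrum(k: CompositeKernel, eigenvectors: bool = False) -> KernelSpectrum:
    """Composite eigenvalues = all products of factor eigenvalues, descending.

    Works factor-wise; the dense Kronecker matrix is never formed.
    """
    factor_ev = [np.linalg.eigvalsh(mat) for _, mat, _ in k.factors]
    ev = np.ones(1)
    for fe in factor_ev:
        ev = np.outer(ev, fe).ravel()
    ev = np.sort(ev)[::-1]
    ev[np.abs(ev) < 1e-12] = 0.0
    return KernelSpectrum(eigenvalues=ev, factor_eigenvalues=factor_ev)
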