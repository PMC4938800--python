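"""Essential dynamics: PCA of Cα coordinate fluctuations.

The covariance of centered Cα coordinates over a superposed ensemble is
eigendecomposed; the leading eigenvectors span the essential subspace of
large collective motions, eigenvalues measure per-mode variance (Å²; the
conformer spread sqrt(sum lambda) is also reported in nm), and projections
place every conformer in the essential subspace.  Population (divide-by-N)
statistics throughout; eigenvector signs are fixed by making the
largest-magnitude component positive so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import ConformerEnsemble, ResidueKey, ResidueProfile, Structure


@dataclass
class PCModel:
    """Principal components of Cα fluctuations.

    ``eigvecs`` holds one orthonormal eigenvector per row (K x 3m); the
    projection matrix is N conformers x K, in Å.
    """

    mean_coord: np.ndarray  # (m, 3)
    eigvals: np.ndarray  # (K,), Å^2, descending
    eigvecs: np.ndarray  # (K, 3m)
    projections: np.ndarray  # (N, K)
    selection: list[ResidueKey]
    selection_structure: Structure

    @property
    def n_conformers(self) -> int:
        return self.projections.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.eigvals)

    def eigvals_nm2(self) -> np.ndarray:
        return self.eigvals / 100.0


def _ca_selection(e: ConformerEnsemble,
                  selection: list[ResidueKey] | None) -> tuple[np.ndarray,
                                                               list[ResidueKey]]:
    ca = e.reference.ca_index()
    keys = selection if selection is not None else list(ca)
    try:
        idx = np.array([ca[k] for k in keys])
    except KeyError as exc:
        raise ValueError(f"selection residue {exc.args[0]} has no Calpha") from exc
    return idx, list(keys)


def fit_pca(e: ConformerEnsemble,
            selection: list[ResidueKey] | None = None) -> PCModel:
    """Eigendecompose the Cα covariance of a superposed ensemble."""
    if not e.superposed:
        raise ValueError("ensemble must be superposed before PCA")
    idx, keys = _ca_selection(e, selection)
    m = len(idx)
    N = e.n_conformers
    if N <= 3 * m:
        warnings.warn(f"only {N} conformers for {3 * m} coordinates; "
                      "covariance will be rank-deficient")
    X = e.coords[:, idx, :].reshape(N, 3 * m)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / N
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order].T  # rows
    # deterministic sign: largest-magnitude component positive
    for k in range(vecs.shape[0]):
        if vecs[k, np.argmax(np.abs(vecs[k]))] < 0:
            vecs[k] = -vecs[k]
    proj = Xc @ vecs.T
    sub = e.reference.subset(np.isin(np.arange(e.reference.n_atoms), idx))
    return PCModel(mean_coord=mean.reshape(m, 3), eigvals=vals, eigvecs=vecs,
                   projections=proj, selection=keys, selection_structure=sub)


def normalized_spectrum(m: PCModel, reference: PCModel, k: int) -> np.ndarray:
    """First k eigenvalues divided by the reference spectrum's total."""
    total = float(reference.eigvals.sum())
    if total <= 0:
        raise ValueError("reference spectrum sums to zero")
    if k > m.n_modes:
        raise ValueError(f"k={k} exceeds the {m.n_modes} available PCs")
    return m.eigvals[:k] / total


def cumulative_anisotropy(m: PCModel) -> np.ndarray:
    """Cumulative variance fraction per PC (monotone, ends at 1)."""
    total = float(m.eigvals.sum())
    if total <= 0:
        raise ValueError("spectrum sums to zero")
    return np.cumsum(m.eigvals) / total


def pc_trajectory(m: PCModel, k: int, amplitudes: np.ndarray) -> ConformerEnsemble:
    """Pseudo-trajectory along PC ``k`` (1-based): mean + a sqrt(lambda_k) v_k.

    The returned ensemble lives on the PCA selection's Cα sub-structure and
    is flagged superposed, so angle series can be measured on single PCs.
    """
    if not 1 <= k <= m.n_modes:
        raise ValueError(f"PC {k} out of range")
    lam = float(m.eigvals[k - 1])
    if lam <= 0:
        raise ValueError(f"PC {k} has zero variance; no trajectory")
    amplitudes = np.asarray(amplitudes, dtype=float)
    disp = np.sqrt(lam) * m.eigvecs[k - 1]
    flat = m.mean_coord.reshape(-1)[None, :] + amplitudes[:, None] * disp[None, :]
    coords = flat.reshape(len(amplitudes), -1, 3)
    return ConformerEnsemble(reference=m.selection_structure, coords=coords,
                             superposed=True)


def gaussian_amplitude_grid(n: int = 41, span: float = 3.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude grid in units of sqrt(lambda) with standard-normal weights."""
    a = np.linspace(-span, span, n)
    w = np.exp(-0.5 * a ** 2)
    return a, w / w.sum()


def conformer_spread(m: PCModel, pcs: list[int], n_boot: int = 100,
                     seed: int = 0) -> tuple[float, float]:
    """Conformer spread sigma = sqrt(sum_k lambda_k) over the given PCs, nm.

    The uncertainty is a bootstrap over conformers: projections are
    resampled, the covariance refit in projection space, and the SD of the
    resampled sigma returned.
    """
    if not pcs:
        raise ValueError("empty PC set")
    pcs0 = [p - 1 for p in pcs]
    sigma_a = float(np.sqrt(m.eigvals[pcs0].sum()))
    rng = np.random.default_rng(seed)
    N = m.n_conformers
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, N, N)
        P = m.projections[idx]
        Pc = P - P.mean(axis=0)
        cov = Pc.T @ Pc / N
        vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        boots[b] = np.sqrt(np.maximum(vals[pcs0], 0.0).sum())
    return sigma_a / 10.0, float(boots.std() / 10.0)


def rmsf_profile(e: ConformerEnsemble) -> ResidueProfile:
    """Per-residue root-mean-square Cα fluctuation about the ensemble mean, Å."""
    if not e.superposed:
        raise ValueError("ensemble must be superposed")
    ca = e.reference.ca_index()
    keys = list(ca)
    idx = np.array(list(ca.values()))
    xyz = e.coords[:, idx, :]
    msf = np.mean(np.sum((xyz - xyz.mean(axis=0)) ** 2, axis=2), axis=0)
    return ResidueProfile(keys=keys, values=np.sqrt(msf), label="RMSF [A]")
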