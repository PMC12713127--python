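"""Complex principal component analysis (cPCA) of analytic ICN signals.

Each ICN time course ``x(t)`` is lifted to its analytic signal
``z(t) = x(t) + i*H(x(t))`` (H = Hilbert transform), whose modulus and
argument are instantaneous amplitude and phase. The complex correlation
matrix ``R_ij = (1/T) * sum_t z_i(t) * conj(z_j(t))`` is Hermitian positive
semidefinite; its leading eigenvector ``u_1`` carries a per-ICN amplitude
map ``|u_1|`` and phase map ``arg(u_1)``, which together describe the
dominant phase-coherent spatiotemporal pattern (e.g. a traveling wave).

Phase convention: component time courses are ``a_k(t) = u_k^H z(t)``, so
for rank-1 data ``z_m(t) ~ u_m * a(t)``; an ICN whose activity peaks
*later* (lags) therefore carries a *more negative* ``arg(u_1)``. The
phase-delay map is ``-arg(u_1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .timeseries import ICNTimeSeries


@dataclass(frozen=True)
class AnalyticSignalMatrix:
    """Complex ``T x N`` analytic-signal matrix; real part equals the
    (demeaned) input series."""

    Z: np.ndarray
    tr_seconds: float
    flags: frozenset = frozenset()
    icn_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class ComplexCorrMatrix:
    """Hermitian PSD complex correlation matrix of analytic signals."""

    R: np.ndarray
    normalized: bool
    icn_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if np.abs(R - R.conj().T).max() > 1e-10:
            raise ValueError("R must be Hermitian")
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class CPCAResult:
    """Top-K complex eigenpairs with derived amplitude and phase maps.

    ``loadings`` is ``N x K`` with unit-norm columns (canonical global
    phase), ``eigenvalues`` descending and non-negative, ``timecourses``
    is ``T x K`` with ``a_k(t) = u_k^H z(t)``.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    timecourses: np.ndarray
    icn_ids: tuple[int, ...] = ()

    @property
    def amplitude_map(self) -> np.ndarray:
        return np.abs(self.loadings[:, 0])

    @property
    def phase_map(self) -> np.ndarray:
        """arg(u_1) in radians, (-pi, pi]; more negative = later peak."""
        return np.angle(self.loadings[:, 0])


def analytic_signal(ts: ICNTimeSeries) -> AnalyticSignalMatrix:
    """Per-column analytic signal via the discrete Hilbert transform.

    Columns are demeaned first (with a warning if the departure is
    material) since the analytic signal of a nonzero-mean series conflates
    DC with amplitude.
    """
    x = ts.data
    if x.shape[0] < 4:
        raise ValueError("need at least 4 timepoints for the Hilbert transform")
    mu = x.mean(axis=0)
    scale = np.abs(x).max() or 1.0
    if np.abs(mu).max() > 1e-8 * scale:
        warnings.warn("columns are not zero-mean; demeaning before Hilbert "
                      "transform", stacklevel=2)
    Z = signal.hilbert(x - mu, axis=0)
    return AnalyticSignalMatrix(Z=Z, tr_seconds=ts.tr_seconds, flags=ts.flags,
                                icn_ids=ts.icn_ids)


def complex_corr(zmat: AnalyticSignalMatrix | np.ndarray, normalize: bool = True,
                 edge_exclude: int = 0) -> ComplexCorrMatrix:
    """Complex correlation matrix ``R_ij = (1/T) sum_t z_i(t) conj(z_j(t))``.

    ``edge_exclude`` drops that many frames from each end of the time
    average to suppress Hilbert-transform ringing. With ``normalize`` the
    diagonal is scaled to 1, making ``|R_ij|`` a coherence in [0, 1].
    """
    ids: tuple[int, ...] = ()
    if isinstance(zmat, AnalyticSignalMatrix):
        ids = zmat.icn_ids
        Z = zmat.Z
    else:
        Z = np.asarray(zmat)
    T = Z.shape[0]
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    if edge_exclude:
        if T - 2 * edge_exclude < 2:
            raise ValueError(f"edge_exclude={edge_exclude} leaves fewer than "
                             f"2 of {T} frames")
        Z = Z[edge_exclude:T - edge_exclude]
    R = Z.T @ Z.conj() / Z.shape[0]
    if normalize:
        d = np.real(np.diag(R))
        bad = np.nonzero(d <= 0)[0]
        if bad.size:
            names = [ids[i] if ids else i + 1 for i in bad]  # 1-based default
            raise ValueError(f"zero-power column(s) for ICN(s) {names}; "
                             "cannot normalize")
        scale = np.sqrt(d)
        R = R / np.outer(scale, scale)
    R = (R + R.conj().T) / 2  # enforce exact Hermitian symmetry
    return ComplexCorrMatrix(R=R, normalized=normalize, icn_ids=ids)


def canonical_phase(u: np.ndarray) -> np.ndarray:
    """Fix the arbitrary global phase of a complex vector.

    Rotates by the amplitude-weighted circular mean of the entry phases,
    ``phi* = arg(sum_m |u_m| e^{i arg(u_m)}) = arg(sum_m u_m)``, so the
    rotated vector's weighted mean phase is zero. If the entries cancel
    exactly, the phase of the largest-amplitude entry is used instead.
    """
    u = np.asarray(u, dtype=complex)
    total = np.abs(u).sum()
    if total == 0:
        raise ValueError("cannot fix the phase of a zero vector")
    s = u.sum()
    if np.abs(s) < 1e-12 * total:
        phi = np.angle(u[np.argmax(np.abs(u))])
    else:
        phi = np.angle(s)
    return u * np.exp(-1j * phi)


def decompose(rmat: ComplexCorrMatrix | np.ndarray,
              zmat: AnalyticSignalMatrix | np.ndarray | None = None,
              n_components: int = 1) -> CPCAResult:
    """Top-K eigendecomposition of the complex correlation matrix.

    Eigenpairs are sorted by descending eigenvalue; each loading column is
    unit-norm with its global phase fixed by :func:`canonical_phase`.
    Component time courses are ``a_k(t) = u_k^H z(t)`` when the analytic
    signal is supplied.
    """
    ids: tuple[int, ...] = ()
    if isinstance(rmat, ComplexCorrMatrix):
        ids = rmat.icn_ids
        R = rmat.R
    else:
        R = np.asarray(rmat)
    N = R.shape[0]
    if not (1 <= n_components <= N):
        raise ValueError(f"n_components must lie in [1, {N}], got {n_components}")
    try:
        evals, evecs = linalg.eigh(R)
    except linalg.LinAlgError as exc:  # pragma: no cover - scipy rarely fails
        raise RuntimeError(f"eigendecomposition of R ({N}x{N}) failed") from exc
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.maximum(evals[order], 0.0)
    U = np.column_stack([canonical_phase(evecs[:, k]) for k in order])
    if zmat is None:
        A = np.empty((0, n_components), dtype=complex)
    else:
        Z = zmat.Z if isinstance(zmat, AnalyticSignalMatrix) else np.asarray(zmat)
        A = Z @ U.conj()
    return CPCAResult(loadings=U, eigenvalues=lam, timecourses=A, icn_ids=ids)


def reconstruct_pattern(u1: np.ndarray, window_frames: int) -> np.ndarray:
    """Render one full cycle of the leading component as an ``N x W``
    real pattern directly comparable to a QPP template.

    Column ``w`` is ``Re(u1 * e^{+i*2*pi*w/W})``, one forward period of the
    rank-1 evolution ``Re(u1 * a(t))`` with ``a(t) = e^{i*omega*t}``. Under
    this (and the ``a_k = u_k^H z``) convention an ICN with loading phase
    ``+pi/2`` leads: it attains its peak a quarter-cycle *before* an ICN
    with phase 0.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    u1 = np.asarray(u1, dtype=complex)
    w = np.arange(window_frames)
    return np.real(u1[:, None] * np.exp(2j * np.pi * w[None, :] / window_frames))


def cpca(ts: ICNTimeSeries, n_components: int = 1, *, normalize: bool = True,
         edge_exclude: int | None = None) -> CPCAResult:
    """Convenience wrapper: analytic signal -> R -> eigendecomposition.

    ``edge_exclude`` defaults to 8 frames (one template window at TR = 3 s)
    clipped to at most a quarter of the series.
    """
    if edge_exclude is None:
        edge_exclude = min(8, ts.n_timepoints // 4 - 1)
        edge_exclude = max(edge_exclude, 0)
    Z = analytic_signal(ts)
    R = complex_corr(Z, normalize=normalize, edge_exclude=edge_exclude)
    return decompose(R, Z, n_components=n_components)
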