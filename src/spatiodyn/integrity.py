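"""Template-integrity metrics: ICN-pair correlation structure of
spatiotemporal templates, cross-cohort deltas, and domain-level summaries.

For cohort templates ``Q_i`` (N ICNs x W frames), the self-similarity
matrix ``C_ii`` correlates every pair of ICN time courses within the
template window, and the cross-cohort matrix ``C_ij`` correlates cohort
``i``'s rows against cohort ``j``'s. The integrity delta
``dC_ij = C_ii - C_ij`` measures how strongly cohort ``j``'s pattern
departs from the reference; attenuated (degenerated) networks show
predominantly positive deltas. cPCA engagement indices are the leading
loading magnitudes ``l = |u_1|`` averaged per domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .atlas import AtlasMap
from .cpca import CPCAResult
from .qpp import QPPTemplate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateCorrMatrix:
    """N x N Pearson correlations between template ICN time courses."""

    C: np.ndarray
    cohort_a: str
    cohort_b: str
    source: str = "qpp"  # or "cpca"
    icn_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if np.any(np.abs(self.C) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class IntegrityDelta:
    """Elementwise ``C_self - C_cross`` against a reference cohort."""

    delta: np.ndarray
    reference: str
    comparison: str
    source: str = "qpp"
    icn_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class DomainEngagement:
    """Per-domain mean engagement scores with the per-ICN values kept."""

    scores: dict[str, float]
    icn_scores: dict[int, float]
    source: str = "cpca_loading"


class AlignmentResult(NamedTuple):
    pattern: np.ndarray
    shift: int
    sign: int
    correlation: float


def _pattern_of(q) -> np.ndarray:
    if isinstance(q, QPPTemplate):
        return q.pattern
    return np.asarray(q, dtype=float)


def _ids_of(q, n: int) -> tuple[int, ...]:
    if isinstance(q, QPPTemplate) and q.icn_ids:
        return q.icn_ids
    return tuple(range(1, n + 1))


def _standardize_rows(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Pc = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Pc, axis=1)
    ok = norms > 0
    Pc[ok] /= norms[ok, None]
    return Pc, ok


def template_corr(qa, qb, cohort_a: str = "a", cohort_b: str = "b",
                  source: str = "qpp") -> TemplateCorrMatrix:
    """Entry ``(m, n)`` = Pearson correlation of ICN ``m``'s W-frame time
    course in ``qa`` with ICN ``n``'s in ``qb``. Zero-variance rows give 0
    entries with a logged warning."""
    A = _pattern_of(qa)
    B = _pattern_of(qb)
    if A.shape != B.shape:
        raise ValueError(f"template shapes differ: {A.shape} vs {B.shape}")
    Ac, a_ok = _standardize_rows(A)
    Bc, b_ok = _standardize_rows(B)
    if not (a_ok.all() and b_ok.all()):
        logger.warning("zero-variance template row(s); correlations set to 0")
    C = np.clip(Ac @ Bc.T, -1.0, 1.0)
    C[~a_ok, :] = 0.0
    C[:, ~b_ok] = 0.0
    return TemplateCorrMatrix(C=C, cohort_a=cohort_a, cohort_b=cohort_b,
                              source=source, icn_ids=_ids_of(qa, A.shape[0]))


def align_templates(q_ref, q_other) -> AlignmentResult:
    """Best circular shift ``s`` and sign ``sigma`` of ``q_other`` against
    ``q_ref`` under flattened Pearson correlation (templates are only
    defined up to shift and sign). Ties break to the smallest shift, then
    positive sign."""
    ref = _pattern_of(q_ref)
    other = _pattern_of(q_other)
    if ref.shape != other.shape:
        raise ValueError(f"template shapes differ: {ref.shape} vs {other.shape}")
    W = ref.shape[1]
    rflat = ref.ravel()
    rc = rflat - rflat.mean()
    rn = np.linalg.norm(rc)
    best = (-np.inf, 0, 1)
    for s in range(W):
        shifted = np.roll(other, s, axis=1)
        for sigma in (1, -1):
            f = (sigma * shifted).ravel()
            fc = f - f.mean()
            d = rn * np.linalg.norm(fc)
            corr = float(rc @ fc / d) if d > 0 else 0.0
            if corr > best[0]:
                best = (corr, s, sigma)
    corr, s, sigma = best
    return AlignmentResult(pattern=sigma * np.roll(other, s, axis=1),
                           shift=s, sign=sigma, correlation=corr)


def phase_locked_template(ts, detected: QPPTemplate, reference) -> np.ndarray:
    """Re-extract a cohort's template in the reference cohort's phase.

    Cohort templates are defined only up to a circular shift; rolling an
    8-frame window, however, wraps one or more junk frames into the
    pattern. Instead, the shift and sign estimated by
    :func:`align_templates` are removed by re-averaging the data segments
    at the shift-corrected occurrence starts, which keeps every frame a
    genuine sample of the comparison cohort's pattern.
    """
    from .qpp import refine_template  # local import avoids a cycle at load

    ref = _pattern_of(reference)
    W = ref.shape[1]
    aln = align_templates(ref, detected.pattern)
    offset = aln.shift if aln.shift <= W // 2 else aln.shift - W
    T = ts.data.shape[0] if isinstance(ts, QPPTemplate) else np.asarray(
        ts.data if hasattr(ts, "data") else ts).shape[0]
    starts = [s - offset for s in detected.occurrences
              if 0 <= s - offset <= T - W]
    if not starts:
        return aln.pattern
    data = ts.data if hasattr(ts, "data") else np.asarray(ts)
    return aln.sign * refine_template(data, starts, W)


def integrity_delta(c_self: TemplateCorrMatrix, c_cross: TemplateCorrMatrix
                    ) -> IntegrityDelta:
    """``delta = C_self - C_cross`` with direction metadata (reference
    minus comparison)."""
    if c_self.C.shape != c_cross.C.shape:
        raise ValueError("matrix shapes differ")
    if c_self.cohort_a != c_self.cohort_b:
        raise ValueError("C_self must be a self-correlation matrix "
                         f"(got {c_self.cohort_a} vs {c_self.cohort_b})")
    if c_cross.cohort_a != c_self.cohort_a:
        raise ValueError(
            f"reference mismatch: {c_self.cohort_a} vs {c_cross.cohort_a}")
    return IntegrityDelta(delta=c_self.C - c_cross.C,
                          reference=c_self.cohort_a,
                          comparison=c_cross.cohort_b,
                          source=c_self.source, icn_ids=c_self.icn_ids)


def engagement_scores(result: CPCAResult | np.ndarray, atlas: AtlasMap
                      ) -> DomainEngagement:
    """Per-ICN engagement ``l = |u_1|`` averaged within each atlas domain."""
    if isinstance(result, CPCAResult):
        l = result.amplitude_map
        ids = result.icn_ids or tuple(range(1, len(l) + 1))
    else:
        l = np.abs(np.asarray(result))
        ids = tuple(range(1, len(l) + 1))
    if len(ids) != atlas.n_icn:
        raise ValueError(f"amplitude map has {len(ids)} ICNs, atlas has "
                         f"{atlas.n_icn}")
    icn_scores: dict[int, float] = {}
    for i, icn in enumerate(ids):
        atlas.domain_of(icn)  # raises naming the ICN if missing
        icn_scores[icn] = float(l[i])
    scores = {d: float(np.mean([icn_scores[i] for i in atlas.icns_in_domain(d)]))
              for d in atlas.domains}
    return DomainEngagement(scores=scores, icn_scores=icn_scores,
                            source="cpca_loading")


def domain_block_values(mat, atlas: AtlasMap, domain: str) -> np.ndarray:
    """Upper-triangle entries (m < n, both ICNs in ``domain``) of a
    correlation or delta matrix: the observation set for the group tests."""
    if isinstance(mat, TemplateCorrMatrix):
        M, ids = mat.C, mat.icn_ids
    elif isinstance(mat, IntegrityDelta):
        M, ids = mat.delta, mat.icn_ids
    else:
        M = np.asarray(mat)
        ids = tuple(range(1, M.shape[0] + 1))
    if domain not in atlas.domains:
        raise KeyError(f"domain {domain!r} not in atlas")
    members = set(atlas.icns_in_domain(domain))
    if len(members) < 2:
        raise ValueError(f"domain {domain!r} has fewer than 2 ICNs: no pairs")
    pos = {icn: k for k, icn in enumerate(ids)}
    idx = [pos[i] for i in sorted(members) if i in pos]
    if len(idx) < 2:
        raise ValueError(f"matrix covers fewer than 2 ICNs of {domain!r}")
    out = [M[a, b] for ii, a in enumerate(idx) for b in idx[ii + 1:]]
    return np.asarray(out, dtype=float)
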