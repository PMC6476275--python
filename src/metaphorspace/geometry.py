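"""Statistical geometry of a projected subspace: the 48 features.

A subspace holds five labelled points — the word vectors V and N, the
generic mean/maximum/central vectors M, X, C — plus their images V',
N', M', X', C' on the unit sphere and the origin O. From these we take

* 7 distances: the norms of V, N, M, X, C, the separation |VN|, and
  the normalised separation |V'N'|;
* 6 means of distance pairs to generic vectors, full and normalised;
* 6 ratios (min over max of the same pairs — orientation-free);
* 13 directed fractions (a stated numerator over a stated denominator);
* 10 angles, at the origin and at generic-vector vertices;
* 6 triangle areas.

Angles are radians in [0, pi]; ratios lie in [0, 1]; areas and
distances are non-negative. In permissive mode, features whose
definition requires a direction or a denominator that degenerates to
zero come back as NaN; strict mode raises instead.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateVectorError
from .subspace import Subspace

__all__ = [
    "FEATURE_NAMES",
    "angle_at_vertex",
    "angle_at_origin",
    "triangle_area",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    # distances (7)
    "norm_V", "norm_N", "dist_V_N", "norm_M", "norm_X", "norm_C", "dist_Vn_Nn",
    # means (6)
    "mean_VM_NM", "mean_VX_NX", "mean_VC_NC",
    "mean_VnMn_NnMn", "mean_VnXn_NnXn", "mean_VnCn_NnCn",
    # ratios, min/max (6)
    "ratio_VM_NM", "ratio_VX_NX", "ratio_VC_NC",
    "ratio_VnMn_NnMn", "ratio_VnXn_NnXn", "ratio_VnCn_NnCn",
    # directed fractions (13)
    "frac_V_N", "frac_VM_NM", "frac_VX_NX", "frac_VC_NC",
    "frac_mean_VN_M", "frac_mean_VN_X", "frac_mean_VN_C",
    "frac_C_M", "frac_C_X", "frac_M_X",
    "frac_VnMn_NnMn", "frac_VnXn_NnXn", "frac_VnCn_NnCn",
    # angles (10)
    "angle_VON", "angle_VMN", "angle_VXN", "angle_VCN",
    "angle_MOC", "angle_MOX", "angle_COX",
    "angle_VnMnNn", "angle_VnXnNn", "angle_VnCnNn",
    # areas (6)
    "area_VMN", "area_VXM", "area_VCM",
    "area_VnMnNn", "area_VnXnMn", "area_VnCnMn",
)
assert len(FEATURE_NAMES) == 48


def angle_at_vertex(
    A: np.ndarray, B: np.ndarray, Cc: np.ndarray, strict: bool = False
) -> float:
    """Angle (radians) at vertex B between the rays B->A and B->Cc.

    The cosine is clamped to [-1, 1] before arccos to absorb
    floating-point overshoot. A zero-length ray has no direction: NaN
    in permissive mode, :class:`DegenerateVectorError` in strict mode.
    """
    a = np.asarray(A, dtype=np.float64) - np.asarray(B, dtype=np.float64)
    c = np.asarray(Cc, dtype=np.float64) - np.asarray(B, dtype=np.float64)
    na, nc = np.linalg.norm(a), np.linalg.norm(c)
    if na == 0.0 or nc == 0.0:
        if strict:
            raise DegenerateVectorError("zero-length ray at angle vertex")
        return math.nan
    cos = float(np.dot(a, c) / (na * nc))
    return math.acos(max(-1.0, min(1.0, cos)))


def angle_at_origin(u: np.ndarray, v: np.ndarray, strict: bool = False) -> float:
    """Angle between two vectors measured at the origin."""
    z = np.zeros(np.shape(u))
    return angle_at_vertex(u, z, v, strict=strict)


def triangle_area(A: np.ndarray, B: np.ndarray, Cc: np.ndarray) -> float:
    """Area of the triangle ABC in any ambient dimension.

    Uses the Gram form 1/2 * sqrt(|a|^2 |b|^2 - (a.b)^2) with a = B-A,
    b = Cc-A; collinear (and degenerate) triples give 0.
    """
    a = np.asarray(B, dtype=np.float64) - np.asarray(A, dtype=np.float64)
    b = np.asarray(Cc, dtype=np.float64) - np.asarray(A, dtype=np.float64)
    g = np.dot(a, a) * np.dot(b, b) - np.dot(a, b) ** 2
    return 0.5 * math.sqrt(max(g, 0.0))


def _dist(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(u) - np.asarray(v)))


def _ratio(a: float, b: float) -> float:
    """Min over max; 1 when both are zero (equal), 0 when exactly one is."""
    lo, hi = min(a, b), max(a, b)
    if hi == 0.0:
        return 1.0
    return lo / hi


def _frac(num: float, den: float, strict: bool) -> float:
    if den == 0.0:
        if strict:
            raise DegenerateVectorError("zero denominator in directed fraction")
        return math.nan
    return num / den


def extract_features(s: Subspace, strict: bool = False) -> dict[str, float]:
    """All 48 geometric features of a subspace, in canonical order."""
    V, N, M, X, C = s.V, s.N, s.M, s.X, s.C
    Vn, Nn, Mn, Xn, Cn = s.Vn, s.Nn, s.Mn, s.Xn, s.Cn

    nV, nN = float(np.linalg.norm(V)), float(np.linalg.norm(N))
    nM, nX, nC = (float(np.linalg.norm(u)) for u in (M, X, C))

    dVM, dNM = _dist(V, M), _dist(N, M)
    dVX, dNX = _dist(V, X), _dist(N, X)
    dVC, dNC = _dist(V, C), _dist(N, C)
    dVnMn, dNnMn = _dist(Vn, Mn), _dist(Nn, Mn)
    dVnXn, dNnXn = _dist(Vn, Xn), _dist(Nn, Xn)
    dVnCn, dNnCn = _dist(Vn, Cn), _dist(Nn, Cn)

    f: dict[str, float] = {
        "norm_V": nV,
        "norm_N": nN,
        "dist_V_N": _dist(V, N),
        "norm_M": nM,
        "norm_X": nX,
        "norm_C": nC,
        "dist_Vn_Nn": _dist(Vn, Nn),
        "mean_VM_NM": (dVM + dNM) / 2.0,
        "mean_VX_NX": (dVX + dNX) / 2.0,
        "mean_VC_NC": (dVC + dNC) / 2.0,
        "mean_VnMn_NnMn": (dVnMn + dNnMn) / 2.0,
        "mean_VnXn_NnXn": (dVnXn + dNnXn) / 2.0,
        "mean_VnCn_NnCn": (dVnCn + dNnCn) / 2.0,
        "ratio_VM_NM": _ratio(dVM, dNM),
        "ratio_VX_NX": _ratio(dVX, dNX),
        "ratio_VC_NC": _ratio(dVC, dNC),
        "ratio_VnMn_NnMn": _ratio(dVnMn, dNnMn),
        "ratio_VnXn_NnXn": _ratio(dVnXn, dNnXn),
        "ratio_VnCn_NnCn": _ratio(dVnCn, dNnCn),
        "frac_V_N": _frac(nV, nN, strict),
        "frac_VM_NM": _frac(dVM, dNM, strict),
        "frac_VX_NX": _frac(dVX, dNX, strict),
        "frac_VC_NC": _frac(dVC, dNC, strict),
        "frac_mean_VN_M": _frac((nV + nN) / 2.0, nM, strict),
        "frac_mean_VN_X": _frac((nV + nN) / 2.0, nX, strict),
        "frac_mean_VN_C": _frac((nV + nN) / 2.0, nC, strict),
        "frac_C_M": _frac(nC, nM, strict),
        "frac_C_X": _frac(nC, nX, strict),
        "frac_M_X": _frac(nM, nX, strict),
        "frac_VnMn_NnMn": _frac(dVnMn, dNnMn, strict),
        "frac_VnXn_NnXn": _frac(dVnXn, dNnXn, strict),
        "frac_VnCn_NnCn": _frac(dVnCn, dNnCn, strict),
        "angle_VON": angle_at_origin(V, N, strict),
        "angle_VMN": angle_at_vertex(V, M, N, strict),
        "angle_VXN": angle_at_vertex(V, X, N, strict),
        "angle_VCN": angle_at_vertex(V, C, N, strict),
        "angle_MOC": angle_at_origin(M, C, strict),
        "angle_MOX": angle_at_origin(M, X, strict),
        "angle_COX": angle_at_origin(C, X, strict),
        "angle_VnMnNn": angle_at_vertex(Vn, Mn, Nn, strict),
        "angle_VnXnNn": angle_at_vertex(Vn, Xn, Nn, strict),
        "angle_VnCnNn": angle_at_vertex(Vn, Cn, Nn, strict),
        "area_VMN": triangle_area(V, M, N),
        "area_VXM": triangle_area(V, X, M),
        "area_VCM": triangle_area(V, C, M),
        "area_VnMnNn": triangle_area(Vn, Mn, Nn),
        "area_VnXnMn": triangle_area(Vn, Xn, Mn),
        "area_VnCnMn": triangle_area(Vn, Cn, Mn),
    }
    assert tuple(f) == FEATURE_NAMES
    return f
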