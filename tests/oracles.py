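"""Independent scalar oracles used by the test suite.

Everything here is written in plain Python (loops, ``math``), on
purpose: these functions re-derive quantities by a different route than
the library (brute-force pair scans, the law of cosines, Heron's
formula) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import Counter


# --- corpus ------------------------------------------------------------


def brute_force_counts(sentences, vocab_words, window):
    """O(n^2) within-sentence pair scan: (w, c) -> count."""
    vocab = set(vocab_words)
    counts = Counter()
    for sent in sentences:
        for i, w in enumerate(sent):
            if w not in vocab:
                continue
            for j, c in enumerate(sent):
                if i != j and abs(i - j) <= window:
                    counts[(w, c)] += 1
    return counts


def scalar_pmi(fwc, fw, fc, W, a):
    """Direct evaluation of the smoothed non-negative PMI formula."""
    if fwc == 0:
        return 0.0
    return math.log2(fwc * W / (fw * (fc + a)) + 1.0)


# --- geometry ----------------------------------------------------------


def _norm(u):
    return math.sqrt(sum(x * x for x in u))


def _sub(u, v):
    return [a - b for a, b in zip(u, v)]


def _dist(u, v):
    return _norm(_sub(u, v))


def _dot(u, v):
    return sum(a * b for a, b in zip(u, v))


def _unit(u):
    n = _norm(u)
    return [x / n for x in u] if n > 0 else list(u)


def law_of_cosines_angle(A, B, C):
    """Angle at vertex B from the three pairwise distances only."""
    ba, bc, ac = _dist(B, A), _dist(B, C), _dist(A, C)
    cos = (ba * ba + bc * bc - ac * ac) / (2.0 * ba * bc)
    return math.acos(max(-1.0, min(1.0, cos)))


def heron_area(A, B, C):
    """Triangle area from the three pairwise distances only."""
    a, b, c = _dist(A, B), _dist(A, C), _dist(B, C)
    s = (a + b + c) / 2.0
    val = s * (s - a) * (s - b) * (s - c)
    return math.sqrt(max(val, 0.0))


def _ratio(a, b):
    lo, hi = min(a, b), max(a, b)
    return 1.0 if hi == 0.0 else lo / hi


def _frac(num, den):
    return float("nan") if den == 0.0 else num / den


def _angle(A, B, C):
    a, c = _sub(A, B), _sub(C, B)
    na, nc = _norm(a), _norm(c)
    if na == 0.0 or nc == 0.0:
        return float("nan")
    cos = _dot(a, c) / (na * nc)
    return math.acos(max(-1.0, min(1.0, cos)))


def scalar_features(V, N, M, X, C):
    """All 48 geometric features, computed with scalar arithmetic and
    Heron's formula (the library uses the Gram form)."""
    V, N, M, X, C = (list(map(float, u)) for u in (V, N, M, X, C))
    O = [0.0] * len(V)
    Vn, Nn, Mn, Xn, Cn = (_unit(u) for u in (V, N, M, X, C))

    nV, nN, nM, nX, nC = (_norm(u) for u in (V, N, M, X, C))
    dVM, dNM = _dist(V, M), _dist(N, M)
    dVX, dNX = _dist(V, X), _dist(N, X)
    dVC, dNC = _dist(V, C), _dist(N, C)
    dVnMn, dNnMn = _dist(Vn, Mn), _dist(Nn, Mn)
    dVnXn, dNnXn = _dist(Vn, Xn), _dist(Nn, Xn)
    dVnCn, dNnCn = _dist(Vn, Cn), _dist(Nn, Cn)

    return {
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
        "frac_V_N": _frac(nV, nN),
        "frac_VM_NM": _frac(dVM, dNM),
        "frac_VX_NX": _frac(dVX, dNX),
        "frac_VC_NC": _frac(dVC, dNC),
        "frac_mean_VN_M": _frac((nV + nN) / 2.0, nM),
        "frac_mean_VN_X": _frac((nV + nN) / 2.0, nX),
        "frac_mean_VN_C": _frac((nV + nN) / 2.0, nC),
        "frac_C_M": _frac(nC, nM),
        "frac_C_X": _frac(nC, nX),
        "frac_M_X": _frac(nM, nX),
        "frac_VnMn_NnMn": _frac(dVnMn, dNnMn),
        "frac_VnXn_NnXn": _frac(dVnXn, dNnXn),
        "frac_VnCn_NnCn": _frac(dVnCn, dNnCn),
        "angle_VON": _angle(V, O, N),
        "angle_VMN": _angle(V, M, N),
        "angle_VXN": _angle(V, X, N),
        "angle_VCN": _angle(V, C, N),
        "angle_MOC": _angle(M, O, C),
        "angle_MOX": _angle(M, O, X),
        "angle_COX": _angle(C, O, X),
        "angle_VnMnNn": _angle(Vn, Mn, Nn),
        "angle_VnXnNn": _angle(Vn, Xn, Nn),
        "angle_VnCnNn": _angle(Vn, Cn, Nn),
        "area_VMN": heron_area(V, M, N),
        "area_VXM": heron_area(V, X, M),
        "area_VCM": heron_area(V, C, M),
        "area_VnMnNn": heron_area(Vn, Mn, Nn),
        "area_VnXnMn": heron_area(Vn, Xn, Mn),
        "area_VnCnMn": heron_area(Vn, Cn, Mn),
    }
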