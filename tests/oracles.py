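"""Independent brute-force oracles used by the test suite.

Everything here is a deliberate, literal re-derivation kept separate from
the package's code paths: plain loops, math.sqrt/atan2, and a hard-coded
copy of every endpoint definition.
"""

import math

import numpy as np


def affine_oracle(m, point):
    """Explicit 2x3 affine product on a homogeneous column vector."""
    x, y = point
    return (
        m[0][0] * x + m[0][1] * y + m[0][2] * 1.0,
        m[1][0] * x + m[1][1] * y + m[1][2] * 1.0,
    )


def perimeter_oracle(points):
    """Pairwise edge sum, including the closing edge."""
    total = 0.0
    n = len(points)
    for i in range(n):
        ax, ay = points[i]
        bx, by = points[(i + 1) % n]
        total += math.sqrt((ax - bx) ** 2 + (ay - by) ** 2)
    return total


def metrics_oracle(tp, tn, fp, fn):
    """Literal re-evaluation of the seven statistics."""

    def div(a, b):
        return float("nan") if b == 0 else a / b

    return {
        "Acc": div(tp + tn, tp + tn + fp + fn),
        "Rec": div(tp, tp + fn),
        "Prec": div(tp, tp + fp),
        "F1s": div(2 * tp, 2 * tp + fp + fn),
        "TNR": div(tn, tn + fp),
        "FNR": div(fn, fn + tp),
        "FPR": div(fp, fp + tn),
    }


# --------------------------------------------------------------------------
# Literal transliteration of the feature table
# --------------------------------------------------------------------------

def _d(p, i, j):
    return math.sqrt((p[i][0] - p[j][0]) ** 2 + (p[i][1] - p[j][1]) ** 2)


def _incl(p, i, j):
    ang = math.degrees(math.atan2(p[j][1] - p[i][1], p[j][0] - p[i][0]))
    while ang > 90.0:
        ang -= 180.0
    while ang <= -90.0:
        ang += 180.0
    return abs(ang)


def _slope(p, i, j):
    return (p[i][1] - p[j][1]) / (p[i][0] - p[j][0])


def _perim(p, idx):
    return perimeter_oracle([p[i] for i in idx])


def _mx(a, b):
    return max(a / b, b / a)


def feature_oracle(points):
    """All 29 features recomputed with hard-coded endpoints, no shared code."""
    p = np.asarray(points, dtype=float)

    A = _d(p, 10, 19)
    Bl, Br = _d(p, 10, 13), _d(p, 16, 19)
    C = _d(p, 13, 16)
    D, E = _d(p, 11, 15), _d(p, 18, 20)
    F, G = _d(p, 23, 28), _d(p, 27, 34)
    H, I = _d(p, 0, 4), _d(p, 5, 9)
    J, K = _d(p, 2, 28), _d(p, 7, 34)
    Nl, Nr = _d(p, 0, 10), _d(p, 4, 13)
    Ol, Or = _d(p, 5, 16), _d(p, 9, 19)
    Pl, Pu = _d(p, 28, 37), _d(p, 28, 31)
    Ql, Qu = _d(p, 34, 37), _d(p, 31, 34)
    R, S = _d(p, 10, 22), _d(p, 19, 22)
    T, U = _d(p, 10, 25), _d(p, 19, 25)
    Vl, Vr = _d(p, 10, 28), _d(p, 19, 34)
    W = _d(p, 28, 34)
    X = _d(p, 22, 25)
    y_ref = (p[10][1] + p[19][1]) / 2.0
    L = sum(y_ref - p[i][1] for i in range(0, 5)) / 5.0
    M = sum(y_ref - p[i][1] for i in range(5, 10)) / 5.0
    Wl = _perim(p, [28, 29, 30, 31, 37, 38, 39])
    Wr = _perim(p, [31, 32, 33, 34, 35, 36, 37])
    N = (Nl + Nr) / 2.0
    O = (Ol + Or) / 2.0

    return [
        _incl(p, 0, 9),
        _incl(p, 2, 7),
        _incl(p, 4, 5),
        _mx(L, M),
        _slope(p, 0, 9),
        _slope(p, 2, 7),
        _slope(p, 4, 5),
        _incl(p, 10, 19),
        _mx(Bl, Br),
        _mx(D, E),
        _mx(H, I),
        _mx(N, O),
        _mx(Nl, Or),
        _mx(Nr, Ol),
        _incl(p, 28, 34),
        _mx(F, G),
        _mx(Pl, Ql),
        _mx(Pu, Qu),
        max(Vl / A, Vr / A),
        max(Pl / W, Ql / W),
        max(Pu / W, Qu / W),
        max(Wl / W, Wr / W),
        _incl(p, 23, 27),
        _incl(p, 22, 37),
        _mx(J, K),
        max(T / A, U / A),
        max(R / A, S / A),
        C / A,
        X / A,
    ]
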