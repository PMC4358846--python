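"""Literal loop-based reference implementation of the fluctuation pipeline.

Deliberately naive: explicit Python loops, explicit normal equations and
explicit moment sums, mirroring the published formulas step by step.  It
serves as the independent oracle for the vectorized production code and
must never import from it.
"""

import math

import numpy as np


def naive_origins(M, N, s, corner):
    Ms, Ns = M // s, N // s
    row_off = (M - Ms * s) if corner in ("BL", "BR") else 0
    col_off = (N - Ns * s) if corner in ("TR", "BR") else 0
    origins = []
    for m in range(Ms):
        for n in range(Ns):
            origins.append((row_off + m * s, col_off + n * s))
    return origins


def naive_cumsum(seg):
    s = len(seg)
    G = [[0.0] * s for _ in range(s)]
    for i in range(s):
        for j in range(s):
            total = 0.0
            for k1 in range(i + 1):
                for k2 in range(j + 1):
                    total += seg[k1][k2]
            G[i][j] = total
    return G


def naive_plane_fit(G):
    """Least-squares plane a*i + b*j + c via explicit normal equations."""
    s = len(G)
    Sii = Sjj = Sij = Si = Sj = S1 = 0.0
    Sgi = Sgj = Sg = 0.0
    for i0 in range(s):
        for j0 in range(s):
            i, j = i0 + 1, j0 + 1
            g = G[i0][j0]
            Sii += i * i
            Sjj += j * j
            Sij += i * j
            Si += i
            Sj += j
            S1 += 1.0
            Sgi += g * i
            Sgj += g * j
            Sg += g
    A = np.array([[Sii, Sij, Si], [Sij, Sjj, Sj], [Si, Sj, S1]])
    rhs = np.array([Sgi, Sgj, Sg])
    a, b, c = np.linalg.solve(A, rhs)
    return a, b, c


def naive_segment_fluctuation(seg):
    s = len(seg)
    G = naive_cumsum(seg)
    a, b, c = naive_plane_fit(G)
    acc = 0.0
    for i0 in range(s):
        for j0 in range(s):
            y = G[i0][j0] - (a * (i0 + 1) + b * (j0 + 1) + c)
            acc += y * y
    return math.sqrt(acc / (s * s))


def naive_fluctuation_function(surface, s, q_values, corners=("TL", "TR", "BL", "BR")):
    """F_q(s) with segments pooled over the requested corner tilings."""
    X = [list(map(float, row)) for row in np.asarray(surface)]
    M, N = len(X), len(X[0])
    F = []
    for corner in corners:
        for (r, t) in naive_origins(M, N, s, corner):
            seg = [[X[r + i][t + j] for j in range(s)] for i in range(s)]
            F.append(naive_segment_fluctuation(seg))
    out = []
    for q in q_values:
        if abs(q) < 1e-9:
            out.append(math.exp(sum(math.log(f) for f in F) / len(F)))
        else:
            out.append((sum(f ** q for f in F) / len(F)) ** (1.0 / q))
    return out
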