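"""Independent brute-force oracle for the 18-component vector.

A literal, loop-by-loop transcription of the defining step-function and
moment formulas, written without numpy vectorisation and kept independent
of the package's implementation.  Used only by the tests.
"""

from __future__ import annotations

NUCS = ("A", "C", "G", "T")
PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


def ref_positions(seq: str) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {n: [] for n in NUCS}
    for i, ch in enumerate(seq, start=1):
        if ch in out:
            out[ch].append(i)
    return out


def ref_U(positions: list[int], N: int) -> list[float]:
    """Evaluate the step function site by site, straight from its cases."""
    p = [0] + list(positions)  # p[0] = 0 convention
    n = len(positions)
    U = []
    for i in range(1, N + 1):
        if n == 0:
            U.append(0.0)
            continue
        if i >= p[n]:  # tail block [p_n, N]
            U.append(p[n] / (N - (p[n] - 1)))
            continue
        value = 0.0
        for j in range(0, n):  # block [p_j, p_{j+1})
            if p[j] <= i < p[j + 1]:
                value = p[j] / (p[j + 1] - p[j])
                break
        U.append(value)
    return U


def ref_pcnv(seq: str) -> list[float]:
    """The 18 components via nested loops: counts, means, variances,
    covariances in the fixed layout order."""
    N = len(seq)
    pos = ref_positions(seq)
    U = {a: ref_U(pos[a], N) for a in NUCS}
    counts = {a: len(pos[a]) for a in NUCS}

    def mean(a: str) -> float:
        if counts[a] == 0:
            return 0.0
        total = 0.0
        for i in range(N):
            total += U[a][i]
        return total / counts[a]

    def ubar(a: str) -> float:
        total = 0.0
        for i in range(N):
            total += U[a][i]
        return total / N

    def cov(a: str, b: str) -> float:
        if counts[a] == 0 or counts[b] == 0:
            return 0.0
        ua, ub = ubar(a), ubar(b)
        total = 0.0
        for i in range(N):
            total += (U[a][i] - ua) * (U[b][i] - ub)
        return total / (counts[a] * counts[b])

    vec = [float(counts[a]) for a in NUCS]
    vec += [mean(a) for a in NUCS]
    vec += [cov(a, a) for a in NUCS]
    vec += [cov(a, b) for a, b in PAIRS]
    return vec
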