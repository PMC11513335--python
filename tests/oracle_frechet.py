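"""Independent discrete-Fréchet oracle: exhaustive coupling enumeration."""

from functools import lru_cache


@lru_cache(maxsize=None)
def monotone_couplings(n: int, m: int):
    """All monotone couplings of curves with n and m points.

    A coupling starts at (0, 0), ends at (n-1, m-1) and advances one step in
    either or both indices; returned as tuples of (i, j) pairs.
    """
    if n == 1 and m == 1:
        return ((((0, 0)),),)
    out = []

    def extend(path):
        i, j = path[-1]
        if i == n - 1 and j == m - 1:
            out.append(tuple(path))
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                extend(path + [(ni, nj)])

    extend([(0, 0)])
    return tuple(out)


def oracle_frechet(P, Q, window) -> float:
    """min over all monotone couplings of the max point cost.

    ``window(t1, t2)`` returns the admissible time difference for a pair;
    pairs with |t1 - t2| > window are forbidden (+inf cost).
    """
    best = float("inf")
    for path in monotone_couplings(len(P), len(Q)):
        worst = 0.0
        for i, j in path:
            (t1, v1), (t2, v2) = P[i], Q[j]
            c = abs(v1 - v2) if abs(t1 - t2) <= window(t1, t2) else float("inf")
            if c > worst:
                worst = c
            if worst >= best:
                break
        if worst < best:
            best = worst
    return best
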