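"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: the path enumerator walks
every monotone move sequence recursively, and the Gotoh aligner is the
textbook three-matrix formulation with full matrices and no traceback.
"""

from functools import lru_cache


def enumerate_best_score(ref, track, query, profile):
    """Optimal semi-global score by enumerating monotone alignment paths.

    Paths start anywhere on the first row/column for free and end in the
    last reference column; gap runs pay open at their first step and ext on
    continuations, with per-reference-column feature-class parameters.
    Feasible for sequences up to ~10 bp.
    """
    n, m = len(ref), len(query)
    match, mis = profile.match, profile.mismatch
    go, ge = profile.gap_open, profile.gap_ext

    @lru_cache(maxsize=None)
    def best(i, j, last):
        # best score of any path ending at cell (i, j) whose final move is
        # `last` ('' = the free start, 'M' diagonal, 'D' ref-consuming,
        # 'I' query-consuming)
        cands = []
        if last == "" and (i == 0 or j == 0):
            cands.append(0)
        if last == "M" and i > 0 and j > 0:
            c = int(track[j - 1])
            w = match[c] if ref[j - 1] == query[i - 1] else mis[c]
            cands += [best(i - 1, j - 1, p) + w for p in ("", "M", "D", "I")]
        if last == "D" and j > 0:
            c = int(track[j - 1])
            cands.append(best(i, j - 1, "D") - ge[c])
            cands += [best(i, j - 1, p) - go[c] for p in ("", "M", "I")]
        if last == "I" and i > 0 and j > 0:
            c = int(track[j - 1])
            cands.append(best(i - 1, j, "I") - ge[c])
            cands += [best(i - 1, j, p) - go[c] for p in ("", "M", "D")]
        return max(cands) if cands else -(10**9)

    return max(
        best(i, n, last) for i in range(m + 1) for last in ("", "M", "D", "I")
    )


def gotoh_semiglobal_score(ref, query, match, mismatch, gap_open, gap_ext):
    """Textbook three-matrix affine-gap aligner, uniform scoring.

    Semi-global boundary rules: H zero on the first row and column, optimum
    taken over the last reference column.
    """
    n, m = len(ref), len(query)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_ext, H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_ext, H[i - 1][j] - gap_open)
            w = match if ref[j - 1] == query[i - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + w, E[i][j], F[i][j])
    return max(H[i][n] for i in range(m + 1))


def admissible_random_profile(rng):
    """A random per-class profile satisfying the scoring-sign contract."""
    from zebralift.zdp import ScoringProfile

    match = tuple(int(rng.integers(1, 20)) for _ in range(5))
    mismatch = tuple(-int(rng.integers(0, 20)) for _ in range(5))
    opens = [int(rng.integers(0, 30)) for _ in range(5)]
    exts = [int(rng.integers(0, o + 1)) for o in opens]
    # keep the weighting-order invariant so no warning fires
    opens[3] = opens[4] = max(opens) + 5
    exts[3] = exts[4] = opens[3]
    opens[2] = max(opens[2], opens[1], opens[0])
    exts[2] = min(max(exts[2], exts[1]), opens[2])
    return ScoringProfile(match, mismatch, tuple(opens), tuple(exts))
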