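"""Independent reference implementations (oracles) used by the tests.

These deliberately take a different route from the package: regex-based
site enumeration, substring-enumeration motif matching, and plain
quadratic dynamic programming for alignments.
"""

import re

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

MAX_SPAN = 40


def oracle_sites(residues: str):
    """Independent site oracle: regex non-overlapping left-greedy dibasic
    pairs within basic runs, plus fully isolated monobasic R."""
    sites = []
    for m in re.finditer(r"KR|RR", residues):
        # regex finditer is left-greedy and non-overlapping, matching the
        # stated resolution of overlapping dibasic runs
        sites.append((m.start(), m.end(), m.group()))
    for m in re.finditer(r"(?<![KR])R(?![KR])", residues):
        sites.append((m.start(), m.end(), "R"))
    sites.sort()
    return [
        (start, end, kind, start > 0 and residues[start - 1] == "G")
        for start, end, kind in sites
    ]


def lcs_len(a: str, b: str) -> int:
    """Quadratic DP longest-common-subsequence reference."""
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i][j] = (
                dp[i - 1][j - 1] + 1
                if a[i - 1] == b[j - 1]
                else max(dp[i - 1][j], dp[i][j - 1])
            )
    return dp[-1][-1]


def brute_force_scan(pattern: str, residues: str, max_len: int = MAX_SPAN):
    """Oracle: test every substring against the pattern."""
    compiled = re.compile(pattern)
    hits = []
    for start in range(len(residues)):
        for end in range(start + 1, min(len(residues), start + max_len) + 1):
            if compiled.fullmatch(residues[start:end]):
                hits.append((start, end))
    return hits


def sw_reference(a: str, b: str, open_cost: int = 11, extend_cost: int = 1) -> float:
    """Quadratic affine-gap Smith-Waterman reference (a length-k gap
    costs open_cost + k*extend_cost, the BLAST convention)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost - extend_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost - extend_cost, F[i - 1][j] - extend_cost)
            sub = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
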