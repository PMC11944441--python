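"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles, separately from the
library code paths it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Full O(nm) affine-gap Smith-Waterman optimum (three-matrix Gotoh).

    A gap of length L costs gap_open + L * gap_extend, matching the BLAST
    penalty convention.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (moving along b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (moving along a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def scan_standard(sequences: list[str], alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> int:
    """Count sequences whose every character is in the given alphabet."""
    ok = 0
    for seq in sequences:
        if all(c in alphabet for c in seq.upper()):
            ok += 1
    return ok


def equal_pair_count(sequences: list[str], include_self: bool = True) -> int:
    """Ordered pairs (i, j) with identical sequences, exhaustively compared."""
    n = 0
    for i, a in enumerate(sequences):
        for j, b in enumerate(sequences):
            if i == j and not include_self:
                continue
            if a == b:
                n += 1
    return n


def flood_fill_components(
    nodes: list[str], edges: list[tuple[str, str]]
) -> list[frozenset[str]]:
    """Connected components by explicit breadth-first flood fill."""
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen: set[str] = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        queue = [start]
        members = set()
        while queue:
            node = queue.pop()
            if node in members:
                continue
            members.add(node)
            queue.extend(adjacency[node] - members)
        seen |= members
        components.append(frozenset(members))
    return components


def histogram_tally(pidents: list[float], bin_width: float) -> list[int]:
    """Direct per-value binning with the last bin closed at 100."""
    n_bins = int(round(100.0 / bin_width))
    counts = [0] * n_bins
    for p in pidents:
        idx = int(p // bin_width)
        if idx >= n_bins:
            idx = n_bins - 1
        counts[idx] += 1
    return counts


def cleavage_sites_by_scan(sequence: str, p1: str, blocked_p1_prime: str = "") -> list[int]:
    """Position-by-position application of a P1/P1' rule."""
    out = []
    for p in range(1, len(sequence)):
        if sequence[p - 1] in p1 and (
            not blocked_p1_prime or sequence[p] not in blocked_p1_prime
        ):
            out.append(p)
    return out
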