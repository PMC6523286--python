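"""Independent brute-force oracles used by the test suite.

Each oracle is written against first principles (exact rational
arithmetic, exhaustive enumeration) and shares no code path with the
implementation it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


# ---------------------------------------------------------------------------
# Fisher's exact test: exact rational enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided exact P as an exact rational.

    Enumerates every 2x2 table with the observed margins and sums the
    hypergeometric point probabilities that are <= the observed table's
    (exact comparison, ties included).
    """
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, k)
    obs = Fraction(comb(n1, a) * comb(n2, c), denom)
    total = Fraction(0)
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = Fraction(comb(n1, x) * comb(n2, k - x), denom)
        if p <= obs:
            total += p
    return min(total, Fraction(1))


# ---------------------------------------------------------------------------
# global affine-gap alignment: exhaustive search
# ---------------------------------------------------------------------------

def best_global_score(
    a: str, b: str,
    match: float = 1.0, mismatch: float = -1.0,
    gap_open: float = -5.0, gap_extend: float = -1.0,
) -> float:
    """Optimal global alignment score by exhaustive recursion.

    Explores every alignment path (diagonal / gap-in-a / gap-in-b) with
    affine gap costs: a length-L gap scores gap_open + gap_extend*(L-1).
    Exponential; only for short sequences.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b (delete from a)
            g = gap_extend if last == "D" else gap_open
            best = max(best, g + rec(i + 1, j, "D"))
        if j < len(b):  # gap in a (insert from b)
            g = gap_extend if last == "I" else gap_open
            best = max(best, g + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "M")


# ---------------------------------------------------------------------------
# Dollo parsimony: enumeration over gain edge x loss subsets
# ---------------------------------------------------------------------------

def dollo_min_events(tree, profile: dict[str, str], allow_loss: bool = True):
    """Minimum Dollo event count by exhaustive enumeration.

    ``tree`` is a :class:`shadowy.phylo.SpeciesTree` (used only for its
    branch/tip structure).  Tries every gain branch and, if losses are
    allowed, every subset of branches strictly below it; a candidate is
    feasible when the implied tip states match the profile's known
    (present/absent) tips.  ``present_independent`` tips are forced gains
    on their own terminal branches; ``unknown`` tips are unconstrained.
    Returns the minimal total event count, or ``None`` if infeasible.
    """
    present = {t for t, s in profile.items() if s == "present"}
    absent = {t for t, s in profile.items() if s == "absent"}
    indep = [t for t, s in profile.items() if s == "present_independent"]
    base = len(indep)
    if not present:
        return base
    branch_tips = {bid: set(bid.split(",")) for bid in tree.branch_ids}
    best = None
    for gid, gtips in branch_tips.items():
        below = [b for b, t in branch_tips.items() if t < gtips]
        max_losses = len(below) if allow_loss else 0
        for r in range(max_losses + 1):
            for lost in combinations(below, r):
                carried = set(gtips)
                for lid in lost:
                    carried -= branch_tips[lid]
                if present <= carried and not (absent & carried):
                    events = base + 1 + r
                    if best is None or events < best:
                        best = events
    return best
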