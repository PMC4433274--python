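"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration or position-by-position
scanning) and shares no code path with the implementation it checks.
"""

from functools import lru_cache

from mirpipe.candidates import PAIR_WEIGHTS

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def naive_reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_best_fold(seq: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over ALL nested structures, by explicit
    enumeration.  Exponential; only for short sequences."""

    @lru_cache(maxsize=None)
    def structures(i: int, j: int):
        if j - i < min_loop + 1:
            return [frozenset()]
        out = list(structures(i, j - 1))
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in PAIR_WEIGHTS:
                lefts = structures(i, k - 1) if k > i else [frozenset()]
                for s1 in lefts:
                    for s2 in structures(k + 1, j - 1):
                        out.append(s1 | s2 | {(k, j)})
        return out

    best = 0
    for st in structures(0, len(seq) - 1):
        best = max(best, sum(PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in st))
    return best


def naive_substring_hits(query: str, genome: dict[str, str]) -> set[tuple]:
    """All (chrom, start, end, strand) exact occurrences by per-position
    character comparison on both strands."""
    hits = set()
    rc = naive_reverse_complement(query)
    for chrom, text in genome.items():
        for probe, strand in ((query, "+"), (rc, "-")):
            m = len(probe)
            for start in range(len(text) - m + 1):
                if all(text[start + k] == probe[k] for k in range(m)):
                    hits.add((chrom, start, start + m, strand))
    return hits


def naive_seed_sites(seed: str, utrs: dict[str, str]) -> set[tuple]:
    """(gene, offset) of every seed-complement occurrence by naive scan."""
    site = naive_reverse_complement(seed)
    out = set()
    for gene, utr in utrs.items():
        for start in range(len(utr) - len(site) + 1):
            if utr[start:start + len(site)] == site:
                out.add((gene, start))
    return out


def transitive_closure_clusters(loci, gap: int) -> set[frozenset]:
    """Connected components of the <=gap proximity graph; singletons
    dropped.  ``loci`` is a list of (name, interval)."""
    n = len(loci)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = loci[i][1], loci[j][1]
            if a.chrom != b.chrom:
                continue
            lo, hi = sorted((a, b), key=lambda iv: iv.start)
            if max(0, hi.start - lo.end) <= gap:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    comps = set()
    for i in range(n):
        if i in seen:
            continue
        comp, stack = set(), [i]
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.add(frozenset(loci[k][0] for k in comp))
    return comps


def max_matches_by_enumeration(a: str, b: str) -> int:
    """Maximum identical aligned positions over all global alignments with
    free gaps, by plain recursion (no memoization)."""
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        best = max(rec(i + 1, j), rec(i, j + 1))
        best = max(best, rec(i + 1, j + 1) + (a[i] == b[j]))
        return best

    return rec(0, 0)
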