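"""Independent from-the-definition reference implementations.

These deliberately avoid the library code paths (and the libraries they
delegate to) so tests can compare the package against a second route:
exact combinatorics for the hypergeometric tail, literal step-up/step-down
multiple-testing definitions, a double-loop induced subgraph, and the 2x2
contingency form of Cohen's kappa.
"""

from fractions import Fraction
from math import comb


def hypergeom_sf_exact(k, n_pop, n_succ, n_draw) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact counting."""
    total = comb(n_pop, n_draw)
    acc = Fraction(0)
    for i in range(max(k, 0), min(n_succ, n_draw) + 1):
        acc += Fraction(comb(n_succ, i) * comb(n_pop - n_succ, n_draw - i), total)
    return acc


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adj[i] = running_min
    return [min(1.0, a) for a in adj]


def holm_adjust(pvalues):
    """Holm (Bonferroni step-down) from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order, start=1):
        running_max = max(running_max, (m - rank + 1) * pvalues[i])
        adj[i] = min(1.0, running_max)
    return adj


def induced_edges(seed_genes, edges):
    """Brute-force double loop over the edge list."""
    out = set()
    for a, b in edges:
        if a != b and a in seed_genes and b in seed_genes:
            out.add((min(a, b), max(a, b)))
    return sorted(out)


def cohen_kappa(vec_a, vec_b) -> float:
    """Cohen's kappa of two equal-length binary vectors via the 2x2 table."""
    n = len(vec_a)
    n11 = sum(1 for x, y in zip(vec_a, vec_b) if x and y)
    n00 = sum(1 for x, y in zip(vec_a, vec_b) if not x and not y)
    r_a = sum(vec_a)
    r_b = sum(vec_b)
    p_o = (n11 + n00) / n
    p_e = (r_a * r_b + (n - r_a) * (n - r_b)) / n**2
    if p_e == 1.0:
        return 1.0 if list(vec_a) == list(vec_b) else 0.0
    return (p_o - p_e) / (1.0 - p_e)
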