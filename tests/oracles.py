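"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (direct enumeration, hand
formulas) so it stays independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def km_product_limit(times, events):
    """Hand product-limit estimator: [(event_time, S(t), n_at_risk), ...]."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = []
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= 1.0 - d / n_at_risk
        out.append((float(t), s, n_at_risk))
    return out


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Hand O/E/V log-rank tabulation: chi2 = (sum O - sum E)^2 / sum V."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, dtype=bool),
                           np.zeros(tb.size, dtype=bool)])
    obs = exp = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n1 = int((at_risk & in_a).sum())
        n2 = int((at_risk & ~in_a).sum())
        n = n1 + n2
        d1 = int(((times == t) & events & in_a).sum())
        d = int(((times == t) & events).sum())
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:  # arms never simultaneously at risk at an event time
        return float("nan")
    return (obs - exp) ** 2 / var


def bh_stepup(p_values) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def naive_sign_lists(rho_by_gene: dict[str, list[float]], min_support: int):
    """Direct enumeration of the sign-consistency filter.

    ``rho_by_gene`` maps gene -> list of per-dataset rho values (one entry per
    dataset where the gene is measured). Mirrors the contract: a gene joins
    the positive list iff rho > 0 in >= min_support measured datasets, never
    joins both lists (larger count wins, exact ties excluded).
    """
    pos, neg = [], []
    for gene, rhos in rho_by_gene.items():
        n_pos = sum(1 for r in rhos if r > 0)
        n_neg = sum(1 for r in rhos if r < 0)
        p_ok, n_ok = n_pos >= min_support, n_neg >= min_support
        if p_ok and n_ok:
            if n_pos > n_neg:
                pos.append(gene)
            elif n_neg > n_pos:
                neg.append(gene)
        elif p_ok:
            pos.append(gene)
        elif n_ok:
            neg.append(gene)
    return sorted(pos), sorted(neg)


def exact_subset_counts(gene_lists: dict[str, set], min_degree: int = 1):
    """Exhaustive set-algebra oracle for UpSet-style exact intersection counts.

    Returns {frozenset(dataset ids): count of genes in exactly those sets}.
    """
    import itertools

    ids = sorted(gene_lists)
    counts = {}
    for degree in range(min_degree, len(ids) + 1):
        for subset in itertools.combinations(ids, degree):
            inside = set.intersection(*(gene_lists[d] for d in subset))
            for d in ids:
                if d not in subset:
                    inside -= gene_lists[d]
            if inside:
                counts[frozenset(subset)] = len(inside)
    return counts
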