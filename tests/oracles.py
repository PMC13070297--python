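"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores come
from exhaustive path enumeration, domain overlap from a naive nested scan,
Δ oxidation from all pairwise mean differences, and 4PL objectives from a
dense grid search (linear in bottom/top at fixed ec50/hill).
"""

from __future__ import annotations

import numpy as np


def brute_force_align_score(sa: str, sb: str, subst, gap_open: float, gap_extend: float) -> float:
    """Maximum global-alignment score by exhaustive enumeration.

    Walks every monotone path through the edit graph, scoring affine gaps as
    gap_open for the first gapped residue and gap_extend for each extension
    (same convention as the dynamic program under test).  Exponential; only
    for short sequences.
    """
    n, m = len(sa), len(sb)
    best = [-np.inf]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            rec(i + 1, j + 1, score + subst[sa[i], sb[j]], "M")
        if i < n:  # gap in b
            pen = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, score - pen, "X")
        if j < m:  # gap in a
            pen = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, score - pen, "Y")

    rec(0, 0, 0.0, "")
    return float(best[0])


def naive_domain_scan(positions, intervals) -> list[bool]:
    """Per-position in-domain flag by scanning every interval (O(N*M))."""
    ivals = [
        (row["protein"], int(row["start"]), int(row["end"]))
        for _, row in intervals.iterrows()
    ]
    out = []
    for _, row in positions.iterrows():
        hit = False
        for prot, start, end in ivals:
            if prot == row["protein"] and start <= row["position"] <= end:
                hit = True
                break
        out.append(hit)
    return out


def pairwise_delta(means: np.ndarray) -> float:
    """Max over all pairwise |mean differences| — equals max-min."""
    best = 0.0
    for i in range(len(means)):
        for j in range(len(means)):
            d = abs(means[i] - means[j])
            if d > best:
                best = d
    return best


def grid_4pl_objective(dose, response, direction="activation", n_ec50=120, n_hill=60):
    """Best residual sum of squares over a dense (ec50, hill) grid.

    At fixed (ec50, hill) the 4PL is linear in (bottom, top); the inner
    problem is solved exactly by linear least squares, making the grid an
    independent near-global oracle for the fitted objective.
    """
    dose = np.asarray(dose, float)
    response = np.asarray(response, float)
    log_ec50s = np.linspace(np.log10(dose.min()) - 1, np.log10(dose.max()) + 1, n_ec50)
    hills = np.linspace(0.2, 5.0, n_hill)
    best = np.inf
    for le in log_ec50s:
        for h in hills:
            if direction == "activation":
                w = 1.0 / (1.0 + 10.0 ** ((le - np.log10(dose)) * h))
            else:
                w = 1.0 / (1.0 + 10.0 ** ((np.log10(dose) - le) * h))
            A = np.column_stack([1.0 - w, w])  # y = bottom*(1-w) + top*w
            coef, _, _, _ = np.linalg.lstsq(A, response, rcond=None)
            rss = float(np.sum((A @ coef - response) ** 2))
            if rss < best:
                best = rss
    return best
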