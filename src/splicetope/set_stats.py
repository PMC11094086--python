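"""Gene-set overlap and location-shift statistics.

Overlap significance is the upper-tail hypergeometric probability of
observing at least the measured intersection when |A| and |B| genes are
drawn from a declared universe. The universe must be passed explicitly —
overlap p-values are meaningless without one (typically: all genes testable
in both experiments).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSetOverlap:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_size: int
    p_value: float


def hypergeometric_overlap(set_a, set_b, universe, tail: str = "enrichment") -> GeneSetOverlap:
    """Hypergeometric overlap test between two gene sets.

    ``tail='enrichment'`` (default) gives P(X >= overlap); ``'depletion'``
    gives P(X <= overlap). Elements outside the universe raise ValueError.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    for name, s in (("A", A), ("B", B)):
        stray = s - U
        if stray:
            raise ValueError(
                f"set {name} contains elements outside the universe: "
                f"{sorted(stray)[:5]}"
            )
    k = len(A & B)
    M, nA, nB = len(U), len(A), len(B)
    if tail == "enrichment":
        p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    elif tail == "depletion":
        p = float(stats.hypergeom.cdf(k, M, nA, nB))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return GeneSetOverlap(nA, nB, M, k, p)


def foreground_background_shift(fg_values, bg_values, test: str = "t"):
    """Two-sided location-shift test of foreground vs background values.

    Returns ``(location_fg, location_bg, direction, p)`` where location is
    the mean (t-test) or median (Mann-Whitney) and direction = fg - bg.
    """
    fg = np.asarray(list(fg_values), dtype=float)
    bg = np.asarray(list(bg_values), dtype=float)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "t":
        loc_fg, loc_bg = float(fg.mean()), float(bg.mean())
        stat, p = stats.ttest_ind(fg, bg)
        if np.isnan(p):  # zero pooled variance
            p = 1.0 if loc_fg == loc_bg else 0.0
    elif test == "mann_whitney":
        loc_fg, loc_bg = float(np.median(fg)), float(np.median(bg))
        if np.ptp(np.concatenate([fg, bg])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(fg, bg, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return loc_fg, loc_bg, loc_fg - loc_bg, float(p)


def multiset_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive-region counts of a Venn decomposition.

    Every non-empty membership pattern over the named sets is one region;
    region counts partition the union. Returns columns ``region`` (sorted
    '+'-joined member names) and ``count``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    regions: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = 0
    for element in set().union(*sets.values()):
        membership = tuple(n for n in names if element in sets[n])
        regions[membership] += 1
    return pd.DataFrame(
        [{"region": "+".join(k), "count": v} for k, v in regions.items()]
    )


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_overlap_report(overlaps: dict[str, GeneSetOverlap], path) -> None:
    rows = [
        {"comparison": name, "set_a": o.set_a_size, "set_b": o.set_b_size,
         "universe": o.universe_size, "overlap": o.overlap_size, "p_value": o.p_value}
        for name, o in overlaps.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
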