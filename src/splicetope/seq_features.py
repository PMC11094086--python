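"""Sequence features of regulated exons/introns and group comparisons.

For skipped-exon events: cassette exon length and GC content, upstream
intron length, and the distance from the predicted branch-point adenosine
to the 3' splice site. For retained introns: intron length and GC content.
Groups (UP = increased inclusion/retention, DOWN = decreased, NO =
unregulated background) are compared feature-by-feature with a two-sided
Mann-Whitney U test (exact enumeration for small samples).

Branch points are called with a transparent consensus position-weight
model of the yUnAy branch-point heptamer (branch A at the centre), scored
over adenosines 15-100 nt upstream of the intron's 3' end. The PWM ships
as a versioned fixture (``data/branch_point_pwm.tsv``) and is pluggable.
Distance convention: the number of intron bases strictly between the
branch adenosine and the final intron base.
"""
from __future__ import annotations

import math
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._pwm import encode, load_pwm, log_odds
from ._seq import fetch, gc_content
from .splice_events import ri_intron_interval, se_upstream_intron

BP_SEARCH_WINDOW = (15, 100)  # distance range scanned upstream of the 3'ss


def load_branch_point_pwm() -> np.ndarray:
    with resources.as_file(
        resources.files("splicetope").joinpath("data/branch_point_pwm.tsv")
    ) as p:
        return load_pwm(p)


def find_branch_point(
    intron_seq: str,
    pwm: np.ndarray | None = None,
    window: tuple[int, int] = BP_SEARCH_WINDOW,
):
    """Best-scoring branch-point adenosine in the 3' region of an intron.

    ``intron_seq`` is the intron 5'->3' in transcript orientation. Scans
    every A whose distance to the 3' splice site lies within ``window``,
    scoring the 7-mer centred on it against the branch-point PWM. Returns
    ``(position, distance)`` — position is the 0-based index of the A in the
    intron, distance the number of bases strictly between the A and the
    last intron base — or ``None`` when no adenosine is scorable (intron
    too short, or no A in the window).
    """
    if pwm is None:
        pwm = load_branch_point_pwm()
    L = len(intron_seq)
    half = pwm.shape[0] // 2
    lo = log_odds(pwm)
    codes = encode(intron_seq)
    best = None  # (score, position)
    for i, c in enumerate(intron_seq.upper()):
        if c != "A":
            continue
        dist = L - 1 - i
        if not window[0] <= dist <= window[1]:
            continue
        if i - half < 0 or i + half >= L:
            continue
        score = float(lo[np.arange(pwm.shape[0]), codes[i - half : i + half + 1]].sum()) \
            if (codes[i - half : i + half + 1] >= 0).all() else -math.inf
        # ties resolved toward the 3'ss (larger i)
        if best is None or score > best[0] or (score == best[0] and i > best[1]):
            best = (score, i)
    if best is None:
        return None
    pos = best[1]
    return pos, L - 1 - pos


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def extract_features(
    events: pd.DataFrame, genome, pwm: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-event feature table for SE and RI events.

    ``events`` needs rMATS-style coordinates, ``strand``, ``event_type``
    and a ``group`` column (UP/DOWN/NO). GC content is computed on the
    annotated strand (it is strand-invariant); intron sequences are taken
    in transcript orientation for branch-point calling.
    """
    if pwm is None:
        pwm = load_branch_point_pwm()
    rows = []
    for _, ev in events.iterrows():
        chrom, strand = ev["chr"], ev["strand"]
        rec = {
            "event_id": ev.get("event_id", ""),
            "event_type": ev["event_type"],
            "group": ev.get("group", ev.get("direction", "NO")),
            "exon_length": np.nan,
            "upstream_intron_length": np.nan,
            "intron_length": np.nan,
            "gc_content": np.nan,
            "bp_to_3ss_distance": np.nan,
            "bp_genomic_pos": np.nan,
            "chrom": chrom,
        }
        if ev["event_type"] == "SE":
            s, e = int(ev["exonStart_0base"]), int(ev["exonEnd"])
            rec["exon_length"] = e - s
            rec["gc_content"] = gc_content(fetch(genome, chrom, s, e, "+"))
            us, ue = se_upstream_intron(ev)
            rec["upstream_intron_length"] = ue - us
            intron_seq = fetch(genome, chrom, us, ue, strand)
            bp = find_branch_point(intron_seq, pwm)
            if bp is not None:
                pos, dist = bp
                rec["bp_to_3ss_distance"] = dist
                rec["bp_genomic_pos"] = us + pos if strand == "+" else ue - 1 - pos
        elif ev["event_type"] == "RI":
            s, e = ri_intron_interval(ev)
            rec["intron_length"] = e - s
            rec["gc_content"] = gc_content(fetch(genome, chrom, s, e, "+"))
            intron_seq = fetch(genome, chrom, s, e, strand)
            bp = find_branch_point(intron_seq, pwm)
            if bp is not None:
                pos, dist = bp
                rec["bp_to_3ss_distance"] = dist
                rec["bp_genomic_pos"] = s + pos if strand == "+" else e - 1 - pos
        else:
            continue  # features defined for SE and RI only
        rows.append(rec)
    return pd.DataFrame(rows)


def write_branch_point_bed(features: pd.DataFrame, path) -> None:
    """Branch-point calls as BED (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for _, row in features.dropna(subset=["bp_genomic_pos"]).iterrows():
            pos = int(row["bp_genomic_pos"])
            fh.write(
                f"{row['chrom']}\t{pos}\t{pos + 1}\t{row['event_id']}\t"
                f"{int(row['bp_to_3ss_distance'])}\t.\n"
            )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return r1 - len(a) * (len(a) + 1) / 2.0


def compare_groups(values_a, values_b, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U comparison of two feature distributions.

    Returns ``(median_a, median_b, U, p)``. When both groups have at most
    ``exact_max_n`` observations the null distribution of U is enumerated
    exhaustively over all label assignments (valid under ties); otherwise
    the tie-corrected normal approximation with continuity correction is
    used.
    """
    a = np.asarray([v for v in values_a if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    b = np.asarray([v for v in values_b if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    u_obs = _u_statistic(a, b)
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        # midranks are invariant under label permutation, so the exact null
        # distribution of U is the distribution of subset rank sums
        pooled = np.concatenate([a, b])
        n1 = len(a)
        ranks = stats.rankdata(pooled)
        idx = np.array(list(combinations(range(len(pooled)), n1)))
        us = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        tol = 1e-9
        p_low = float((us <= u_obs + tol).mean())
        p_high = float((us >= u_obs - tol).mean())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
    return med_a, med_b, float(u_obs), p


def compare_feature_table(
    features: pd.DataFrame,
    feature_cols=("exon_length", "upstream_intron_length", "intron_length",
                  "gc_content", "bp_to_3ss_distance"),
    group_pairs=(("UP", "NO"), ("DOWN", "NO"), ("UP", "DOWN")),
) -> pd.DataFrame:
    """All pairwise group comparisons over the feature columns."""
    rows = []
    for col in feature_cols:
        for ga, gb in group_pairs:
            va = features.loc[features["group"] == ga, col].dropna()
            vb = features.loc[features["group"] == gb, col].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            med_a, med_b, u, p = compare_groups(va, vb)
            rows.append(
                {"feature": col, "group_a": ga, "group_b": gb,
                 "median_a": med_a, "median_b": med_b, "U": u, "p_value": p}
            )
    return pd.DataFrame(rows)
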