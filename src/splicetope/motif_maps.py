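"""Position-resolved RNA-binding-protein motif maps around cassette exons.

An RNA map asks where an RBP's binding motif sits relative to regulated
splice sites: for each position in fixed windows anchored at the four
boundaries of a cassette exon (3' end of the upstream intron, the exon's
5' and 3' edges, and the 5' start of the downstream intron), coverage is
the fraction of events in a group (UP / DOWN / NO) whose sequence has at
least one motif hit overlapping that position, smoothed with a running
mean. Motif hits are PWM log-odds matches against a uniform background;
the default threshold is 80% of the maximal attainable score.

Windows default to 300 nt into the flanking introns and 50 nt into the
exon, smoothing to 31 nt. Reverse-strand events contribute in transcript
orientation, so "upstream" always means 5' of the exon on the mRNA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pwm import encode, load_pwm, log_odds, validate_pwm
from ._seq import fetch, get_chrom_seq

logger = logging.getLogger(__name__)

ANCHORS = ("upstream_3ss", "exon_5p", "exon_3p", "downstream_5ss")


@dataclass
class MotifModel:
    """An RBP binding motif as a PWM over {A, C, G, U} with a hit threshold."""

    motif_id: str
    rbp_name: str
    pwm: np.ndarray
    threshold: float | None = None  # log-odds; None -> 80% of max score

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        validate_pwm(self.pwm)
        if not 5 <= self.pwm.shape[0] <= 12:
            raise ValueError("motif length must be 5-12")
        if self.threshold is None:
            self.threshold = 0.8 * self.max_score

    @property
    def max_score(self) -> float:
        return float(log_odds(self.pwm).max(axis=1).sum())

    @classmethod
    def from_file(cls, path, motif_id: str = "", rbp_name: str = "",
                  threshold: float | None = None) -> "MotifModel":
        return cls(motif_id or str(path), rbp_name, load_pwm(path), threshold)


def scan_motif(sequence: str, motif: MotifModel) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals where the log-odds score meets the
    threshold; overlapping hits allowed. Shorter-than-motif sequences yield
    an empty list."""
    L = motif.pwm.shape[0]
    n = len(sequence)
    if n < L:
        return []
    lo = log_odds(motif.pwm)
    codes = encode(sequence)
    # sliding-window sum of per-position log odds
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    per_pos = lo[np.tile(np.arange(L), (n - L + 1, 1)),
                 np.lib.stride_tricks.sliding_window_view(safe, L)]
    scores = per_pos.sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    hits = np.flatnonzero(ok & (scores >= motif.threshold))
    return [(int(i), int(i + L)) for i in hits]


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def _event_windows(ev, genome, flank: int, into_exon: int) -> dict[str, str] | None:
    """Anchor-window sequences in transcript orientation, or None when the
    event sits too close to a chromosome edge."""
    chrom, strand = ev["chr"], ev["strand"]
    s, e = int(ev["exonStart_0base"]), int(ev["exonEnd"])
    L = len(get_chrom_seq(genome, chrom))
    if s - flank < 0 or e + flank > L or e - s < into_exon:
        return None
    # genomic windows; transcript orientation decided by strand
    gwin = {
        "left_intron": (s - flank, s),
        "exon_left": (s, s + into_exon),
        "exon_right": (e - into_exon, e),
        "right_intron": (e, e + flank),
    }
    seqs = {k: fetch(genome, chrom, a, b, strand) for k, (a, b) in gwin.items()}
    if strand == "+":
        return {
            "upstream_3ss": seqs["left_intron"],
            "exon_5p": seqs["exon_left"],
            "exon_3p": seqs["exon_right"],
            "downstream_5ss": seqs["right_intron"],
        }
    return {
        "upstream_3ss": seqs["right_intron"],
        "exon_5p": seqs["exon_right"],
        "exon_3p": seqs["exon_left"],
        "downstream_5ss": seqs["left_intron"],
    }


def running_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centered running mean with edge windows shrunk to the available span."""
    if width <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


@dataclass
class RnaMap:
    """Motif coverage profiles for one event group.

    ``coverage[anchor]`` is the smoothed per-position hit fraction;
    ``raw_coverage`` the unsmoothed one; ``indicators[anchor]`` the
    underlying events x positions hit matrix used for permutation tests.
    """

    group: str
    n_events: int
    flank: int
    into_exon: int
    smooth: int
    coverage: dict[str, np.ndarray] = field(default_factory=dict)
    raw_coverage: dict[str, np.ndarray] = field(default_factory=dict)
    indicators: dict[str, np.ndarray] = field(default_factory=dict)


def build_rna_map(
    event_groups: dict[str, pd.DataFrame],
    genome,
    motif: MotifModel,
    flank: int = 300,
    into_exon: int = 50,
    smooth: int = 31,
) -> dict[str, RnaMap]:
    """RNA map per group around the four cassette-exon anchors.

    Coverage at a position is the fraction of the group's events with >= 1
    motif hit overlapping that position, then running-mean smoothed. Events
    too close to a chromosome edge are skipped with a warning.
    """
    out: dict[str, RnaMap] = {}
    for group, events in event_groups.items():
        if len(events) == 0:
            raise ValueError(f"group {group!r} is empty")
        per_anchor = {a: [] for a in ANCHORS}
        n_used = 0
        for _, ev in events.iterrows():
            windows = _event_windows(ev, genome, flank, into_exon)
            if windows is None:
                logger.warning(
                    "event %s too close to chromosome edge; skipped",
                    ev.get("event_id", "?"),
                )
                continue
            n_used += 1
            for anchor, seq in windows.items():
                ind = np.zeros(len(seq), dtype=bool)
                for h0, h1 in scan_motif(seq, motif):
                    ind[h0:h1] = True
                per_anchor[anchor].append(ind)
        if n_used == 0:
            raise ValueError(f"group {group!r}: no usable events")
        rmap = RnaMap(group=group, n_events=n_used, flank=flank,
                      into_exon=into_exon, smooth=smooth)
        for anchor, rows in per_anchor.items():
            mat = np.vstack(rows)
            raw = mat.mean(axis=0)
            rmap.indicators[anchor] = mat
            rmap.raw_coverage[anchor] = raw
            rmap.coverage[anchor] = running_mean(raw, smooth)
        out[group] = rmap
    return out


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def map_significance(
    map_a: RnaMap,
    map_b: RnaMap,
    n_permutations: int = 500,
    seed: int = 0,
    min_events: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-position permutation test of coverage difference between groups.

    Event-group labels are shuffled; at each position the p-value is the
    fraction of permutations whose absolute coverage difference reaches the
    observed one (add-one corrected), BH-adjusted across positions within
    each anchor. Returns per anchor a DataFrame (position, coverage_a,
    coverage_b, diff, p_value, q_value).
    """
    if map_a.n_events < min_events or map_b.n_events < min_events:
        raise ValueError(
            f"groups too small for a permutation test "
            f"({map_a.n_events} and {map_b.n_events} events; need >= {min_events})"
        )
    if map_a.flank != map_b.flank or map_a.into_exon != map_b.into_exon:
        raise ValueError("maps were built with different windows")
    rng = np.random.default_rng(seed)
    out = {}
    for anchor in ANCHORS:
        A = map_a.indicators[anchor].astype(float)
        B = map_b.indicators[anchor].astype(float)
        na = A.shape[0]
        pooled = np.vstack([A, B])
        obs = A.mean(axis=0) - B.mean(axis=0)
        exceed = np.ones(pooled.shape[1])
        for _ in range(n_permutations):
            perm = rng.permutation(pooled.shape[0])
            pa = pooled[perm[:na]].mean(axis=0)
            pb = pooled[perm[na:]].mean(axis=0)
            exceed += np.abs(pa - pb) >= np.abs(obs)
        p = exceed / (n_permutations + 1)
        q = _bh(p)
        out[anchor] = pd.DataFrame(
            {
                "position": np.arange(pooled.shape[1]),
                "coverage_a": A.mean(axis=0),
                "coverage_b": B.mean(axis=0),
                "diff": obs,
                "p_value": p,
                "q_value": q,
            }
        )
    return out


def write_rna_map_tsv(maps: dict[str, RnaMap], path) -> None:
    rows = []
    for group, rmap in maps.items():
        for anchor in ANCHORS:
            cov = rmap.coverage[anchor]
            raw = rmap.raw_coverage[anchor]
            for pos in range(len(cov)):
                rows.append(
                    {"group": group, "anchor": anchor, "position": pos,
                     "coverage": cov[pos], "raw_coverage": raw[pos]}
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_rna_map(maps: dict[str, RnaMap], path) -> None:
    """Optional rendering of the four anchor panels (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ANCHORS), figsize=(16, 3), sharey=True)
    for ax, anchor in zip(axes, ANCHORS):
        for group, rmap in maps.items():
            ax.plot(rmap.coverage[anchor], label=group)
        ax.set_title(anchor)
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("motif coverage")
    axes[-1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
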