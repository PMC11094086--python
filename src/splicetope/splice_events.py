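"""Alternative-splicing event tables: rMATS I/O, PSI, filters, skew tests.

Event tables are pandas DataFrames in the rMATS 4.1.2 "JC" dialect, one row
per event. Replicate junction counts are comma-separated in the file and
parsed to integer lists. PSI (percent spliced-in) per replicate is the
length-normalised inclusion fraction

    psi = (I/lI) / (I/lI + S/lS)

with I inclusion-junction reads, S skipping-junction reads and lI, lS the
effective inclusion/skipping form lengths; a replicate with I = S = 0 has
undefined PSI. Group PSI is the mean over defined replicates and
dPSI = psi_treated - psi_control.

Sign convention: rMATS reports IncLevelDifference = sample1 - sample2 and
never says which is treated. The caller declares it via ``treated_sample``;
the default (1) makes dPSI = IncLevelDifference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")

# rMATS 4.1.2 *.MATS.JC.txt headers, frozen per event type.
_COMMON_TAIL = [
    "ID.1",
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
    "PValue",
    "FDR",
    "IncLevel1",
    "IncLevel2",
    "IncLevelDifference",
]
RMATS_COLUMNS: dict[str, list[str]] = {
    "SE": ["ID", "GeneID", "geneSymbol", "chr", "strand",
           "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"] + _COMMON_TAIL,
    "RI": ["ID", "GeneID", "geneSymbol", "chr", "strand",
           "riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"] + _COMMON_TAIL,
    "MXE": ["ID", "GeneID", "geneSymbol", "chr", "strand",
            "1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE", "downstreamES",
            "downstreamEE"] + _COMMON_TAIL,
    "A3SS": ["ID", "GeneID", "geneSymbol", "chr", "strand",
             "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"] + _COMMON_TAIL,
    "A5SS": ["ID", "GeneID", "geneSymbol", "chr", "strand",
             "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"] + _COMMON_TAIL,
}

_COUNT_COLS = ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2"]


class RmatsFormatError(ValueError):
    pass


@dataclass
class EventFilter:
    """Significance cut-offs for alternative splicing events.

    Strict inequalities: fdr < max_fdr AND |dPSI| > min_abs_dpsi.
    """

    max_fdr: float = 0.05
    min_abs_dpsi: float = 0.1

    def __post_init__(self):
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must be in (0, 1)")
        if self.min_abs_dpsi < 0:
            raise ValueError("min_abs_dpsi must be >= 0")


def _parse_int_list(field: str, what: str, lineno: int) -> list[int]:
    try:
        return [int(x) for x in str(field).split(",")]
    except ValueError:
        raise RmatsFormatError(
            f"line {lineno}: cannot parse {what} counts from {field!r}"
        ) from None


def read_rmats_table(path, event_type: str) -> pd.DataFrame:
    """Read one rMATS 4.1.2 JC table into an event DataFrame.

    Validates the header against the frozen column list for the event type
    and parses comma-separated replicate counts to integer lists. Malformed
    rows raise :class:`RmatsFormatError` naming the offending line.
    """
    if event_type not in RMATS_COLUMNS:
        raise ValueError(f"unknown event type {event_type!r}")
    expected = RMATS_COLUMNS[event_type]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        # rMATS repeats the literal column name "ID"; internally the second
        # copy is called "ID.1", so compare against the raw on-disk header.
        raw_expected = [c if c != "ID.1" else "ID" for c in expected]
        if header != raw_expected:
            missing = [c for c in raw_expected if c not in header]
            raise RmatsFormatError(
                f"{path}: header does not match rMATS 4.1.2 {event_type} JC "
                f"format; missing columns: {missing or 'none (order/extras differ)'}"
            )
        rows = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(expected):
                raise RmatsFormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected {len(expected)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=expected)
    for col in _COUNT_COLS:
        df[col] = [
            _parse_int_list(v, col, i + 2) for i, v in enumerate(df[col])
        ]
    for col in expected:
        if col.endswith(("_0base", "ES", "EE", "Start_0base", "End")) or col in (
            "exonEnd", "riExonEnd", "1stExonEnd", "2ndExonEnd", "longExonEnd",
        ):
            df[col] = df[col].astype(int)
    df["IncFormLen"] = df["IncFormLen"].astype(int)
    df["SkipFormLen"] = df["SkipFormLen"].astype(int)
    df["PValue"] = df["PValue"].astype(float)
    df["FDR"] = df["FDR"].astype(float)
    df["event_type"] = event_type
    df["event_id"] = event_type + ":" + df["ID"].astype(str)
    df["gene_id"] = df["GeneID"]
    return df


def write_rmats_table(df: pd.DataFrame, path, event_type: str) -> None:
    """Write an event DataFrame back to the rMATS 4.1.2 JC dialect."""
    cols = RMATS_COLUMNS[event_type]
    out = df.copy()
    for col in _COUNT_COLS:
        out[col] = out[col].map(
            lambda v: ",".join(str(int(x)) for x in v)
            if isinstance(v, (list, tuple, np.ndarray))
            else v
        )
    raw_header = [c if c != "ID.1" else "ID" for c in cols]
    with open(path, "w") as fh:
        fh.write("\t".join(raw_header) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def compute_psi(I_counts, S_counts, lI: float, lS: float):
    """Length-normalised PSI per replicate plus the group mean.

    Returns ``(psi_per_replicate, group_mean)``; replicates with
    I = S = 0 yield NaN and are excluded from the mean (NaN mean when no
    replicate is defined).
    """
    if lI < 1 or lS < 1:
        raise ValueError("effective lengths must be >= 1")
    I = np.asarray(I_counts, dtype=float)
    S = np.asarray(S_counts, dtype=float)
    if (I < 0).any() or (S < 0).any():
        raise ValueError("negative junction counts")
    inc = I / lI
    skip = S / lS
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(inc + skip > 0, inc / (inc + skip), np.nan)
    mean = float(np.nanmean(psi)) if np.isfinite(psi).any() else math.nan
    return psi, mean


def add_psi_columns(df: pd.DataFrame, treated_sample: int = 1) -> pd.DataFrame:
    """Compute psi_control/psi_treated/delta_psi from the junction counts.

    ``treated_sample`` declares which rMATS sample group (1 or 2) is the
    treated condition; with the default 1, delta_psi equals
    IncLevelDifference.
    """
    if treated_sample not in (1, 2):
        raise ValueError("treated_sample must be 1 or 2")
    control_sample = 2 if treated_sample == 1 else 1
    out = df.copy()
    psis = {1: [], 2: []}
    for _, row in df.iterrows():
        for s in (1, 2):
            _, mean = compute_psi(
                row[f"IJC_SAMPLE_{s}"],
                row[f"SJC_SAMPLE_{s}"],
                row["IncFormLen"],
                row["SkipFormLen"],
            )
            psis[s].append(mean)
    out["psi_treated"] = psis[treated_sample]
    out["psi_control"] = psis[control_sample]
    out["delta_psi"] = out["psi_treated"] - out["psi_control"]
    return out


def replicate_psi_strings(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """IncLevel1/IncLevel2 comma strings recomputed from the counts."""
    lvl1, lvl2 = [], []
    for _, row in df.iterrows():
        for s, acc in ((1, lvl1), (2, lvl2)):
            psi, _ = compute_psi(
                row[f"IJC_SAMPLE_{s}"],
                row[f"SJC_SAMPLE_{s}"],
                row["IncFormLen"],
                row["SkipFormLen"],
            )
            acc.append(",".join("NA" if np.isnan(p) else repr(float(p)) for p in psi))
    return lvl1, lvl2


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------


def filter_significant(df: pd.DataFrame, flt: EventFilter | None = None) -> pd.DataFrame:
    """Apply the significance cut-off: FDR < max_fdr AND |dPSI| > min_abs_dpsi.

    Events with undefined PSI in either group cannot be evaluated and are
    excluded.
    """
    flt = flt or EventFilter()
    dpsi = df["delta_psi"]
    keep = (
        dpsi.notna()
        & (df["FDR"] < flt.max_fdr)
        & (dpsi.abs() > flt.min_abs_dpsi)
    )
    return df[keep].copy()


def classify_direction(df: pd.DataFrame) -> pd.DataFrame:
    """Add direction UP (dPSI > 0, increased inclusion/retention) or DOWN.

    Significant events must have non-zero dPSI; a zero raises ValueError.
    """
    if (df["delta_psi"] == 0).any():
        bad = df.loc[df["delta_psi"] == 0, "event_id"].tolist()
        raise ValueError(f"delta_psi == 0 on significant events: {bad}")
    out = df.copy()
    out["direction"] = np.where(out["delta_psi"] > 0, "UP", "DOWN")
    return out


def count_by_type(df: pd.DataFrame) -> pd.DataFrame:
    """Zero-filled contingency table event_type x direction."""
    table = pd.DataFrame(0, index=list(EVENT_TYPES), columns=["UP", "DOWN"])
    if len(df):
        counts = df.groupby(["event_type", "direction"]).size()
        for (etype, direction), n in counts.items():
            table.loc[etype, direction] = n
    table.index.name = "event_type"
    return table


def family_skew_test(n_up: int, n_down: int, total_up: int, total_down: int) -> float:
    """One-sided hypergeometric test for directional skew within a family.

    Probability of drawing >= ``n_up`` UP events when ``n_up + n_down``
    events are drawn without replacement from the pooled population of
    ``total_up`` UP and ``total_down`` DOWN events. Empty family -> NaN.
    """
    for v in (n_up, n_down, total_up, total_down):
        if v < 0:
            raise ValueError("counts must be >= 0")
    if n_up > total_up or n_down > total_down:
        raise ValueError("family counts exceed totals")
    family = n_up + n_down
    if family == 0:
        return math.nan
    M = total_up + total_down
    return float(stats.hypergeom.sf(n_up - 1, M, total_up, family))


def se_upstream_intron(ev) -> tuple[int, int]:
    """Genomic interval of the intron transcript-upstream of a cassette exon.

    rMATS upstream/downstream exon columns are transcript-relative: on '-'
    the upstream exon lies genomically right of the cassette exon.
    """
    if ev["strand"] == "+":
        return int(ev["upstreamEE"]), int(ev["exonStart_0base"])
    return int(ev["exonEnd"]), int(ev["upstreamES"])


def ri_intron_interval(ev) -> tuple[int, int]:
    """Genomic interval of a retained intron from its flanking exon columns."""
    if ev["strand"] == "+":
        return int(ev["upstreamEE"]), int(ev["downstreamES"])
    return int(ev["downstreamEE"]), int(ev["upstreamES"])


def write_significant_events(df: pd.DataFrame, path) -> None:
    cols = [
        "event_id", "event_type", "gene_id", "chr", "strand",
        "psi_control", "psi_treated", "delta_psi", "FDR", "direction",
    ]
    df.to_csv(path, sep="\t", index=False, columns=[c for c in cols if c in df])
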