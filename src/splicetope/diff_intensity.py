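"""Perseus-style differential analysis of log2 intensity matrices.

Implements the label-free proteomics workflow: validity filtering within
sample groups, phosphosite quality filtering, median normalisation,
missing-not-at-random imputation from a downshifted normal distribution,
and the SAM-moderated two-sample test

    d = dm / (s + s0)

where dm is the treated-minus-control mean difference, s the pooled
two-sample standard error and s0 a variance-stabilising offset ("S0" in
Perseus). False discovery is controlled by group-label permutations using
the SAM convention: the q-value of a feature is the median number of
permutation |d| values at or above its |d|, divided by the observed count
at that cut-off, made monotone in |d| and capped at 1.

Two named presets ship with the module, mirroring common proteome and
phosphoproteome parameterisations:

    proteome: valid fraction 0.75, imputation width 0.3 / downshift 2.4, s0 0.35
    phospho:  valid fraction 1.0,  imputation width 0.3 / downshift 1.8, s0 0.1,
              site localization probability >= 0.75
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("control", "treated")

PRESETS: dict[str, dict] = {
    "proteome": {"valid_fraction": 0.75, "width": 0.3, "downshift": 2.4, "s0": 0.35,
                 "fdr_threshold": 0.05},
    "phospho": {"valid_fraction": 1.0, "width": 0.3, "downshift": 1.8, "s0": 0.1,
                "fdr_threshold": 0.05, "min_localization": 0.75},
}


@dataclass
class IntensityMatrix:
    """Features x samples log2 intensities with missing entries as NaN.

    ``groups`` maps sample id -> 'control' / 'treated'; ``meta`` (optional)
    carries per-feature annotation (protein_id, residue, position,
    localization_prob, reverse, contaminant for phosphosite data).
    """

    values: pd.DataFrame
    groups: pd.Series
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        if self.meta is not None:
            self.meta = self.meta.reindex(self.values.index)

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset(self, features) -> "IntensityMatrix":
        meta = self.meta.loc[features] if self.meta is not None else None
        return IntensityMatrix(self.values.loc[features].copy(), self.groups.copy(), meta)

    def copy(self) -> "IntensityMatrix":
        meta = self.meta.copy() if self.meta is not None else None
        return IntensityMatrix(self.values.copy(), self.groups.copy(), meta)


# ---------------------------------------------------------------------------
# TSV I/O (first column feature id, header sample ids, empty cell = missing)
# ---------------------------------------------------------------------------


def read_intensity_tsv(path, group_labels: dict | None = None) -> IntensityMatrix:
    """Read a features x samples TSV.

    When ``group_labels`` is omitted, group membership is inferred from the
    sample-name prefix before the final underscore ('control_1', 'treated_2').
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if group_labels is None:
        group_labels = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return IntensityMatrix(df.astype(float), pd.Series(group_labels))


def write_intensity_tsv(matrix: IntensityMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_valid_fraction(
    matrix: IntensityMatrix, min_fraction: float, scope: str = "at least one group"
) -> IntensityMatrix:
    """Keep features whose valid-value fraction reaches ``min_fraction``
    within at least one sample group. Row order is preserved."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if scope != "at least one group":
        raise ValueError(f"unsupported scope {scope!r}")
    keep = pd.Series(False, index=matrix.values.index)
    for g in GROUPS:
        cols = matrix.samples(g)
        frac = matrix.values[cols].notna().mean(axis=1)
        keep |= frac >= min_fraction
    if not keep.any():
        warnings.warn("validity filter removed every feature", stacklevel=2)
    return matrix.subset(matrix.values.index[keep])


def filter_phosphosites(
    matrix: IntensityMatrix, min_localization: float = 0.75
) -> IntensityMatrix:
    """Drop reverse-database hits, contaminants, and poorly localized sites
    (localization probability < ``min_localization``, inclusive bound kept)."""
    if matrix.meta is None or "localization_prob" not in matrix.meta.columns:
        raise ValueError("phosphosite metadata with localization_prob required")
    meta = matrix.meta
    keep = meta["localization_prob"] >= min_localization
    for flag in ("reverse", "contaminant"):
        if flag in meta.columns:
            keep &= ~meta[flag].fillna(False).astype(bool)
    return matrix.subset(matrix.values.index[keep.to_numpy()])


# ---------------------------------------------------------------------------
# Normalisation and imputation
# ---------------------------------------------------------------------------


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract the per-sample median of observed values (medians -> 0)."""
    out = matrix.copy()
    out.values = out.values - out.values.median(axis=0)
    return out


def impute_downshifted_normal(
    matrix: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
    per: str = "sample",
) -> IntensityMatrix:
    """Replace missing entries with draws from a downshifted normal.

    For each sample s with observed mean mu_s and SD sigma_s, missing
    entries are drawn from N(mu_s - downshift*sigma_s, (width*sigma_s)^2) —
    the Perseus emulation of missing-not-at-random dropout. ``per='matrix'``
    pools mu/sigma over the whole matrix instead.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if downshift < 0:
        raise ValueError("downshift must be >= 0")
    if per not in ("sample", "matrix"):
        raise ValueError("per must be 'sample' or 'matrix'")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values
    if per == "matrix":
        obs = vals.to_numpy()[~np.isnan(vals.to_numpy())]
        if obs.size < 2:
            raise ValueError("matrix has fewer than 2 observed values")
        mu_all, sd_all = float(obs.mean()), float(obs.std(ddof=1))
    for col in vals.columns:
        mask = vals[col].isna()
        if not mask.any():
            continue
        if per == "sample":
            obs = vals[col].dropna()
            if len(obs) < 2:
                raise ValueError(
                    f"sample {col!r} has fewer than 2 observed values; "
                    "cannot estimate the imputation distribution"
                )
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        else:
            mu, sd = mu_all, sd_all
        draws = rng.normal(mu - downshift * sd, width * sd, size=int(mask.sum()))
        vals.loc[mask, col] = draws
    return out


# ---------------------------------------------------------------------------
# SAM test
# ---------------------------------------------------------------------------


def _d_statistic(X: np.ndarray, idx_t: np.ndarray, idx_c: np.ndarray, s0: float):
    nt, nc = len(idx_t), len(idx_c)
    mt = X[:, idx_t].mean(axis=1)
    mc = X[:, idx_c].mean(axis=1)
    vt = X[:, idx_t].var(axis=1, ddof=1)
    vc = X[:, idx_c].var(axis=1, ddof=1)
    sp2 = ((nt - 1) * vt + (nc - 1) * vc) / (nt + nc - 2)
    se = np.sqrt(sp2 * (1.0 / nt + 1.0 / nc))
    diff = mt - mc
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return d, diff, se


def _label_permutations(n: int, n_t: int, n_permutations: int, rng) -> list[np.ndarray]:
    """Index sets taking the role of 'treated'; all distinct assignments when
    they number no more than ``n_permutations``, else a random sample."""
    total = math.comb(n, n_t)
    if total <= n_permutations:
        return [np.array(c) for c in combinations(range(n), n_t)]
    return [np.sort(rng.permutation(n)[:n_t]) for _ in range(n_permutations)]


def sam_test(
    matrix: IntensityMatrix,
    s0: float = 0.35,
    fdr_threshold: float = 0.05,
    n_permutations: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-moderated two-sample test with permutation q-values.

    Requires a complete (imputed) matrix. Returns a DataFrame with columns
    feature, log2fc (treated - control), se, d, q_value, significant.
    With s0 = 0, d is exactly the classical pooled-variance t statistic.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    cols = list(vals.columns)
    idx_t = np.array([cols.index(c) for c in matrix.samples("treated")])
    idx_c = np.array([cols.index(c) for c in matrix.samples("control")])
    X = vals.to_numpy(dtype=float)
    d_obs, diff, se = _d_statistic(X, idx_t, idx_c, s0)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(seed)
    n = len(cols)
    perms = _label_permutations(n, len(idx_t), n_permutations, rng)
    all_idx = np.arange(n)
    # per-permutation counts of |d_perm| >= each observed |d| cut-off
    order = np.argsort(-abs_obs)  # descending |d|
    thresholds = abs_obs[order]
    counts = np.empty((len(perms), len(thresholds)))
    for pi, comb in enumerate(perms):
        comp = np.setdiff1d(all_idx, comb, assume_unique=True)
        d_p, _, _ = _d_statistic(X, comb, comp, s0)
        sorted_abs = np.sort(np.abs(d_p))
        # ties count as exceeding (>= comparison)
        counts[pi] = len(d_p) - np.searchsorted(sorted_abs, thresholds, side="left")
    median_fp = np.median(counts, axis=0)
    obs_count = np.arange(1, len(thresholds) + 1, dtype=float)
    # equal |d| values share the largest observed count at that cut-off
    for i in range(len(thresholds) - 2, -1, -1):
        if thresholds[i] == thresholds[i + 1]:
            obs_count[i] = obs_count[i + 1]
    q_sorted = np.minimum(median_fp / obs_count, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone as |d| decreases
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    return pd.DataFrame(
        {
            "feature": vals.index,
            "log2fc": diff,
            "se": se,
            "d": d_obs,
            "q_value": q,
            "significant": q <= fdr_threshold,
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# Protein-level phosphorylation classes
# ---------------------------------------------------------------------------


def classify_protein_phospho(
    site_results: pd.DataFrame,
    protein_ids: pd.Series,
    log2fc_threshold: float = 0.58,
) -> pd.DataFrame:
    """Classify proteins as hyper / hypo / biphasic / unchanged.

    A site counts when it is significant (q-based) AND |log2fc| exceeds
    ``log2fc_threshold``. Proteins with up- and down-regulated sites are
    biphasic; only-up hyper; only-down hypo; no qualifying site unchanged.
    """
    res = site_results.join(protein_ids.rename("protein_id"))
    qualifying = res["significant"] & (res["log2fc"].abs() > log2fc_threshold)
    res = res.assign(
        up=qualifying & (res["log2fc"] > 0),
        down=qualifying & (res["log2fc"] < 0),
    )
    agg = res.groupby("protein_id")[["up", "down"]].sum().astype(int)
    cls = np.select(
        [
            (agg["up"] >= 1) & (agg["down"] >= 1),
            (agg["up"] >= 1) & (agg["down"] == 0),
            (agg["down"] >= 1) & (agg["up"] == 0),
        ],
        ["biphasic", "hyper", "hypo"],
        default="unchanged",
    )
    return pd.DataFrame(
        {"class": cls, "n_sites_up": agg["up"], "n_sites_down": agg["down"]},
        index=agg.index,
    )


# ---------------------------------------------------------------------------
# Condition-specific detection (raw missingness + post-imputation test)
# ---------------------------------------------------------------------------


def detect_condition_specific(
    raw: IntensityMatrix,
    imputed: IntensityMatrix,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Features detected exclusively in one condition.

    A feature qualifies when it has at least one valid raw value in one
    group and none in the other, and its post-imputation two-sample t-test
    p-value falls below ``p_threshold``. Direction is 'treated-only' or
    'control-only'.
    """
    t_cols = raw.samples("treated")
    c_cols = raw.samples("control")
    valid_t = raw.values[t_cols].notna().sum(axis=1)
    valid_c = raw.values[c_cols].notna().sum(axis=1)
    direction = pd.Series("", index=raw.values.index, dtype=object)
    direction[(valid_t >= 1) & (valid_c == 0)] = "treated-only"
    direction[(valid_c >= 1) & (valid_t == 0)] = "control-only"
    cand = direction[direction != ""].index
    rows = []
    for feat in cand:
        a = imputed.values.loc[feat, t_cols].to_numpy(dtype=float)
        b = imputed.values.loc[feat, c_cols].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b)
        if np.isnan(p):  # zero variance in both groups
            p = 1.0 if a.mean() == b.mean() else 0.0
        if p < p_threshold:
            rows.append({"feature": feat, "direction": direction[feat], "p_value": float(p)})
    return pd.DataFrame(rows, columns=["feature", "direction", "p_value"])
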