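"""Position-weight matrix fixture format shared by the feature and RNA-map
modules.

Format: tab-separated, first line ``pos<TAB>A<TAB>C<TAB>G<TAB>U`` (T accepted
as an alias of U), one row per motif position with base probabilities that
sum to 1. Matrices are held as numpy arrays of shape (length, 4) in ACGT
column order.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_BASE_IDX["U"] = _BASE_IDX["T"]


def load_pwm(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[0] != "pos" or len(header) != 5:
            raise ValueError(f"{path}: expected header 'pos A C G U/T', got {header}")
        col_order = [_BASE_IDX[b] for b in header[1:]]
        rows = []
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""]:
                continue
            vals = np.zeros(4)
            for slot, v in zip(col_order, parts[1:]):
                vals[slot] = float(v)
            rows.append(vals)
    pwm = np.array(rows)
    validate_pwm(pwm)
    return pwm


def write_pwm(pwm: np.ndarray, path) -> None:
    validate_pwm(pwm)
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tU\n")
        for i, row in enumerate(pwm):
            fh.write(f"{i + 1}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def validate_pwm(pwm: np.ndarray) -> None:
    pwm = np.asarray(pwm)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must have shape (length, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each PWM row must sum to 1")
    if (pwm < 0).any():
        raise ValueError("PWM probabilities must be >= 0")


def log_odds(pwm: np.ndarray, background: float = 0.25, floor: float = 1e-6) -> np.ndarray:
    """Per-position log2 odds against a uniform background."""
    return np.log2(np.maximum(np.asarray(pwm, dtype=float), floor) / background)


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes (A0 C1 G2 T/U3); unknown letters -> -1."""
    out = np.full(len(seq), -1, dtype=int)
    for i, c in enumerate(seq.upper()):
        out[i] = _BASE_IDX.get(c, -1)
    return out


def score_window(lo: np.ndarray, codes: np.ndarray, start: int) -> float:
    """Log-odds score of the window of PWM length beginning at ``start``."""
    L = lo.shape[0]
    window = codes[start : start + L]
    if (window < 0).any():
        return -np.inf
    return float(lo[np.arange(L), window].sum())
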