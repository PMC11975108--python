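"""Force-trace processing: per-cycle peaks, normalizations, small statistics.

Gait cycling produces one dynamic force peak per cycle in soleus and two in
EDL (stance and swing excitation bursts).  Per-cycle peaks are extracted and
normalized to the muscle's maximum isometric force from the pre-protocol
force-frequency profile; eccentric series are normalized to the first
contraction.  Group-level screening uses the Dixon Q test for single
outliers in small samples and the Holm-Bonferroni step-down correction for
families of pairwise comparisons.  Mixed-model fitting is out of scope: the
module emits tidy tables any modelling tool can consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ForceTrace",
    "extract_cycle_peaks",
    "normalize_to_reference",
    "force_loss",
    "dixon_q_filter",
    "holm_bonferroni",
    "DIXON_CRITICAL_05",
]


@dataclass(frozen=True)
class ForceTrace:
    """A measured force trace with optional cycle boundaries and markers."""

    time_s: np.ndarray
    force_mn: np.ndarray
    cycle_boundaries: tuple[tuple[float, float], ...] | None = None
    protocol_markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.force_mn, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("time and force must be equal-length 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("force must be finite")
        if self.cycle_boundaries is not None:
            b = tuple((float(a), float(z)) for a, z in self.cycle_boundaries)
            prev_end = -np.inf
            for a, z in b:
                if z <= a or a < prev_end - 1e-12:
                    raise ValueError("cycle boundaries must be ordered and "
                                     "non-overlapping")
                prev_end = z
            # a half-open final cycle may end one sample step past t[-1]
            dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
            if b and (b[0][0] < t[0] - 1e-9 or b[-1][1] > t[-1] + 1.5 * dt):
                raise ValueError("cycle boundaries fall outside the time span")
            object.__setattr__(self, "cycle_boundaries", b)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_mn", f)


def extract_cycle_peaks(trace: ForceTrace, n_peaks: int = 1,
                        reference_mn: float | None = None) -> pd.DataFrame:
    """Per-cycle dynamic peak forces, in temporal order.

    For each cycle the ``n_peaks`` largest strict local maxima are reported
    (plateaus resolve to their first sample).  Two-peak extraction requires
    the maxima to be separated by at least 10% of the cycle duration; if only
    one qualifies the second is reported missing (NaN).  A cycle with no
    interior local maximum (monotone ramp) reports its maximum sample flagged
    as a boundary/plateau case.  ``reference_mn`` fills the normalized column.
    """
    if trace.cycle_boundaries is None:
        raise ValueError("cycle boundaries are required for peak extraction")
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    rows = []
    t, f = trace.time_s, trace.force_mn
    for ci, (a, z) in enumerate(trace.cycle_boundaries):
        sel = (t >= a - 1e-12) & (t < z - 1e-12)
        if not sel.any():
            raise ValueError(f"cycle {ci} contains no samples")
        tc, fc = t[sel], f[sel]
        min_sep = max(1, int(0.10 * len(fc))) if n_peaks == 2 else 1
        idx, props = find_peaks(fc, distance=min_sep, plateau_size=1)
        if idx.size:
            idx = props["left_edges"]  # plateaus resolve to their first sample
        flagged = False
        if idx.size == 0:
            idx = np.array([int(np.argmax(fc))])
            flagged = True
        # n_peaks largest maxima, reported in temporal order
        largest = idx[np.argsort(fc[idx])[::-1][:n_peaks]]
        largest = np.sort(largest)
        peak_ids = ["single"] if n_peaks == 1 else ["peak1", "peak2"]
        for k, pid in enumerate(peak_ids):
            if k < len(largest):
                i = largest[k]
                raw = float(fc[i])
                rows.append({"cycle_index": ci, "peak_id": pid,
                             "time_s": float(tc[i]), "raw_peak_mn": raw,
                             "normalized_peak": raw / reference_mn
                             if reference_mn else np.nan,
                             "flagged": flagged})
            else:
                rows.append({"cycle_index": ci, "peak_id": pid,
                             "time_s": np.nan, "raw_peak_mn": np.nan,
                             "normalized_peak": np.nan, "flagged": True})
    return pd.DataFrame(rows)


def normalize_to_reference(values: Sequence[float], reference: float) -> np.ndarray:
    """Elementwise division by a positive reference force."""
    if not reference > 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return np.asarray(values, dtype=float) / reference


def force_loss(pre: float, post: float) -> float:
    """Fractional force loss 1 - post/pre; negative means enhancement."""
    if not pre > 0:
        raise ValueError("pre-protocol force must be > 0")
    return 1.0 - post / pre


# Two-tailed Dixon critical values at alpha = 0.05 (Rorabacher 1991),
# with the variant chosen by sample size as in standard Dixon practice:
# r10 for n <= 7, r11 for 8-10, r21 for 11-13, r22 for n >= 14.
DIXON_CRITICAL_05 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,          # r10
    8: 0.608, 9: 0.564, 10: 0.530,                             # r11
    11: 0.619, 12: 0.583, 13: 0.557,                           # r21
    14: 0.586, 15: 0.565, 16: 0.546, 17: 0.529, 18: 0.514,     # r22
    19: 0.501, 20: 0.489, 21: 0.478, 22: 0.468, 23: 0.459,
    24: 0.451, 25: 0.443, 26: 0.436, 27: 0.429, 28: 0.423,
    29: 0.417, 30: 0.412,
}


def _dixon_ratios(x: np.ndarray) -> tuple[float, float]:
    """(low-end, high-end) Dixon ratios for the size-appropriate variant."""
    n = len(x)
    if n <= 7:      # r10
        lo = (x[1] - x[0]) / (x[-1] - x[0])
        hi = (x[-1] - x[-2]) / (x[-1] - x[0])
    elif n <= 10:   # r11
        lo = (x[1] - x[0]) / (x[-2] - x[0])
        hi = (x[-1] - x[-2]) / (x[-1] - x[1])
    elif n <= 13:   # r21
        lo = (x[2] - x[0]) / (x[-2] - x[0])
        hi = (x[-1] - x[-3]) / (x[-1] - x[1])
    else:           # r22
        lo = (x[2] - x[0]) / (x[-3] - x[0])
        hi = (x[-1] - x[-3]) / (x[-1] - x[2])
    return float(lo), float(hi)


def dixon_q_filter(values: Sequence[float], alpha: float = 0.05,
                   passes: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Dixon outlier screen; returns (kept, removed) in input order.

    The suspect extreme with the larger gap-to-range ratio is tested against
    the two-sided critical value; at most one value is removed per pass, one
    pass by default.  Ties and zero-range inputs remove nothing.  Only the
    published alpha = 0.05 table is shipped.
    """
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 critical values are available")
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3:
        raise ValueError("Dixon test requires at least 3 values")
    if len(vals) > 30:
        raise ValueError("Dixon test is tabulated for n <= 30")
    removed_idx: list[int] = []
    active = list(range(len(vals)))
    for _ in range(max(1, passes)):
        x_idx = sorted(active, key=lambda i: vals[i])
        x = vals[x_idx]
        if len(x) < 3 or x[-1] == x[0]:
            break
        denom_ok = True
        try:
            lo, hi = _dixon_ratios(x)
        except ZeroDivisionError:
            denom_ok = False
        if not denom_ok or not np.isfinite([lo, hi]).all():
            break
        q, suspect = (lo, x_idx[0]) if lo >= hi else (hi, x_idx[-1])
        if q > DIXON_CRITICAL_05[len(x)]:
            removed_idx.append(suspect)
            active.remove(suspect)
        else:
            break
    kept = np.array([v for i, v in enumerate(vals) if i not in removed_idx])
    removed = vals[sorted(removed_idx)]
    return kept, removed


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> pd.DataFrame:
    """Holm-Bonferroni step-down multiple-comparison correction.

    Sort ascending and reject while p_(i) <= alpha / (m - i + 1); the first
    failure stops all later rejections.  Adjusted p-values are the standard
    monotone step-down ones, p_adj(i) = max_{j<=i} min(1, (m-j+1) p_(j)).
    Returns a DataFrame in the input order with ``p``, ``p_adjusted`` and
    ``reject``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject_sorted = np.zeros(m, dtype=bool)
    adj_sorted = np.empty(m)
    running_max = 0.0
    still_rejecting = True
    for rank, i in enumerate(order):
        step = (m - rank) * p[i]
        running_max = max(running_max, min(1.0, step))
        adj_sorted[rank] = running_max
        if still_rejecting and p[i] <= alpha / (m - rank):
            reject_sorted[rank] = True
        else:
            still_rejecting = False
    out = pd.DataFrame({"p": p,
                        "p_adjusted": np.empty(m),
                        "reject": np.zeros(m, dtype=bool)})
    out.loc[order, "p_adjusted"] = adj_sorted
    out.loc[order, "reject"] = reject_sorted
    return out
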