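"""Two-group differential expression on log2-scale matrices.

The test is a Welch unequal-variance t per feature (assumption-light and
appropriate after log2 normalization), with Benjamini–Hochberg adjustment
across features. A feature is called differentially expressed when the
adjusted p falls below ``de_alpha`` AND the linear fold change exceeds
``de_fc_threshold`` (i.e. |log2fc| > log2(threshold)), both strict.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .config import Config
from .models import DEResult, ExpressionMatrix


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value.

    Degenerate case: both groups constant with equal means → (0.0, 1.0);
    both constant with different means → (±inf, 0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j ≥ i} (m · p_(j) / j) over the ascending sort, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        bad = int(np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))[0])
        raise ValueError(f"p-value outside [0, 1] at index {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_de(matrix: ExpressionMatrix, config: Config | None = None) -> list[DEResult]:
    """Per-feature Welch t + BH, with the joint adjusted-p / fold-change call."""
    cfg = config or Config()
    case = matrix.group("case")
    control = matrix.group("control")
    log2fc = case.mean(axis=1) - control.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # rows where both groups are constant: scipy yields nan
    degenerate = np.isnan(t)
    equal_means = degenerate & (log2fc == 0.0)
    sep = degenerate & (log2fc != 0.0)
    t[equal_means], p[equal_means] = 0.0, 1.0
    t[sep] = np.sign(log2fc[sep]) * np.inf
    p[sep] = 0.0

    adj = bh_adjust(p)
    lfc_cut = np.log2(cfg.de_fc_threshold)
    return [
        DEResult(
            feature_id=fid,
            log2fc=float(log2fc[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            adj_p=float(adj[i]),
            is_de=bool(adj[i] < cfg.de_alpha and abs(log2fc[i]) > lfc_cut),
        )
        for i, fid in enumerate(matrix.feature_ids)
    ]
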