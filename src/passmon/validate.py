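"""Rank-correlation validation of sensor activations against step counts.

Spearman's rho is computed as the Pearson correlation of average-assigned
ranks; the two-sided p-value uses the t approximation with n-2 degrees of
freedom, with an optional seeded permutation test for small samples.  A
threshold-sensitivity sweep re-runs the correlation under step-outlier
cutoffs from 100 to 400 steps in increments of 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SWEEP_THRESHOLDS = tuple(range(100, 401, 50))


@dataclass(frozen=True)
class ValidationResult:
    """Spearman rho for one scope (pooled ALL or a single house)."""

    scope: str
    rho: float
    n: int
    p_value: float
    outlier_threshold: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "rho": self.rho,
            "n": self.n,
            "p_value": self.p_value,
            "outlier_threshold": self.outlier_threshold,
        }


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("all values tied in one variable; rho is undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return max(-1.0, min(1.0, rho))


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_rho(
    counts,
    steps,
    scope: str = "ALL",
    outlier_threshold: int | None = None,
    p_method: str = "t",
    n_permutations: int = 999,
    seed: int | None = None,
) -> ValidationResult:
    """Spearman rank correlation between activation counts and steps.

    With ``outlier_threshold`` set, pairs with steps strictly above the
    threshold are dropped first.  ``p_method`` is ``"t"`` (default) or
    ``"permutation"`` (seeded, for auditability at small n).
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(steps, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("counts and steps must be 1-D arrays of equal length")
    if outlier_threshold is not None:
        keep = y <= outlier_threshold
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a defined p-value, got {n}")
    rho = _spearman(x, y)
    if p_method == "t":
        p = _t_pvalue(rho, n)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            try:
                r = _spearman(x, perm)
            except ValueError:
                r = 0.0
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return ValidationResult(scope, rho, n, p, outlier_threshold)


def per_house_results(
    pairs: pd.DataFrame, outlier_threshold: int | None = None
) -> list[ValidationResult]:
    """One result per house; ``pairs`` needs house_id/activation_count/steps."""
    out = []
    for house_id, block in pairs.groupby("house_id", sort=True):
        out.append(
            spearman_rho(
                block["activation_count"],
                block["steps"],
                scope=str(house_id),
                outlier_threshold=outlier_threshold,
            )
        )
    return out


def threshold_sweep(
    pairs: pd.DataFrame,
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    scope: str = "ALL",
) -> list[ValidationResult]:
    """Pooled correlation at each outlier threshold, ordered by threshold."""
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValueError("threshold list must not be empty")
    return [
        spearman_rho(
            pairs["activation_count"],
            pairs["steps"],
            scope=scope,
            outlier_threshold=int(t),
        )
        for t in sorted(thresholds)
    ]


def build_pairs(records) -> pd.DataFrame:
    """Paired (activation_count, steps) rows from interval records.

    Records with either quantity missing are skipped.
    """
    rows = [
        {
            "house_id": r.house_id,
            "t_start": r.t_start,
            "activation_count": r.activation_count,
            "steps": r.steps,
        }
        for r in records
        if r.activation_count is not None and r.steps is not None
    ]
    return pd.DataFrame(rows, columns=["house_id", "t_start", "activation_count", "steps"])


def validation_report(records, config) -> dict:
    """Full pilot-style validation: pooled rho (with and without noise
    removal), per-house results with their min/max range, and the
    threshold sweep.

    ``records`` are interval records carrying steps; ``config`` is a
    ClassifierConfig (supplies the outlier threshold and noise rule).
    """
    from passmon.classify import ExclusionReason, classify_records

    pairs_raw = build_pairs(records)
    if pairs_raw.empty:
        raise ValueError("no paired activation/step intervals to validate")
    labeled = classify_records(sorted(records, key=lambda r: (r.house_id, r.t_start)), config)
    noisy_keys = {
        (li.record.house_id, li.record.t_start)
        for li in labeled
        if li.exclusion_reason is ExclusionReason.NOISE
    }
    denoised_mask = ~pairs_raw.apply(
        lambda row: (row["house_id"], row["t_start"]) in noisy_keys, axis=1
    )
    pairs = pairs_raw[denoised_mask]
    thr = config.outlier_step_threshold
    pooled = spearman_rho(pairs["activation_count"], pairs["steps"], outlier_threshold=thr)
    pooled_with_noise = spearman_rho(
        pairs_raw["activation_count"], pairs_raw["steps"], outlier_threshold=thr
    )
    per_house = per_house_results(pairs, outlier_threshold=thr)
    rhos = [r.rho for r in per_house]
    return {
        "pooled": pooled.to_dict(),
        "pooled_with_noise": pooled_with_noise.to_dict(),
        "per_house": [r.to_dict() for r in per_house],
        "rho_range": [min(rhos), max(rhos)],
        "sweep": [r.to_dict() for r in threshold_sweep(pairs)],
    }


def scatter_plot(pairs: pd.DataFrame, path) -> None:
    """Scatter of activation count vs steps (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    jitter = (np.random.default_rng(0).random(len(pairs)) - 0.5) * 0.3
    ax.scatter(pairs["activation_count"] + jitter, pairs["steps"], s=6, alpha=0.3)
    ax.set_xlabel("sensors activated per 5-min interval")
    ax.set_ylabel("steps per 5-min interval")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
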