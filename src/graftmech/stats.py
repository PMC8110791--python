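"""Group-comparison statistics for the in vitro readouts.

Between-condition differences (HSS/OSS/LSS) are tested with a two-sided
Kruskal–Wallis omnibus test (tie-corrected) followed by Dunn's pairwise
z-tests on the pooled mean ranks, with a configurable multiplicity
adjustment (Holm by default).  Gene-expression fold changes are log10
transformed before testing.  Construct mass-change ratios are tested
against 1.0 (no change) with a one-sample t-test.  Significance is
declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupTestReport", "group_tests", "dunn_posthoc", "one_sample_t"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupTestReport:
    """Kruskal–Wallis omnibus result plus Dunn pairwise comparisons."""

    h_statistic: float
    p_value: float
    group_sizes: dict
    pairwise: list  # dicts: group_a, group_b, z, p_raw, p_adjusted, significant
    log_transformed: bool
    adjust_method: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "kruskal_wallis": {
                "H": self.h_statistic,
                "p": self.p_value,
                "significant": self.significant,
            },
            "group_sizes": self.group_sizes,
            "log_transformed": self.log_transformed,
            "adjust_method": self.adjust_method,
            "pairwise": self.pairwise,
        }


def dunn_posthoc(groups: dict, *, adjust: str = "holm") -> list:
    """Dunn's pairwise rank z-tests after a Kruskal–Wallis omnibus.

    All observations are ranked jointly (mid-ranks for ties); for each
    pair, ``z = (r̄_i − r̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j))``
    with tie correction ``T = Σ(t³−t)/(12(N−1))``.  Two-sided normal
    p-values are adjusted by ``adjust`` ('holm', 'bonferroni', 'none',
    or any statsmodels method name).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[i : i + v.size].mean()
        sizes[g] = v.size
        i += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    if adjust == "none":
        for r in rows:
            r["p_adjusted"] = r["p_raw"]
    else:
        _, p_adj, _, _ = multipletests([r["p_raw"] for r in rows], method=adjust)
        for r, pa in zip(rows, p_adj):
            r["p_adjusted"] = float(pa)
    for r in rows:
        r["significant"] = bool(r["p_adjusted"] < ALPHA)
    return rows


def group_tests(
    groups: dict,
    *,
    log_transform: bool = False,
    adjust: str = "holm",
) -> GroupTestReport:
    """Kruskal–Wallis + Dunn report for ≥2 groups of observations.

    ``log_transform`` applies log10 first (for fold-change data; values
    must then be positive).  Note the Kruskal–Wallis and Dunn statistics
    are rank-based and unaffected by the monotone transform; it is
    applied for fidelity to the reporting pipeline and for any
    downstream parametric summaries.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable observations")
        if log_transform:
            if np.any(v <= 0):
                raise ValueError("log transform requires positive values")
            v = np.log10(v)
        clean[g] = v
    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0.0:
        # identical distributions: all mean ranks coincide, H = 0
        H, p = 0.0, 1.0
        pairwise = [
            {"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0,
             "p_adjusted": 1.0, "significant": False}
            for a, b in combinations(clean, 2)
        ]
    else:
        H, p = sps.kruskal(*clean.values())
        pairwise = dunn_posthoc(clean, adjust=adjust)
    return GroupTestReport(
        h_statistic=float(H),
        p_value=float(p),
        group_sizes={g: int(v.size) for g, v in clean.items()},
        pairwise=pairwise,
        log_transformed=log_transform,
        adjust_method=adjust,
    )


def one_sample_t(values, reference: float = 1.0) -> dict:
    """Two-sided one-sample t-test against ``reference`` (default 1.0,
    the no-change mass ratio).  A zero-variance sample equal to the
    reference is reported as t = 0, p = 1 (no effect)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0.0:
        if v[0] == reference:
            return {"t": 0.0, "p": 1.0, "mean": float(v[0]), "n": int(v.size), "significant": False}
        raise ValueError("zero-variance sample differing from reference: t undefined")
    t, p = sps.ttest_1samp(v, reference)
    return {
        "t": float(t),
        "p": float(p),
        "mean": float(v.mean()),
        "n": int(v.size),
        "significant": bool(p < ALPHA),
    }
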