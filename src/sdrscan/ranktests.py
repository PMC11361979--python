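"""Chromosome-level inference on window log2(XY:ZW) ratios.

A Kruskal-Wallis test asks whether the log ratio distribution differs
among chromosomes; when it does, Dunn's rank-based pairwise comparisons
(Benjamini-Hochberg adjusted across all chromosome pairs) localize which
chromosomes differ.  Top-percentile windows are merged into candidate
sex-determining regions.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ChromTestResult:
    H: float
    df: int
    p: float
    dunn: pd.DataFrame | None  # columns: group_i, group_j, z, p_raw, p_adjusted
    groups: list[str]


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    With every observation equal, H is defined as 0 (p = 1) rather than
    undefined.  Requires at least two groups, each non-empty.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Dunn's pairwise z statistics on midranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))](1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; p_raw is the two-sided normal
    tail.  Rows cover all unordered pairs in group order.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))

    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]

    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:  # all observations tied: no evidence either way
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z, "p_raw": min(p_raw, 1.0)})
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j) over the ascending sort,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def run_chrom_tests(
    windows: pd.DataFrame,
    alpha: float = 0.05,
    observations: str = "all",
    top: pd.DataFrame | None = None,
) -> ChromTestResult:
    """Kruskal-Wallis across chromosomes on window log2 ratios, with
    Dunn + BH post-hoc when the omnibus test is significant at ``alpha``.

    ``observations='all'`` uses every anchored window (default);
    ``'top'`` restricts to the supplied top-percentile selection.
    """
    if observations == "all":
        obs = windows[windows["anchored"]]
    elif observations == "top":
        if top is None:
            raise ValueError("observations='top' needs the selected windows")
        obs = top
    else:
        raise ValueError(f"unknown observations mode {observations!r}")
    labels = list(dict.fromkeys(obs["chrom"]))
    groups = [obs.loc[obs["chrom"] == c, "log2_ratio"].to_numpy() for c in labels]
    h, p = kruskal_wallis(groups)
    dunn = None
    if p < alpha:
        dunn = dunn_posthoc(groups, labels)
        dunn["p_adjusted"] = bh_adjust(dunn["p_raw"].to_numpy())
    return ChromTestResult(H=h, df=len(groups) - 1, p=p, dunn=dunn, groups=labels)


# ---------------------------------------------------------------------------
# candidate-region calling from top-percentile windows
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int  # 0-based half-open union of member windows
    n_windows: int
    peak_window: tuple[int, int]
    n_xy: int
    n_zw: int
    system_call: str  # XY | ZW | ambiguous

    @property
    def total(self) -> int:
        return self.n_xy + self.n_zw


def call_candidate_regions(
    selected: pd.DataFrame, window_size: int, max_gap: int = 1
) -> list[CandidateRegion]:
    """Merge selected windows into candidate regions.

    Same-chromosome selected windows separated by at most ``max_gap``
    unselected windows join one region.  Regions are returned ranked by
    total patterned-SNP count (descending), ties by (chrom, start).
    """
    regions: list[CandidateRegion] = []
    for chrom, grp in selected.groupby("chrom", observed=True, sort=False):
        grp = grp.sort_values("start")
        run: list[pd.Series] = []
        prev_end = None
        for _, row in grp.iterrows():
            if prev_end is not None and row["start"] - prev_end > max_gap * window_size:
                regions.append(_finish_region(chrom, run))
                run = []
            run.append(row)
            prev_end = row["end"]
        if run:
            regions.append(_finish_region(chrom, run))
    regions.sort(key=lambda r: (-r.total, r.chrom, r.start))
    return regions


def _finish_region(chrom: str, run: list[pd.Series]) -> CandidateRegion:
    n_xy = int(sum(r["n_xy"] for r in run))
    n_zw = int(sum(r["n_zw"] for r in run))
    peak = max(run, key=lambda r: r["n_xy"] + r["n_zw"])
    if n_xy > n_zw:
        call = "XY"
    elif n_zw > n_xy:
        call = "ZW"
    else:
        call = "ambiguous"
    return CandidateRegion(
        chrom=str(chrom),
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        n_windows=len(run),
        peak_window=(int(peak["start"]), int(peak["end"])),
        n_xy=n_xy,
        n_zw=n_zw,
        system_call=call,
    )
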