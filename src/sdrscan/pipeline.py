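"""End-to-end convenience wrapper: counts in, candidate regions out."""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .ranktests import CandidateRegion, ChromTestResult, call_candidate_regions, run_chrom_tests
from .sites import ClassifyParams, scan_sites
from .windows import DEFAULT_WINDOW_SIZE, count_in_windows, make_windows, top_percent


@dataclasses.dataclass
class ScanResult:
    classified: pd.DataFrame
    windows: pd.DataFrame
    top_windows: pd.DataFrame
    regions: list[CandidateRegion]
    chrom_test: ChromTestResult
    unanchored: dict[str, int]


def analyze(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: ClassifyParams | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    top_q: float = 0.01,
    max_gap: int = 1,
    alpha: float = 0.05,
    observations: str = "all",
) -> ScanResult:
    """Run the full scan: classify sites, window them, select the top
    fraction, test chromosomes, and call candidate regions."""
    classified = scan_sites(sites, params)
    windows = make_windows(chrom_lengths, size=window_size)
    windows, unanchored = count_in_windows(windows, classified, size=window_size)
    top = top_percent(windows, q=top_q)
    chrom_test = run_chrom_tests(windows, alpha=alpha, observations=observations, top=top)
    regions = call_candidate_regions(top, window_size=window_size, max_gap=max_gap)
    return ScanResult(
        classified=classified,
        windows=windows,
        top_windows=top,
        regions=regions,
        chrom_test=chrom_test,
        unanchored=unanchored,
    )
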