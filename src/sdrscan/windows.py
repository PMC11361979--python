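"""Fixed-size window aggregation of sex-patterned SNPs.

Windows tile each chromosome in 0-based half-open coordinates (the final
partial window is kept).  Each window carries its XY- and ZW-patterned
SNP counts and the log2 ratio of the two densities with a pseudocount,
and the top fraction of anchored windows by combined count can be
selected for region calling.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZE = 100_000


def make_windows(chrom_lengths: Mapping[str, int], size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``size`` bp.

    Returns a DataFrame with ``chrom, start, end, anchored`` where
    ``start``/``end`` are 0-based half-open.  Every chromosome in
    ``chrom_lengths`` is treated as anchored (chromosome-scale).
    """
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        edges = np.arange(0, length, size, dtype=np.int64)
        chroms.extend([chrom] * len(edges))
        starts.extend(edges.tolist())
        ends.extend(np.minimum(edges + size, length).tolist())
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "anchored": True,
        }
    )


def log2_ratio(n_xy, n_zw, pseudocount: float = 1.0):
    """log2((n_xy + c) / (n_zw + c)); the pseudocount keeps zero-count
    windows finite and maps them to 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((np.asarray(n_xy, dtype=float) + pseudocount) / (np.asarray(n_zw, dtype=float) + pseudocount))


def count_in_windows(
    windows: pd.DataFrame,
    classified: pd.DataFrame,
    size: int | None = None,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill ``n_xy``/``n_zw``/``log2_ratio`` for each window.

    A labeled site at 1-based position p lands in the window with
    start <= p-1 < end.  Sites on chromosomes absent from ``windows``
    are tallied as unanchored (returned in the dict), never an error.
    """
    windows = windows.copy()
    if size is None:
        size = int((windows["end"] - windows["start"]).max()) if len(windows) else DEFAULT_WINDOW_SIZE
    known = set(windows["chrom"])
    labeled = classified[classified["label"].isin(["XY", "ZW"])]
    on_chrom = labeled[labeled["chrom"].isin(known)]
    unanchored = (
        labeled[~labeled["chrom"].isin(known)].groupby("chrom", observed=True)["label"].count().to_dict()
    )

    if len(on_chrom):
        widx = (on_chrom["pos"].to_numpy(dtype=np.int64) - 1) // size
        key = pd.MultiIndex.from_arrays([on_chrom["chrom"], widx], names=["chrom", "widx"])
        counts = (
            pd.DataFrame({"label": on_chrom["label"].to_numpy()}, index=key)
            .groupby(level=["chrom", "widx"], observed=True)["label"]
            .value_counts()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    windows["widx"] = windows["start"] // size
    windows = windows.set_index(["chrom", "widx"])
    for lab, col in (("XY", "n_xy"), ("ZW", "n_zw")):
        if lab in getattr(counts, "columns", []):
            windows[col] = counts[lab].reindex(windows.index, fill_value=0).astype(np.int64)
        else:
            windows[col] = 0
    windows = windows.reset_index().drop(columns="widx")
    windows["log2_ratio"] = log2_ratio(windows["n_xy"], windows["n_zw"], pseudocount)
    return windows[["chrom", "start", "end", "anchored", "n_xy", "n_zw", "log2_ratio"]], unanchored


def top_percent(windows: pd.DataFrame, q: float = 0.01, mode: str = "joint") -> pd.DataFrame:
    """Select the top fraction ``q`` of anchored windows by patterned-SNP
    count and give each a dominant label.

    ``joint`` mode (default) ranks on n_xy + n_zw and selects
    ceil(q * n_anchored) windows; ``separate`` mode ranks XY and ZW
    densities independently and unions the two selections.  Ties at the
    cutoff break deterministically by chromosome order then start.
    Selected windows are labeled XY/ZW by the larger count, ``tie`` on
    equality.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    anchored = windows[windows["anchored"]].reset_index(drop=True)
    if anchored.empty:
        return anchored.assign(window_label=pd.Series(dtype=object))
    k = math.ceil(q * len(anchored))

    def pick(key: np.ndarray) -> pd.DataFrame:
        order = np.lexsort((anchored.index.to_numpy(), -key))  # stable: count desc, then input order
        return anchored.iloc[order[:k]]

    if mode == "joint":
        sel = pick((anchored["n_xy"] + anchored["n_zw"]).to_numpy())
    elif mode == "separate":
        sel = (
            pd.concat([pick(anchored["n_xy"].to_numpy()), pick(anchored["n_zw"].to_numpy())])
            .drop_duplicates(subset=["chrom", "start"])
        )
    else:
        raise ValueError(f"unknown top-percent mode {mode!r}")

    sel = sel.sort_index().reset_index(drop=True)
    lab = np.full(len(sel), "tie", dtype=object)
    lab[sel["n_xy"].to_numpy() > sel["n_zw"].to_numpy()] = "XY"
    lab[sel["n_zw"].to_numpy() > sel["n_xy"].to_numpy()] = "ZW"
    sel["window_label"] = lab
    return sel
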