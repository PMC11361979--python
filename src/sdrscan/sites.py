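"""Per-site statistics on pooled counts: allele frequencies, F_ST between
the sex pools, and XY/ZW pattern classification.

An XY-patterned SNP is one whose variant allele is effectively fixed in
the female pool (frequency below ``fixed_max``, or above ``1 -
fixed_max`` for the complementary allele) while segregating at
intermediate frequency (``poly_min``..``poly_max``) in the male pool —
the read-level signature of an allele carried on every Y and absent from
every X.  ZW-patterned SNPs are the mirror image.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BASES, FEMALE_COLS, MALE_COLS, PoolSiteCounts


@dataclasses.dataclass
class ClassifyParams:
    """Thresholds for sex-pattern classification and depth filtering.

    ``fixed_max`` is a strict bound ("fixed" means frequency < 0.1);
    ``poly_min``/``poly_max`` are inclusive ("polymorphic" means 0.3 <=
    f <= 0.7).  ``max_depth=None`` resolves to 3x the mean per-pool depth
    of the dataset being scanned.  ``noise_frac`` is the tolerated
    third-allele fraction before a site is dropped as triallelic.
    """

    fixed_max: float = 0.1
    poly_min: float = 0.3
    poly_max: float = 0.7
    min_depth: int = 10
    max_depth: float | None = None
    noise_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_max < self.poly_min <= self.poly_max <= 1:
            raise ValueError(
                "require 0 <= fixed_max < poly_min <= poly_max <= 1, got "
                f"({self.fixed_max}, {self.poly_min}, {self.poly_max})"
            )


def fst_site(p_male: float, p_female: float) -> float:
    """Per-site F_ST between the two sex pools (Wright/Nei form).

    With pbar = (p_m + p_f)/2, H_T = 2 pbar (1 - pbar) and H_S the mean
    within-pool heterozygosity, returns (H_T - H_S)/H_T, defined as 0
    when H_T = 0 (no variation).
    """
    arr = _fst_array(np.asarray([p_male], dtype=float), np.asarray([p_female], dtype=float))
    return float(arr[0])


def _fst_array(p_m: np.ndarray, p_f: np.ndarray) -> np.ndarray:
    if np.any((p_m < 0) | (p_m > 1) | (p_f < 0) | (p_f > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    pbar = (p_m + p_f) / 2.0
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = (2.0 * p_m * (1.0 - p_m) + 2.0 * p_f * (1.0 - p_f)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return np.clip(fst, 0.0, 1.0)


def classify_site(
    p_male: float,
    p_female: float,
    params: ClassifyParams | None = None,
    depths: tuple[float, float] | None = None,
    max_depth: float | None = None,
) -> str:
    """Label one site XY, ZW, or none.

    The fixed/polymorphic rule is evaluated for the variant allele and
    its complement, so fixation of either allele in one sex counts.  When
    ``depths`` (male, female) are given, a pool depth outside
    ``[min_depth, max_depth]`` returns ``none`` (the site is filtered).
    """
    params = params or ClassifyParams()
    if depths is not None:
        cap = max_depth if max_depth is not None else params.max_depth
        for d in depths:
            if d < params.min_depth or (cap is not None and d > cap):
                return "none"
    labels = _classify_array(
        np.asarray([p_male], dtype=float), np.asarray([p_female], dtype=float), params
    )
    return labels[0]


def _classify_array(p_m: np.ndarray, p_f: np.ndarray, params: ClassifyParams) -> np.ndarray:
    fixed_m = (p_m < params.fixed_max) | (p_m > 1.0 - params.fixed_max)
    fixed_f = (p_f < params.fixed_max) | (p_f > 1.0 - params.fixed_max)
    # polymorphic band is symmetric under p -> 1-p only when poly_min and
    # poly_max mirror each other; evaluate both alleles explicitly
    poly_m = ((params.poly_min <= p_m) & (p_m <= params.poly_max)) | (
        (params.poly_min <= 1.0 - p_m) & (1.0 - p_m <= params.poly_max)
    )
    poly_f = ((params.poly_min <= p_f) & (p_f <= params.poly_max)) | (
        (params.poly_min <= 1.0 - p_f) & (1.0 - p_f <= params.poly_max)
    )
    out = np.full(p_m.shape, "none", dtype=object)
    out[fixed_f & poly_m] = "XY"
    out[fixed_m & poly_f] = "ZW"
    return out


def reduce_biallelic(
    site: PoolSiteCounts, noise_frac: float = 0.1
) -> tuple[str, str] | None:
    """Reduce a site to its (major, variant) allele pair.

    The two highest-count bases across both pools become major and
    variant.  Returns None (drop) for monomorphic sites and for sites
    where a third base exceeds ``noise_frac`` of the total depth.
    """
    m = np.asarray(site.male_counts[:4], dtype=np.int64)
    f = np.asarray(site.female_counts[:4], dtype=np.int64)
    tot = m + f
    depth = int(tot.sum())
    if depth <= 0:
        return None
    order = np.argsort(tot, kind="stable")[::-1]
    if tot[order[1]] == 0:
        return None  # monomorphic
    if tot[order[2]] > noise_frac * depth:
        return None  # triallelic beyond noise
    return BASES[order[0]], BASES[order[1]]


def scan_sites(sites: pd.DataFrame, params: ClassifyParams | None = None) -> pd.DataFrame:
    """Classify every site in a site table (vectorized pipeline).

    Input columns are those produced by :func:`sdrscan.io.read_sync` or
    :func:`sdrscan.simulate.simulate_pools`.  Returns one row per input
    site with columns ``chrom, pos, major, variant, p_male, p_female,
    depth_male, depth_female, fst, label, filter_reason`` (empty reason
    for sites that passed all filters; ``label`` is ``none`` for every
    filtered or dropped site).
    """
    params = params or ClassifyParams()
    n = len(sites)
    m = sites[list(MALE_COLS[:4])].to_numpy(dtype=np.int64)
    f = sites[list(FEMALE_COLS[:4])].to_numpy(dtype=np.int64)
    tot = m + f
    depth_m = m.sum(axis=1)
    depth_f = f.sum(axis=1)
    depth = depth_m + depth_f

    # rank bases by combined count; argsort is stable so ties resolve by
    # base order A<T<C<G, deterministically
    order = np.argsort(tot, axis=1, kind="stable")[:, ::-1]
    idx = np.arange(n)
    major = order[:, 0]
    variant = order[:, 1]
    second = tot[idx, variant] if n else np.array([], dtype=np.int64)
    third = tot[idx, order[:, 2]] if n else np.array([], dtype=np.int64)

    reason = np.full(n, "", dtype=object)
    reason[depth == 0] = "zero_depth"
    mono = (reason == "") & (second == 0)
    reason[mono] = "monomorphic"
    tri = (reason == "") & (third > params.noise_frac * depth)
    reason[tri] = "triallelic"

    max_depth = params.max_depth
    if max_depth is None:
        mean_depth = (depth_m.mean() + depth_f.mean()) / 2.0 if n else 0.0
        max_depth = 3.0 * mean_depth
    low = (reason == "") & ((depth_m < params.min_depth) | (depth_f < params.min_depth))
    reason[low] = "low_depth"
    high = (reason == "") & ((depth_m > max_depth) | (depth_f > max_depth))
    reason[high] = "high_depth"

    with np.errstate(divide="ignore", invalid="ignore"):
        p_m = np.where(depth_m > 0, m[idx, variant] / np.where(depth_m > 0, depth_m, 1), np.nan)
        p_f = np.where(depth_f > 0, f[idx, variant] / np.where(depth_f > 0, depth_f, 1), np.nan)

    ok = reason == ""
    fst = np.full(n, np.nan)
    if ok.any():
        fst[ok] = _fst_array(p_m[ok], p_f[ok])
    label = np.full(n, "none", dtype=object)
    if ok.any():
        label[ok] = _classify_array(p_m[ok], p_f[ok], params)

    base_arr = np.asarray(BASES)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "major": base_arr[major] if n else np.array([], dtype=object),
            "variant": base_arr[variant] if n else np.array([], dtype=object),
            "p_male": p_m,
            "p_female": p_f,
            "depth_male": depth_m,
            "depth_female": depth_f,
            "fst": fst,
            "label": label,
            "filter_reason": reason,
        }
    )
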