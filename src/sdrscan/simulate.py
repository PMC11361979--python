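"""Synthetic pooled-sequencing data with a planted sex-determining region.

The generator emulates a pool-seq sex contrast: two sequencing pools (one
per sex) built from a sibship of diploid individuals, genotyped only
through pooled read counts.  Background SNPs are shared polymorphisms; a
narrow sex-determining region (SDR) carries a configurable fraction of
fully sex-linked sites where, in an XY system, every male is heterozygous
for the Y allele and no female carries it (ZW mirrors the sexes).

Individual genotypes are never materialized: for background sites the
pool's chromosome-sample allele frequency is drawn binomially from the
population frequency, and for fully linked sites it is exactly 0.5 in the
heterogametic pool and 0 in the homogametic pool.  Read counts are then
binomial in that frequency at a Poisson depth, with a symmetric per-base
miscall applied afterwards.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import BASES, FEMALE_COLS, MALE_COLS

_DEFAULT_SDR_WIDTH = 400_000


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated pool-seq sex contrast.

    Defaults mirror the study design the package targets: 23 XY males and
    26 XX females pooled per sex, ~100x pooled coverage per pool, one SNP
    per ~500 bp, and a ~400 kb SDR in which 30% of SNPs are fully
    sex-linked.
    """

    seed: int
    chrom_lengths: Mapping[str, int]
    n_males: int = 23
    n_females: int = 26
    snp_rate: float = 1 / 500
    coverage: float = 100.0
    error_rate: float = 0.002
    system: str = "XY"  # XY | ZW | none
    sdr_chrom: str | None = None
    sdr_interval: tuple[int, int] | None = None  # [start, end), 0-based bp
    sdr_linked_fraction: float = 0.3
    background_af_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("pool sizes must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.sdr_linked_fraction <= 1.0:
            raise ValueError("sdr_linked_fraction must be in [0, 1]")
        if self.system not in ("XY", "ZW", "none"):
            raise ValueError(f"unknown system {self.system!r}")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must name at least one chromosome")
        if self.system == "none":
            if self.sdr_linked_fraction != 0.0:
                raise ValueError("system='none' requires sdr_linked_fraction = 0")
            return
        if self.sdr_chrom is None:
            self.sdr_chrom = next(iter(self.chrom_lengths))
        if self.sdr_chrom not in self.chrom_lengths:
            raise ValueError(f"sdr_chrom {self.sdr_chrom!r} not in chrom_lengths")
        clen = self.chrom_lengths[self.sdr_chrom]
        if self.sdr_interval is None:
            width = min(_DEFAULT_SDR_WIDTH, clen)
            start = max(0, (clen - width) // 2)
            self.sdr_interval = (start, start + width)
        start, end = self.sdr_interval
        if not (0 <= start < end <= clen):
            raise ValueError(f"sdr_interval {self.sdr_interval} outside {self.sdr_chrom} (length {clen})")


@dataclasses.dataclass
class SdrTruth:
    """Ground truth for a simulated dataset.

    ``linked_sites`` maps the SDR chromosome's fully sex-linked SNPs
    (1-based positions); it is empty when ``system == 'none'``.
    """

    system: str
    sdr_chrom: str | None
    sdr_interval: tuple[int, int] | None
    linked_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.sdr_chrom, "pos": self.linked_sites})


def _apply_errors(counts: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Miscall each read with probability ``error_rate``, substituting one
    of the three other bases uniformly.  Mutates ``counts`` (n x 6) in place."""
    if error_rate <= 0:
        return
    for b in range(4):
        errs = rng.binomial(counts[:, b], error_rate)
        counts[:, b] -= errs
        others = [x for x in range(4) if x != b]
        redist = rng.multinomial(errs, [1 / 3, 1 / 3, 1 / 3])
        counts[:, others] += redist


def simulate_pools(config: SimulationConfig) -> tuple[pd.DataFrame, SdrTruth]:
    """Simulate one pooled sex-contrast dataset.

    Returns a site table (one row per simulated SNP, same columns as
    :func:`sdrscan.io.read_sync` produces) and the :class:`SdrTruth`.
    Output is reproducible for a fixed config, including the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_m_chrom = 2 * config.n_males
    n_f_chrom = 2 * config.n_females
    lo, hi = config.background_af_range

    frames: list[pd.DataFrame] = []
    linked_positions: list[np.ndarray] = []

    for chrom, length in config.chrom_lengths.items():
        n_sites = rng.binomial(length, config.snp_rate)
        if n_sites == 0:
            continue
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1  # 1-based
        ref = rng.integers(0, 4, size=n_sites)
        var = (ref + rng.integers(1, 4, size=n_sites)) % 4

        linked = np.zeros(n_sites, dtype=bool)
        if config.system != "none" and chrom == config.sdr_chrom:
            start, end = config.sdr_interval
            in_sdr = (pos > start) & (pos <= end)  # 1-based pos in [start, end)
            linked = in_sdr & (rng.random(n_sites) < config.sdr_linked_fraction)

        # chromosome-sample allele frequencies of the variant allele
        p = rng.uniform(lo, hi, size=n_sites)
        fm = rng.binomial(n_m_chrom, p) / n_m_chrom
        ff = rng.binomial(n_f_chrom, p) / n_f_chrom
        if config.system == "XY":
            fm[linked] = 0.5
            ff[linked] = 0.0
        elif config.system == "ZW":
            ff[linked] = 0.5
            fm[linked] = 0.0

        mcounts = np.zeros((n_sites, 6), dtype=np.int64)
        fcounts = np.zeros((n_sites, 6), dtype=np.int64)
        idx = np.arange(n_sites)
        for counts, freq in ((mcounts, fm), (fcounts, ff)):
            depth = rng.poisson(config.coverage, size=n_sites)
            var_reads = rng.binomial(depth, freq)
            counts[idx, var] += var_reads
            counts[idx, ref] += depth - var_reads
            _apply_errors(counts, config.error_rate, rng)

        frame = pd.DataFrame(
            {"chrom": chrom, "pos": pos.astype(np.int64), "ref": [BASES[r] for r in ref]}
        )
        for i, col in enumerate(MALE_COLS):
            frame[col] = mcounts[:, i]
        for i, col in enumerate(FEMALE_COLS):
            frame[col] = fcounts[:, i]
        frames.append(frame)
        if linked.any():
            linked_positions.append(pos[linked])

    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", *MALE_COLS, *FEMALE_COLS])
    )
    if config.system == "none":
        truth = SdrTruth("none", None, None, np.array([], dtype=np.int64))
    else:
        sites_arr = (
            np.concatenate(linked_positions) if linked_positions else np.array([], dtype=np.int64)
        )
        truth = SdrTruth(config.system, config.sdr_chrom, tuple(config.sdr_interval), sites_arr)
    return sites, truth


# ---------------------------------------------------------------------------
# toy protein alignments with planted X/Y changes
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: planted-change categories understood by :func:`simulate_msa`
CATEGORIES = ("shared", "x", "y", "both", "x_indel", "y_indel")


@dataclasses.dataclass
class PlantedChange:
    """One planted event in a toy alignment.

    ``column`` is 1-based.  ``ancestral`` is the residue carried by the
    outgroups (drawn at random when None).  Substitution categories use
    ``x_res``/``y_res``; ``shared`` plants the same derived residue on X
    and Y, ``both`` plants two different derived residues.  Indel
    categories delete ``length`` columns from the X (``x_indel``) or Y
    (``y_indel``) sequence.
    """

    column: int
    category: str
    ancestral: str | None = None
    x_res: str | None = None
    y_res: str | None = None
    length: int = 1

    def columns(self) -> range:
        n = self.length if self.category in ("x_indel", "y_indel") else 1
        return range(self.column, self.column + n)


def simulate_msa(
    seed: int,
    n_outgroups: int,
    length: int,
    planted_changes: list[PlantedChange],
) -> tuple[dict[str, str], dict[str, str], list[PlantedChange]]:
    """Build a labeled protein alignment with planted X/Y changes.

    Returns ``(sequences, roles, truth)`` where ``sequences`` maps id to
    gapped residue string, ``roles`` maps id to ``X``/``Y``/``outgroup``,
    and ``truth`` is the resolved planted-change list (ancestral residues
    filled in).  Every non-planted column is invariant across sequences.
    """
    if n_outgroups < 2:
        raise ValueError("need at least 2 outgroup sequences")
    occupied: set[int] = set()
    for ch in planted_changes:
        if ch.category not in CATEGORIES:
            raise ValueError(f"unknown category {ch.category!r}")
        for col in ch.columns():
            if not 1 <= col <= length:
                raise ValueError(f"planted column {col} outside alignment of length {length}")
            if col in occupied:
                raise ValueError(f"overlapping planted changes at column {col}")
            occupied.add(col)

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(AMINO_ACIDS), size=length)
    backbone = [AMINO_ACIDS[i] for i in base]

    truth: list[PlantedChange] = []
    x_seq = list(backbone)
    y_seq = list(backbone)
    out_seq = list(backbone)
    for ch in planted_changes:
        resolved = dataclasses.replace(ch)
        col0 = ch.column - 1
        anc = ch.ancestral or backbone[col0]
        out_seq[col0] = anc
        if ch.category in ("x_indel", "y_indel"):
            for col in ch.columns():
                out_seq[col - 1] = ch.ancestral or backbone[col - 1]
                x_seq[col - 1] = out_seq[col - 1]
                y_seq[col - 1] = out_seq[col - 1]
                target = x_seq if ch.category == "x_indel" else y_seq
                target[col - 1] = "-"
        else:
            x_seq[col0] = anc
            y_seq[col0] = anc
            if ch.category == "shared":
                if not ch.x_res or ch.x_res == anc:
                    raise ValueError("shared change needs a derived residue differing from ancestral")
                x_seq[col0] = y_seq[col0] = ch.x_res
                resolved.y_res = ch.x_res
            elif ch.category == "x":
                if not ch.x_res or ch.x_res == anc:
                    raise ValueError("x change needs x_res differing from ancestral")
                x_seq[col0] = ch.x_res
            elif ch.category == "y":
                if not ch.y_res or ch.y_res == anc:
                    raise ValueError("y change needs y_res differing from ancestral")
                y_seq[col0] = ch.y_res
            elif ch.category == "both":
                if not (ch.x_res and ch.y_res) or anc in (ch.x_res, ch.y_res) or ch.x_res == ch.y_res:
                    raise ValueError("both-derived change needs distinct x_res and y_res, both != ancestral")
                x_seq[col0] = ch.x_res
                y_seq[col0] = ch.y_res
        resolved.ancestral = anc
        truth.append(resolved)

    sequences = {"X": "".join(x_seq), "Y": "".join(y_seq)}
    roles = {"X": "X", "Y": "Y"}
    for i in range(n_outgroups):
        sid = f"outgroup_{i + 1}"
        sequences[sid] = "".join(out_seq)
        roles[sid] = "outgroup"
    return sequences, roles, sorted(truth, key=lambda c: c.column)
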