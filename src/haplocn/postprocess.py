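"""CNV region extraction, filtering, and fractional copy-number estimation.

A decoded genotype path marks each locus with an ordered pair of allelic
states.  Maximal runs where either haplotype carries a gain (resp. loss)
state become candidate regions; four filtering rules then remove the
fragmented and low-confidence calls:

1. single-SNP regions are excluded;
2. same-direction regions separated by one or two SNPs are merged, the gap
   loci being absorbed into the joined region;
3. regions with more than 4/5 of their SNPs flagged low-confidence (signal
   inside the shaded normal-genotype region) are excluded;
4. regions of fewer than four SNPs may not contain any shaded-region SNP.

Fractional allele copy numbers are interpolated from the M1/M5/M9 grid: one
grid step along the A axis is one A copy, with the BB center as the zero-A
baseline (and symmetrically for B); when the two per-copy increments differ
the larger is used as a conservative divisor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission_models import ModelBank
from .haplotype_tree import STATE_ALLELE, STATE_CLASS

__all__ = [
    "CNVRegion",
    "extract_regions",
    "filter_regions",
    "estimate_allelic_cn",
    "allelic_cn_matrix",
    "haplotype_cn_summary",
    "total_cn",
    "call_event",
]

_CLASS_OF = {"loss": 0, "gain": 2}


@dataclass
class CNVRegion:
    """A contiguous aberrant segment for one sample.

    ``start``/``end`` are inclusive SNP indices into the arrays the region
    was extracted from.  ``cn_a``/``cn_b`` hold per-SNP fractional allele
    copies (NaN = flagged missing), filled by the pipeline after filtering.
    """

    sample: int
    chrom: str
    start: int
    end: int
    direction: str  # 'gain' or 'loss'
    cn_a: np.ndarray | None = None
    cn_b: np.ndarray | None = None
    hap_cn: tuple[float, float] = (np.nan, np.nan)
    total_cn: float = np.nan
    low_conf: np.ndarray | None = None
    event: str = ""

    @property
    def n_snps(self) -> int:
        return self.end - self.start + 1

    def shifted(self, offset: int) -> "CNVRegion":
        """Copy with SNP indices moved by ``offset`` (chromosome -> genome)."""
        r = CNVRegion(
            self.sample, self.chrom, self.start + offset, self.end + offset,
            self.direction, self.cn_a, self.cn_b, self.hap_cn, self.total_cn,
            self.low_conf, self.event,
        )
        return r


def extract_regions(states: np.ndarray, sample: int = 0, chrom: str = "1") -> list[CNVRegion]:
    """Maximal runs where either haplotype carries a gain (or loss) state.

    Gains and losses never share a region; a locus carrying a gain on one
    haplotype and a loss on the other contributes to one region of each
    direction.
    """
    states = np.asarray(states)
    out: list[CNVRegion] = []
    for direction, cls in _CLASS_OF.items():
        mask = (STATE_CLASS[states] == cls).any(axis=1)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            out.append(CNVRegion(sample, chrom, int(idx[s]), int(idx[e]), direction))
    out.sort(key=lambda r: (r.start, r.direction))
    return out


def filter_regions(regions: list[CNVRegion], shaded: np.ndarray) -> list[CNVRegion]:
    """Apply the four filtering rules in order; idempotent.

    ``shaded`` is a per-SNP boolean low-confidence mask for the same sample
    and index space as the regions.
    """
    shaded = np.asarray(shaded, dtype=bool)
    # rule 1: drop singletons
    kept = [r for r in regions if r.n_snps >= 2]
    # rule 2: merge same-direction regions separated by <=2 SNPs
    merged: list[CNVRegion] = []
    for direction in ("gain", "loss"):
        for key in sorted({(r.sample, r.chrom) for r in kept}):
            group = sorted(
                (r for r in kept if r.direction == direction and (r.sample, r.chrom) == key),
                key=lambda r: r.start,
            )
            i = 0
            while i < len(group):
                cur = group[i]
                while i + 1 < len(group) and group[i + 1].start - cur.end - 1 <= 2:
                    nxt = group[i + 1]
                    cur = CNVRegion(cur.sample, cur.chrom, cur.start, max(cur.end, nxt.end), direction)
                    i += 1
                merged.append(cur)
                i += 1
    merged.sort(key=lambda r: (r.sample, r.chrom, r.start, r.direction))
    out: list[CNVRegion] = []
    for r in merged:
        low = shaded[r.start : r.end + 1]
        # rule 3: exclude when more than 4/5 of the SNPs are low confidence
        if low.sum() * 5 > 4 * r.n_snps:
            continue
        # rule 4: short regions tolerate no shaded SNP at all
        if r.n_snps < 4 and low.any():
            continue
        r.low_conf = low.copy()
        out.append(r)
    return out


def _increments(bank: ModelBank):
    """Per-copy signal increments and baselines from the M1/M5/M9 centers."""
    mu = bank.means
    base_a = mu[:, 9, 0]  # BB center: zero A copies
    delta_a = np.maximum(mu[:, 5, 0] - mu[:, 9, 0], mu[:, 1, 0] - mu[:, 5, 0])
    base_b = mu[:, 1, 1]  # AA center: zero B copies
    delta_b = np.maximum(mu[:, 5, 1] - mu[:, 1, 1], mu[:, 9, 1] - mu[:, 5, 1])
    return base_a, delta_a, base_b, delta_b


def estimate_allelic_cn(signal, bank: ModelBank, snp: int) -> tuple[float, float]:
    """Fractional (n_A, n_B) for one signal pair; NaN when the grid collapses."""
    base_a, delta_a, base_b, delta_b = _increments(bank)
    sa, sb = signal
    na = (sa - base_a[snp]) / delta_a[snp] if delta_a[snp] > 0 else np.nan
    nb = (sb - base_b[snp]) / delta_b[snp] if delta_b[snp] > 0 else np.nan
    return (float(max(na, 0.0)) if np.isfinite(na) else np.nan,
            float(max(nb, 0.0)) if np.isfinite(nb) else np.nan)


def allelic_cn_matrix(bank: ModelBank, a: np.ndarray, b: np.ndarray):
    """Vectorized fractional allele copy numbers, each (L, S)."""
    base_a, delta_a, base_b, delta_b = _increments(bank)
    with np.errstate(invalid="ignore", divide="ignore"):
        na = (a - base_a[:, None]) / delta_a[:, None]
        nb = (b - base_b[:, None]) / delta_b[:, None]
    na = np.where(delta_a[:, None] > 0, np.maximum(na, 0.0), np.nan)
    nb = np.where(delta_b[:, None] > 0, np.maximum(nb, 0.0), np.nan)
    return na, nb


def haplotype_cn_summary(region: CNVRegion, states: np.ndarray) -> tuple[float, float]:
    """Mean copy number per haplotype across the region's SNPs.

    At each SNP the allele carried by haplotype k decides whether n_A or
    n_B contributes to haplotype k's series.
    """
    sl = slice(region.start, region.end + 1)
    sub = np.asarray(states)[sl]  # (n, 2)
    out = []
    for k in range(2):
        is_b = STATE_ALLELE[sub[:, k]] == 1
        series = np.where(is_b, region.cn_b, region.cn_a)
        out.append(float(np.nanmean(series)) if np.isfinite(series).any() else np.nan)
    return out[0], out[1]


def total_cn(region: CNVRegion) -> float:
    """Mean of (n_A + n_B) over the region's SNPs."""
    tot = np.asarray(region.cn_a) + np.asarray(region.cn_b)
    return float(np.nanmean(tot)) if np.isfinite(tot).any() else np.nan


def call_event(total: float) -> str:
    """Event call from a region's fractional total copy number."""
    if not np.isfinite(total):
        return "normal"
    if total > 3.0:
        return "gain"
    if total < 1.0:
        return "loss"
    return "normal"
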