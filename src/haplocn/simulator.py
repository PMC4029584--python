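"""Synthetic diploid cohorts with known CNV haplotypes, and call evaluation.

The generator mirrors a haploid-pairing design: a pool of haploid
chromosomes with block-structured linkage disequilibrium carries implanted
gain/loss segments; diploids are formed by sampling two distinct haploids
with replacement, so aberrant segments recombine freely across samples and
may overlap between the two homologues.  Intensities are drawn from the
bivariate normal of the true genotypic state's emission model on a grid
with one intensity unit per allele copy, and the input genotype calls are
produced by a deliberately naive nearest-normal-cluster caller.

Calls are scored at four nested accuracy levels: region overlap (Rregion),
total copy number (Rtotal), allele-specific copy number (Rspecific) and
haplotype phase (Rhap); each level's denominator is the previous level's
numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emission_models import STATE_TO_MODEL, seed_bank
from .haplotype_tree import STATE_CLASS, STATE_COPIES, STATE_ALLELE
from .signal_io import GenotypeMatrix, SampleSignalSet, SeedClusters, SnpMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimCohort",
    "EvalReport",
    "simulate_cohort",
    "round_cn",
    "evaluate_calls",
    "truth_from_states",
]

_DIR_CLASS = {"gain": 2, "loss": 0}


@dataclass
class SimConfig:
    """Study design of one synthetic cohort; ``seed`` fixes all randomness."""

    n_haploids: int = 45  # haploid chromosomes in the pool
    n_diploids: int = 90  # samples formed by random pairing
    n_snps: int = 2000
    block_mean_len: int = 20  # geometric mean LD-block length (SNPs)
    n_founders: int = 4  # distinct haplotypes per LD block
    events_per_haploid: int = 3
    event_min_snps: int = 10
    event_max_snps: int = 50
    gain_fraction: float = 0.5  # gain:loss ratio of implanted events
    grid_spacing: float = 1.0  # intensity units per allele copy
    noise_sd: float = 0.2  # isotropic cluster noise (spacing/sd >= 4)
    mean_spacing_bp: int = 3000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_haploids, self.n_diploids, self.n_snps, self.n_founders) < 1:
            raise ValueError("counts must be positive")
        if self.n_haploids < 2:
            raise ValueError("need at least two haploids to pair")
        if not 1 <= self.event_min_snps <= self.event_max_snps:
            raise ValueError("bad event length range")


@dataclass
class SimTruth:
    """Generating states and derived integer copy numbers of a cohort."""

    hap_states: np.ndarray  # (S, L, 2) allelic-state codes
    cn_a: np.ndarray  # (L, S) true total A copies
    cn_b: np.ndarray  # (L, S) true total B copies
    regions: list  # (sample, direction, start, end) joint aberrant runs
    haploid_index: np.ndarray  # (S, 2) pool indices of each sample's haploids


@dataclass
class SimCohort:
    signals: SampleSignalSet
    genotypes: GenotypeMatrix
    seeds: SeedClusters
    truth: SimTruth
    config: SimConfig


def truth_from_states(hap_states: np.ndarray):
    """Derive per-SNP true allele copies and joint aberrant runs from states.

    ``hap_states`` is (S, L, 2).  Returns ``(cn_a (L,S), cn_b (L,S),
    regions)`` where regions are maximal runs, per sample and direction, of
    loci where at least one haplotype is aberrant in that direction.
    """
    hs = np.asarray(hap_states)
    S_, L, _ = hs.shape
    copies = STATE_COPIES[hs]  # (S, L, 2)
    is_b = STATE_ALLELE[hs] == 1
    cn_a = np.where(~is_b, copies, 0).sum(axis=2).T.astype(np.int64)
    cn_b = np.where(is_b, copies, 0).sum(axis=2).T.astype(np.int64)
    regions = []
    cls = STATE_CLASS[hs]
    for s in range(S_):
        for direction, c in _DIR_CLASS.items():
            mask = (cls[s] == c).any(axis=1)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            brk = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([0], brk + 1))
            ends = np.concatenate((brk, [idx.size - 1]))
            for i, k in zip(starts, ends):
                regions.append((s, direction, int(idx[i]), int(idx[k])))
    regions.sort()
    return cn_a, cn_b, regions


def _implant_events(rng, L: int, cfg: SimConfig) -> np.ndarray:
    """Copy-number class per locus (0 loss / 1 normal / 2 gain) for one haploid."""
    cls = np.ones(L, dtype=np.int8)
    placed: list[tuple[int, int]] = []
    for _ in range(cfg.events_per_haploid):
        for _try in range(100):
            n = int(rng.integers(cfg.event_min_snps, cfg.event_max_snps + 1))
            if n >= L:
                break
            start = int(rng.integers(0, L - n + 1))
            # keep a 1-SNP buffer so distinct events stay distinct runs
            if all(start > e + 1 or start + n < s - 1 for s, e in placed):
                placed.append((start, start + n - 1))
                direction = 2 if rng.random() < cfg.gain_fraction else 0
                cls[start : start + n] = direction
                break
    return cls


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate one cohort; identical configs yield byte-identical cohorts."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps

    # SNP map with irregular spacing around the configured mean
    lo, hi = max(1, cfg.mean_spacing_bp // 3), cfg.mean_spacing_bp * 5 // 3
    pos = 1 + np.cumsum(rng.integers(lo, hi + 1, size=L))
    snps = SnpMap(np.array([f"snp{i+1}" for i in range(L)]), np.array([cfg.chrom] * L), pos)

    # block-structured haplotype pool: founders per block, haploids pick one
    founder_alleles = np.empty((cfg.n_founders, L), dtype=np.int8)
    block_starts = [0]
    while block_starts[-1] < L:
        block_starts.append(block_starts[-1] + int(rng.geometric(1.0 / cfg.block_mean_len)))
    block_starts[-1] = L
    hap_alleles = np.empty((cfg.n_haploids, L), dtype=np.int8)
    for bi in range(len(block_starts) - 1):
        s, e = block_starts[bi], block_starts[bi + 1]
        freq_b = rng.uniform(0.1, 0.9, size=e - s)
        founder_alleles[:, s:e] = (rng.random((cfg.n_founders, e - s)) < freq_b).astype(np.int8)
        weights = rng.dirichlet(np.ones(cfg.n_founders))
        choice = rng.choice(cfg.n_founders, size=cfg.n_haploids, p=weights)
        hap_alleles[:, s:e] = founder_alleles[choice, s:e]

    hap_class = np.stack([_implant_events(rng, L, cfg) for _ in range(cfg.n_haploids)])

    # pair two distinct haploids per diploid, sampling with replacement
    hap_idx = np.empty((cfg.n_diploids, 2), dtype=np.int64)
    hap_idx[:, 0] = rng.integers(0, cfg.n_haploids, size=cfg.n_diploids)
    second = rng.integers(0, cfg.n_haploids - 1, size=cfg.n_diploids)
    hap_idx[:, 1] = second + (second >= hap_idx[:, 0])

    # allelic state = 3*allele + copy-number class
    hs = (3 * hap_alleles[hap_idx] + hap_class[hap_idx]).transpose(0, 2, 1).astype(np.int8)
    cn_a, cn_b, regions = truth_from_states(hs)
    truth = SimTruth(hs, cn_a, cn_b, regions, hap_idx)

    # seed clusters: one intensity unit per allele copy, isotropic noise
    d = cfg.grid_spacing
    anchor_means = np.array([[2 * d, 0.0], [d, d], [0.0, 2 * d]])
    cov = cfg.noise_sd**2 * np.eye(2)
    seeds = SeedClusters(
        np.broadcast_to(anchor_means, (L, 3, 2)).copy(),
        np.broadcast_to(cov, (L, 3, 2, 2)).copy(),
    )
    bank = seed_bank(seeds)

    pair_idx = 6 * hs[:, :, 0].astype(int) + hs[:, :, 1].astype(int)  # (S, L)
    model = STATE_TO_MODEL[pair_idx]
    centers = bank.means[np.arange(L)[None, :], model]  # (S, L, 2)
    noise = rng.standard_normal((cfg.n_diploids, L, 2)) * cfg.noise_sd
    sig = centers + noise
    a = sig[:, :, 0].T.copy()
    b = sig[:, :, 1].T.copy()
    samples = [f"sim{i+1:03d}" for i in range(cfg.n_diploids)]
    signals = SampleSignalSet(snps, samples, a, b)

    # naive caller: nearest of the three normal clusters
    da = a[:, :, None] - anchor_means[None, None, :, 0]
    db = b[:, :, None] - anchor_means[None, None, :, 1]
    calls = (da**2 + db**2).argmin(axis=2).astype(np.int8) + 1
    genotypes = GenotypeMatrix(calls)

    return SimCohort(signals, genotypes, seeds, truth, cfg)


def round_cn(x: float) -> int:
    """Round a fractional copy number to its reported integer.

    Anything between 0.5 and 1.5 (inclusive) is one copy; elsewhere
    half-points round down (2.5 -> 2), i.e. toward the normal diploid band.
    """
    if not np.isfinite(x):
        raise ValueError("cannot round a non-finite copy number")
    if 0.5 <= x <= 1.5:
        return 1
    return max(int(math.ceil(x - 0.5)), 0)


@dataclass
class EvalReport:
    """Nested accuracy ratios with their numerator/denominator counts."""

    region: tuple[int, int]  # overlapping predicted regions / predicted
    total: tuple[int, int]  # correct total CN / overlapping
    specific: tuple[int, int]  # correct allelic-CN SNPs / SNPs in correct regions
    hap: tuple[int, int]  # correctly phased SNPs / correct allelic-CN SNPs

    @staticmethod
    def _ratio(num_den) -> float:
        num, den = num_den
        return num / den if den else float("nan")

    @property
    def r_region(self) -> float:
        return self._ratio(self.region)

    @property
    def r_total(self) -> float:
        return self._ratio(self.total)

    @property
    def r_specific(self) -> float:
        return self._ratio(self.specific)

    @property
    def r_hap(self) -> float:
        return self._ratio(self.hap)

    def as_dict(self) -> dict:
        return {
            "Rregion": self.r_region,
            "Rtotal": self.r_total,
            "Rspecific": self.r_specific,
            "Rhap": self.r_hap,
            "counts": {
                "region": self.region,
                "total": self.total,
                "specific": self.specific,
                "hap": self.hap,
            },
        }


def evaluate_calls(result, truth: SimTruth) -> EvalReport:
    """Score a :class:`haplocn.decoder.PipelineResult` against the truth.

    A predicted region overlaps when it shares at least one SNP with a true
    aberrant run of the same sample.  Total copy number is compared after
    rounding, averaging the true per-SNP totals over the predicted span.
    Allelic copy numbers are compared per SNP after rounding; haplotype
    phase is scored under the better of the two haplotype labelings per
    region (labels are arbitrary up to a global swap).
    """
    true_by_sample: dict[int, list] = {}
    for s, direction, st, en in truth.regions:
        true_by_sample.setdefault(s, []).append((st, en))
    true_total = truth.cn_a + truth.cn_b  # (L, S)

    n_pred = n_overlap = n_total_ok = 0
    n_snp = n_snp_ok = n_phase_den = n_phase_ok = 0
    for r in result.regions:
        n_pred += 1
        spans = true_by_sample.get(r.sample, [])
        if not any(st <= r.end and en >= r.start for st, en in spans):
            continue
        n_overlap += 1
        sl = slice(r.start, r.end + 1)
        if not np.isfinite(r.total_cn):
            continue
        true_mean = float(true_total[sl, r.sample].mean())
        if round_cn(r.total_cn) != round_cn(true_mean):
            continue
        n_total_ok += 1
        # allele-specific level, SNP by SNP
        pa, pb = np.asarray(r.cn_a), np.asarray(r.cn_b)
        ok = np.zeros(r.n_snps, dtype=bool)
        for i in range(r.n_snps):
            n_snp += 1
            if not (np.isfinite(pa[i]) and np.isfinite(pb[i])):
                continue
            if (
                round_cn(pa[i]) == truth.cn_a[r.start + i, r.sample]
                and round_cn(pb[i]) == truth.cn_b[r.start + i, r.sample]
            ):
                ok[i] = True
                n_snp_ok += 1
        if not ok.any():
            continue
        # phase level: best of the two global labelings over the region
        pred = result.paths[r.sample, sl]  # (n, 2)
        ts = truth.hap_states[r.sample, sl]
        matches = []
        for perm in ((0, 1), (1, 0)):
            m = (pred[:, 0] == ts[:, perm[0]]) & (pred[:, 1] == ts[:, perm[1]])
            matches.append(m & ok)
        best = max(matches, key=lambda m: int(m.sum()))
        n_phase_den += int(ok.sum())
        n_phase_ok += int(best.sum())

    return EvalReport(
        (n_overlap, n_pred),
        (n_total_ok, n_overlap),
        (n_snp_ok, n_snp),
        (n_phase_ok, n_phase_den),
    )
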