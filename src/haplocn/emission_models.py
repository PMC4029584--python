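"""The eleven bivariate-normal emission models per SNP.

Signal space is (s_A, s_B): x = A-allele intensity, y = B-allele intensity.
The 36 ordered genotypic states (six allelic states per haplotype) partition
into 11 groups with indistinguishable expected signals, M0..M10.  At
initiation the AA/AB/BB seed clusters anchor a rectangular grid of centers:
the A-axis takes the three seed A-means (a_hi > a_mid > a_lo) and the B-axis
the three seed B-means; M0 and M10 extrapolate one grid step beyond M1 and
M9 respectively, so that dist(M1, M0) = dist(M1, M4) along the A axis and
dist(M9, M10) = dist(M9, M8) along the B axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .haplotype_tree import AllelicState
from .signal_io import SeedClusters

__all__ = [
    "EmissionModel",
    "ModelBank",
    "MODEL_MEMBERS",
    "STATE_TO_MODEL",
    "seed_models",
    "seed_bank",
    "mahalanobis",
    "select_group",
    "emission_logdensity",
    "in_shaded_region",
    "update_models",
    "grid_centers",
]

S = AllelicState
#: ordered genotypic states (haplotype 1, haplotype 2) belonging to each model
MODEL_MEMBERS: tuple[tuple[tuple[int, int], ...], ...] = (
    # M0: A present on both chromosomes, total A copies > 2, no B
    ((S.A_PLUS, S.A_PLUS), (S.A_PLUS, S.A), (S.A, S.A_PLUS)),
    # M1: total A copies ~2, B barely present
    ((S.A, S.A), (S.A_MINUS, S.A_PLUS), (S.A_PLUS, S.A_MINUS), (S.A_PLUS, S.B_MINUS), (S.B_MINUS, S.A_PLUS)),
    # M2: amplified A with one normal B
    ((S.A_PLUS, S.B), (S.B, S.A_PLUS)),
    # M3: gains on both chromosomes
    ((S.A_PLUS, S.B_PLUS), (S.B_PLUS, S.A_PLUS)),
    # M4: one normal A, the other chromosome below one copy
    ((S.A, S.B_MINUS), (S.B_MINUS, S.A), (S.A, S.A_MINUS), (S.A_MINUS, S.A)),
    # M5: normal heterozygote
    ((S.A, S.B), (S.B, S.A)),
    # M6: amplified B with one normal A (mirror of M2)
    ((S.A, S.B_PLUS), (S.B_PLUS, S.A)),
    # M7: losses on both chromosomes
    ((S.B_MINUS, S.B_MINUS), (S.A_MINUS, S.A_MINUS), (S.A_MINUS, S.B_MINUS), (S.B_MINUS, S.A_MINUS)),
    # M8: one normal B, the other chromosome below one copy (mirror of M4)
    ((S.A_MINUS, S.B), (S.B, S.A_MINUS), (S.B, S.B_MINUS), (S.B_MINUS, S.B)),
    # M9: total B copies ~2, A barely present (mirror of M1)
    ((S.B, S.B), (S.B_MINUS, S.B_PLUS), (S.B_PLUS, S.B_MINUS), (S.B_PLUS, S.A_MINUS), (S.A_MINUS, S.B_PLUS)),
    # M10: B present on both chromosomes, total B copies > 2 (mirror of M0)
    ((S.B_PLUS, S.B_PLUS), (S.B_PLUS, S.B), (S.B, S.B_PLUS)),
)

#: pair-state index (6*h1 + h2) -> model id; the models partition all 36 states
STATE_TO_MODEL = np.full(36, -1, dtype=np.int8)
for _mid, _members in enumerate(MODEL_MEMBERS):
    for _h1, _h2 in _members:
        _p = 6 * int(_h1) + int(_h2)
        if STATE_TO_MODEL[_p] != -1:
            raise AssertionError("genotypic state assigned to two models")
        STATE_TO_MODEL[_p] = _mid
if (STATE_TO_MODEL < 0).any():
    raise AssertionError("genotypic state missing from the model partition")

_ANCHORS = (1, 5, 9)  # models seeded directly from the AA/AB/BB clusters


@dataclass
class EmissionModel:
    """One bivariate normal model: center, covariance and member states."""

    id: int
    mean: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2)

    @property
    def members(self) -> tuple[tuple[int, int], ...]:
        return MODEL_MEMBERS[self.id]


def _ridge(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and, if needed, ridge-regularize a 2x2 covariance."""
    cov = 0.5 * (cov + cov.T)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 1e-12 * max(np.trace(cov) ** 2, 1e-12) or cov[0, 0] <= 0 or cov[1, 1] <= 0:
        tr = np.trace(cov)
        eps = 1e-6 * (tr / 2 if tr > 0 else 1.0)
        cov = cov + eps * np.eye(2)
        if cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2 <= 0:
            cov = cov + max(1e-6, abs(cov[0, 1])) * np.eye(2)
    return cov


def grid_centers(m1: np.ndarray, m5: np.ndarray, m9: np.ndarray) -> np.ndarray:
    """Eleven model centers from the three anchor centers (AA, AB, BB)."""
    a_hi, b_lo = m1
    a_mid, b_mid = m5
    a_lo, b_hi = m9
    return np.array(
        [
            (a_hi + (a_hi - a_mid), b_lo),  # M0
            (a_hi, b_lo),  # M1
            (a_hi, b_mid),  # M2
            (a_hi, b_hi),  # M3
            (a_mid, b_lo),  # M4
            (a_mid, b_mid),  # M5
            (a_mid, b_hi),  # M6
            (a_lo, b_lo),  # M7
            (a_lo, b_mid),  # M8
            (a_lo, b_hi),  # M9
            (a_lo, b_hi + (b_hi - b_mid)),  # M10
        ]
    )


def _extend(anchor_means: np.ndarray, anchor_covs: np.ndarray):
    """Grid centers plus nearest-anchor covariance inheritance (ties -> AB)."""
    centers = grid_centers(*anchor_means)
    covs = np.empty((11, 2, 2))
    for mid in range(11):
        d = np.linalg.norm(centers[mid] - anchor_means, axis=1)
        # ties resolve to the AB anchor (index 1)
        best = min(range(3), key=lambda k: (round(d[k] - d.min(), 12) != 0, k != 1))
        covs[mid] = anchor_covs[best]
    return centers, covs


def seed_models(seeds: SeedClusters, snp: int, fallback=None):
    """Build the 11 models for one SNP from its AA/AB/BB seed clusters.

    Returns ``(means (11,2), covs (11,2,2), degenerate: bool)``.  Seeds are
    degenerate when the grid coordinates are not strictly ordered
    (a_hi > a_mid > a_lo and b_hi > b_mid > b_lo); then ``fallback`` —
    a (means, covs) anchor pair, e.g. the cohort median — is used instead.
    """
    anchor_means = seeds.means[snp]  # rows: AA, AB, BB
    anchor_covs = seeds.covs[snp]
    a_hi, a_mid, a_lo = anchor_means[:, 0]
    b_lo, b_mid, b_hi = anchor_means[:, 1]
    degenerate = not (a_hi > a_mid > a_lo and b_hi > b_mid > b_lo)
    if degenerate:
        if fallback is None:
            raise ValueError(f"degenerate seed geometry at SNP {snp} and no fallback")
        anchor_means, anchor_covs = fallback
    centers, covs = _extend(anchor_means, anchor_covs)
    for mid in range(11):
        covs[mid] = _ridge(covs[mid])
    return centers, covs, degenerate


@dataclass
class ModelBank:
    """Per-SNP arrays of the 11 emission models, with cached inverses."""

    means: np.ndarray  # (L, 11, 2)
    covs: np.ndarray  # (L, 11, 2, 2)
    flagged: np.ndarray  # (L,) degenerate-seed flags

    def __post_init__(self) -> None:
        self._inv = None
        self._logdet = None

    @property
    def n_snps(self) -> int:
        return self.means.shape[0]

    def _cache(self):
        if self._inv is None:
            c = self.covs
            det = c[..., 0, 0] * c[..., 1, 1] - c[..., 0, 1] * c[..., 1, 0]
            inv = np.empty_like(c)
            inv[..., 0, 0] = c[..., 1, 1] / det
            inv[..., 1, 1] = c[..., 0, 0] / det
            inv[..., 0, 1] = -c[..., 0, 1] / det
            inv[..., 1, 0] = -c[..., 1, 0] / det
            self._inv, self._logdet = inv, np.log(det)
        return self._inv, self._logdet

    def model(self, snp: int, mid: int) -> EmissionModel:
        return EmissionModel(mid, self.means[snp, mid], self.covs[snp, mid])

    def distances_sq(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distances, shape (L, S, 11)."""
        inv, _ = self._cache()
        da = a[:, :, None] - self.means[:, None, :, 0]  # (L, S, 11)
        db = b[:, :, None] - self.means[:, None, :, 1]
        return (
            inv[:, None, :, 0, 0] * da**2
            + 2.0 * inv[:, None, :, 0, 1] * da * db
            + inv[:, None, :, 1, 1] * db**2
        )

    def logdensity(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Bivariate-normal log densities, shape (L, S, 11)."""
        _, logdet = self._cache()
        d2 = self.distances_sq(a, b)
        return -np.log(2 * np.pi) - 0.5 * logdet[:, None, :] - 0.5 * d2

    def to_table(self):
        """Serialize to rows (snp, model, mean_a, mean_b, var_a, cov_ab, var_b)."""
        rows = []
        for snp in range(self.n_snps):
            for mid in range(11):
                m, c = self.means[snp, mid], self.covs[snp, mid]
                rows.append((snp, mid, m[0], m[1], c[0, 0], c[0, 1], c[1, 1]))
        return rows


def seed_bank(seeds: SeedClusters) -> ModelBank:
    """Seed a full per-SNP model bank; degenerate SNPs fall back to the
    cohort-median anchor geometry and are flagged."""
    med = (np.median(seeds.means, axis=0), np.median(seeds.covs, axis=0))
    L = seeds.means.shape[0]
    means = np.empty((L, 11, 2))
    covs = np.empty((L, 11, 2, 2))
    flagged = np.zeros(L, dtype=bool)
    for snp in range(L):
        means[snp], covs[snp], flagged[snp] = seed_models(seeds, snp, fallback=med)
    return ModelBank(means, covs, flagged)


def mahalanobis(signal, model: EmissionModel) -> float:
    """Mahalanobis distance sqrt((s-mu)' Sigma^-1 (s-mu)) of a signal pair."""
    diff = np.asarray(signal, dtype=float) - model.mean
    cov = model.cov
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    if det <= 0:
        warnings.warn(f"singular covariance in model M{model.id}; ridge applied")
        cov = _ridge(cov)
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    return float(np.sqrt(diff @ inv @ diff))


def select_group(signal, bank: ModelBank, snp: int) -> int:
    """Model id with the smallest Mahalanobis distance; ties -> lowest id."""
    d = [mahalanobis(signal, bank.model(snp, mid)) for mid in range(11)]
    return int(np.argmin(d))


def emission_logdensity(signal, state: tuple[int, int], bank: ModelBank, snp: int) -> float:
    """Log density of a signal under the model owning the ordered state pair."""
    h1, h2 = state
    mid = int(STATE_TO_MODEL[6 * int(h1) + int(h2)])
    model = bank.model(snp, mid)
    d = mahalanobis(signal, model)
    cov = _ridge(model.cov)
    logdet = float(np.log(cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]))
    return -np.log(2 * np.pi) - 0.5 * logdet - 0.5 * d * d


def in_shaded_region(signal, bank: ModelBank, snp: int, quantile: float = 0.99) -> bool:
    """Whether a signal lies in the union of the normal-genotype ellipses.

    The shaded region covers most probe signals of the three normal
    genotypes: the Mahalanobis ellipses of M1, M5 and M9 at the chi2(2)
    ``quantile`` radius (boundary inclusive).
    """
    r2 = chi2.ppf(quantile, df=2)
    return any(mahalanobis(signal, bank.model(snp, mid)) ** 2 <= r2 for mid in _ANCHORS)


def shaded_mask(bank: ModelBank, a: np.ndarray, b: np.ndarray, quantile: float = 0.99) -> np.ndarray:
    """Vectorized shaded-region membership, shape (L, S)."""
    r2 = chi2.ppf(quantile, df=2)
    d2 = bank.distances_sq(a, b)
    return (d2[:, :, _ANCHORS] <= r2).any(axis=2)


def update_models(bank: ModelBank, assignments: np.ndarray, a: np.ndarray, b: np.ndarray) -> ModelBank:
    """Re-estimate model parameters from one decoding pass.

    ``assignments`` is (L, S) of decoded model ids.  Each model's mean is
    the sample mean of its member signals at that SNP across samples and the
    covariance the sample covariance.  Models with fewer than two members
    are re-seeded by extending the grid from the updated M1/M5/M9 anchors
    (anchors themselves keep their previous parameters when under-populated).
    """
    L, nS = assignments.shape
    cnt = np.empty((L, 11))
    mean = np.empty((L, 11, 2))
    cov = np.empty((L, 11, 2, 2))
    for mid in range(11):
        mask = assignments == mid
        n = mask.sum(axis=1)
        cnt[:, mid] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            sa = (a * mask).sum(axis=1)
            sb = (b * mask).sum(axis=1)
            mu_a, mu_b = sa / n, sb / n
            mean[:, mid, 0], mean[:, mid, 1] = mu_a, mu_b
            n1 = np.maximum(n - 1, 1)
            cov[:, mid, 0, 0] = ((a**2 * mask).sum(axis=1) - n * mu_a**2) / n1
            cov[:, mid, 1, 1] = ((b**2 * mask).sum(axis=1) - n * mu_b**2) / n1
            cab = ((a * b * mask).sum(axis=1) - n * mu_a * mu_b) / n1
            cov[:, mid, 0, 1] = cov[:, mid, 1, 0] = cab

    new_means = bank.means.copy()
    new_covs = bank.covs.copy()
    # anchors first: keep previous values where under-populated
    for mid in _ANCHORS:
        ok = cnt[:, mid] >= 2
        new_means[ok, mid] = mean[ok, mid]
        new_covs[ok, mid] = cov[ok, mid]
    for snp in range(L):
        anchor_means = new_means[snp, list(_ANCHORS)]
        a_hi, a_mid_, a_lo = anchor_means[:, 0]
        b_lo, b_mid_, b_hi = anchor_means[:, 1]
        if not (a_hi > a_mid_ > a_lo and b_hi > b_mid_ > b_lo):
            # updated anchors lost their grid ordering: keep previous models
            continue
        ext_means, ext_covs = _extend(anchor_means, new_covs[snp, list(_ANCHORS)])
        for mid in range(11):
            if mid in _ANCHORS:
                continue
            if cnt[snp, mid] >= 2:
                new_means[snp, mid] = mean[snp, mid]
                new_covs[snp, mid] = cov[snp, mid]
            else:
                new_means[snp, mid] = ext_means[mid]
                new_covs[snp, mid] = ext_covs[mid]
    for snp in range(L):
        for mid in range(11):
            new_covs[snp, mid] = _ridge(new_covs[snp, mid])
    return ModelBank(new_means, new_covs, bank.flagged.copy())
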