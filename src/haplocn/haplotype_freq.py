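"""Two-locus haplotype-proportion estimation by EM.

For every pair of consecutive loci the cohort's 3x3 genotype count table is
reduced to proportions of the four haplotype sets A-A, A-B, B-A and B-B.
Eight of the nine genotype combinations resolve unambiguously; the double
heterozygote (AB, AB) is a mixture of A-A/B-B and A-B/B-A phases, whose
A-A/B-B share q is estimated jointly with the proportions:

    h_AA = 2 N11 + N12 + N21 + q N22        alpha = h / (2N)
    h_AB = 2 N13 + N12 + N23 + (1-q) N22
    h_BA = 2 N31 + N21 + N32 + (1-q) N22    q' = a_AA a_BB /
    h_BB = 2 N33 + N23 + N32 + q N22             (a_AA a_BB + a_AB a_BA)

starting from q0 = 0.5 and iterating until |q' - q| < 1e-5.  This is the
classic phase-ambiguity EM for two biallelic loci; q's update is the
posterior phase probability of a double heterozygote under random pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import GenotypeMatrix

__all__ = [
    "PairCounts",
    "HaplotypeProportions",
    "ConditionalTable",
    "ConvergenceError",
    "count_genotype_pairs",
    "em_haplotype_proportions",
    "em_batch",
    "conditional_probabilities",
    "pairwise_tables",
    "tables_from_haplotypes",
    "pair_loglik",
]

#: haplotype-set order used everywhere: A-A, A-B, B-A, B-B
HAPLOTYPE_SETS = ("AA", "AB", "BA", "BB")


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the last parameter state."""

    def __init__(self, msg: str, last: "HaplotypeProportions"):
        super().__init__(msg)
        self.last = last


@dataclass
class PairCounts:
    """3x3 genotype count table N[g-1, h-1] for genotype codes g, h in {1,2,3}."""

    table: np.ndarray  # (3, 3) int
    n: int

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (3, 3) or (self.table < 0).any():
            raise ValueError("pair counts must be a non-negative 3x3 table")
        if self.table.sum() != self.n:
            raise ValueError("pair counts must sum to the sample count")


@dataclass
class HaplotypeProportions:
    """Estimated proportions (alpha) of the four haplotype sets plus phase share q."""

    alpha: np.ndarray  # (4,) in HAPLOTYPE_SETS order
    q: float
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (4,) or np.any(self.alpha < -1e-12) or np.any(self.alpha > 1 + 1e-12):
            raise ValueError("alpha out of range")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must sum to 1")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q out of [0,1]")


@dataclass
class ConditionalTable:
    """Joint (J) and conditional (C) allele-transition probabilities between two loci.

    ``c[x, y] = P(allele y at j+1 | allele x at j)``; allele index 0 = A,
    1 = B.  Rows whose marginal vanished are set to (0.5, 0.5) and flagged.
    """

    c: np.ndarray  # (2, 2)
    j: np.ndarray  # (2, 2)
    flagged_rows: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.j = np.asarray(self.j, dtype=float)
        if not np.allclose(self.c.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")


def count_genotype_pairs(genos: GenotypeMatrix, j: int) -> PairCounts:
    """Tabulate the 3x3 genotype counts between loci ``j`` and ``j+1``."""
    L = genos.calls.shape[0]
    if not 0 <= j < L - 1:
        raise IndexError(f"locus index {j} out of range for {L} loci")
    g, h = genos.calls[j], genos.calls[j + 1]
    if (g == 0).any() or (h == 0).any():
        raise ValueError("pair counting requires fully imputed genotypes")
    table = np.bincount(3 * (g - 1) + (h - 1), minlength=9).reshape(3, 3)
    return PairCounts(table, genos.calls.shape[1])


def _em_updates(tables: np.ndarray, q: np.ndarray):
    """One EM sweep on stacked (P,3,3) tables; returns (alpha (P,4), q' (P))."""
    N = tables.sum(axis=(1, 2))
    t = tables
    h = np.stack(
        [
            2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0] + q * t[:, 1, 1],
            2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2] + (1 - q) * t[:, 1, 1],
            2 * t[:, 2, 0] + t[:, 1, 0] + t[:, 2, 1] + (1 - q) * t[:, 1, 1],
            2 * t[:, 2, 2] + t[:, 1, 2] + t[:, 2, 1] + q * t[:, 1, 1],
        ],
        axis=1,
    )
    alpha = h / (2 * N)[:, None]
    num = alpha[:, 0] * alpha[:, 3]
    den = num + alpha[:, 1] * alpha[:, 2]
    q_new = np.where(den > 0, num / np.maximum(den, 1e-300), q)
    return alpha, q_new


def em_batch(tables: np.ndarray, tol: float = 1e-5, max_iter: int = 1000):
    """Run the pair EM on stacked (P,3,3) count tables simultaneously.

    Returns ``(alpha (P,4), q (P,), n_iter)``.  Convergence is judged on the
    largest |q change| across pairs.
    """
    tables = np.asarray(tables, dtype=float)
    P = tables.shape[0]
    q = np.full(P, 0.5)
    alpha = np.full((P, 4), 0.25)
    # each pair freezes at its own convergence point, matching per-pair runs
    active = np.ones(P, dtype=bool)
    for it in range(1, max_iter + 1):
        if not active.any():
            return alpha, q, it - 1
        a_new, q_new = _em_updates(tables[active], q[active])
        done = np.abs(q_new - q[active]) < tol
        alpha[active] = a_new
        q[active] = q_new
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    if not active.any():
        return alpha, q, max_iter
    raise ConvergenceError(
        f"pair EM did not converge in {max_iter} iterations",
        HaplotypeProportions(alpha[0] / alpha[0].sum(), float(q[0]), max_iter),
    )


def em_haplotype_proportions(
    counts: PairCounts, tol: float = 1e-5, max_iter: int = 1000
) -> HaplotypeProportions:
    """Estimate the four haplotype-set proportions for one locus pair."""
    if counts.n < 1:
        raise ValueError("at least one sample required")
    try:
        alpha, q, it = em_batch(counts.table[None], tol=tol, max_iter=max_iter)
    except ConvergenceError:
        raise
    a = alpha[0]
    return HaplotypeProportions(a / a.sum(), float(q[0]), it)


def pair_loglik(counts: PairCounts, alpha: np.ndarray) -> float:
    """Observed-data multinomial log-likelihood of a 3x3 table under alpha.

    Each genotype cell's probability is the sum over haplotype-pair
    configurations consistent with it (random union of two haplotypes).
    """
    aAA, aAB, aBA, aBB = alpha
    pa = np.array([aAA, aAB, aBA, aBB])
    # genotype at a locus from two haplotype alleles: code = #B alleles + 1
    cell = np.zeros((3, 3))
    hap_allele = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (allele at j, allele at j+1), 0=A
    for i, (x1, y1) in enumerate(hap_allele):
        for k, (x2, y2) in enumerate(hap_allele):
            cell[x1 + x2, y1 + y2] += pa[i] * pa[k]
    with np.errstate(divide="ignore"):
        lc = np.where(counts.table > 0, np.log(np.maximum(cell, 1e-300)), 0.0)
    return float((counts.table * lc).sum())


def conditional_probabilities(props: HaplotypeProportions) -> ConditionalTable:
    """Derive the 2x2 joint/conditional allele-transition table from alpha."""
    j = props.alpha.reshape(2, 2).copy()
    marg = j.sum(axis=1)
    flagged = marg <= 0.0
    c = np.empty((2, 2))
    for x in range(2):
        c[x] = (0.5, 0.5) if flagged[x] else j[x] / marg[x]
    return ConditionalTable(c, j, flagged)


def pairwise_tables(genos: GenotypeMatrix, tol: float = 1e-5, max_iter: int = 1000):
    """EM-derived conditional tables for every consecutive locus pair.

    Returns a list of L-1 :class:`ConditionalTable`.  All pairs are iterated
    in one vectorized sweep; results match per-pair calls exactly.
    """
    calls = genos.calls
    L = calls.shape[0]
    if (calls == 0).any():
        raise ValueError("pairwise tables require fully imputed genotypes")
    g = calls[:-1] - 1
    h = calls[1:] - 1
    idx = (9 * np.arange(L - 1)[:, None] + 3 * g + h).ravel()
    tables = np.bincount(idx, minlength=9 * (L - 1)).reshape(L - 1, 3, 3)
    alpha, q, _ = em_batch(tables, tol=tol, max_iter=max_iter)
    out = []
    for p in range(L - 1):
        a = alpha[p] / alpha[p].sum()
        out.append(conditional_probabilities(HaplotypeProportions(a, float(q[p]))))
    return out


def tables_from_haplotypes(alleles: np.ndarray, weights: np.ndarray | None = None):
    """Conditional tables from phased haplotype allele sequences.

    ``alleles`` is (H, L) in {0=A, 1=B}; rows are haplotypes (two per
    sample once phased).  Used to refresh the transition structure after a
    decoding pass, when phases are known and no EM is needed.

    Returns ``(tables, marginals)`` where ``tables`` is a list of L-1
    :class:`ConditionalTable` and ``marginals`` is an (L, 2) array of allele
    frequencies per locus.
    """
    alleles = np.asarray(alleles)
    H, L = alleles.shape
    w = np.ones(H) if weights is None else np.asarray(weights, dtype=float)
    marginals = np.stack(
        [(w[:, None] * (alleles == k)).sum(axis=0) for k in (0, 1)], axis=1
    )
    marginals = marginals / marginals.sum(axis=1, keepdims=True)
    out = []
    for p in range(L - 1):
        jtab = np.zeros((2, 2))
        np.add.at(jtab, (alleles[:, p], alleles[:, p + 1]), w)
        jtab = jtab / jtab.sum()
        marg = jtab.sum(axis=1)
        flagged = marg <= 0.0
        c = np.empty((2, 2))
        for x in range(2):
            c[x] = (0.5, 0.5) if flagged[x] else jtab[x] / marg[x]
        out.append(ConditionalTable(c, jtab, flagged))
    return out, marginals
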