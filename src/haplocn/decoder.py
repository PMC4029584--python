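"""Viterbi decoding over two haplotype trees and the global iteration driver.

The hidden state of a sample at a locus is an ordered pair of allelic
states, one per haplotype; both haplotypes are driven by the same population
tree, queried independently, so a pair transition probability is the product
of the two single-haplotype tree transitions.  To keep the state space
manageable, per-locus candidates are restricted to the member states of the
emission model nearest (in Mahalanobis distance) to the observed signal;
if no candidate is reachable at a locus the full 36-state set is restored
there.

The driver alternates (I) tree construction/merging/branching and (II) state
recognition: the first pass uses the genotype-EM transition tables and the
seed emission grid, later passes refresh the emission parameters from the
decoded assignments and the transition tables from the phased haplotype
counts (with the distance-decay redistribution reapplied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import postprocess
from .emission_models import (
    STATE_TO_MODEL,
    ModelBank,
    seed_bank,
    shaded_mask,
    update_models,
)
from .haplotype_freq import pairwise_tables, tables_from_haplotypes
from .haplotype_tree import (
    STATE_ALLELE,
    BranchedTree,
    DecayParams,
    _tree_from_tables,
    branch_aberrant,
    merge_tree,
)
from .signal_io import (
    GenotypeMatrix,
    SampleSignalSet,
    SeedClusters,
    SnpMap,
    impute_missing_genotypes,
)

__all__ = ["GenotypePath", "PipelineConfig", "PipelineResult", "viterbi_decode", "run_pipeline"]

#: all 36 ordered pair states in lexicographic order, as (h1, h2) rows
ALL_PAIRS = np.array([(h1, h2) for h1 in range(6) for h2 in range(6)], dtype=np.int8)
#: model id of each pair state in ALL_PAIRS order
_PAIR_MODEL = STATE_TO_MODEL.copy()
#: candidate pair arrays per model, in the member order (lexicographically
#: smaller ordering of each unordered pair first)
from .emission_models import MODEL_MEMBERS  # noqa: E402

MODEL_PAIRS = [np.array(m, dtype=np.int8) for m in MODEL_MEMBERS]


@dataclass
class GenotypePath:
    """Decoded two-haplotype state path for one sample on one chromosome."""

    states: np.ndarray  # (L, 2) allelic-state codes
    log_score: np.ndarray  # (L,) cumulative best log-probability
    groups: np.ndarray  # (L,) selected model id per locus
    n_fallback: int = 0  # loci where the candidate set had to be widened


@dataclass
class PipelineConfig:
    """Tunable parameters of the caller."""

    d_norm: float = 1e8  # bp; normal-state persistence scale
    d_var: float = 1e5  # bp; aberrant-state persistence scale
    shaded_quantile: float = 0.99  # chi2(2) quantile of the normal ellipses
    global_iterations: int = 2  # tree/recognition alternations
    restrict: bool = True  # Mahalanobis group restriction in the Viterbi
    em_tol: float = 1e-5
    em_max_iter: int = 1000

    @property
    def decay_params(self) -> DecayParams:
        return DecayParams(self.d_norm, self.d_var)


@dataclass
class PipelineResult:
    """Cohort-level decoding output.

    ``paths`` is (S, L, 2) allelic states; ``cn_a``/``cn_b`` are (L, S)
    fractional allele copy numbers; ``regions`` contains the reported CNV
    regions with genome-wide SNP indices; ``shaded`` is the (L, S)
    low-confidence mask under the final models.
    """

    snps: SnpMap
    samples: list[str]
    paths: np.ndarray
    cn_a: np.ndarray
    cn_b: np.ndarray
    regions: list
    shaded: np.ndarray
    bank: ModelBank
    log_scores: np.ndarray  # (S,) final total path log-probabilities


def _viterbi_arrays(logdens, groups, tree: BranchedTree, restrict: bool):
    """Core DP; returns (states (L,2), per-locus cumulative score, n_fallback)."""
    L = logdens.shape[0]
    n_fallback = 0

    def candidates(j):
        return MODEL_PAIRS[groups[j]] if restrict else ALL_PAIRS

    cand = candidates(0)
    pair_idx = 6 * cand[:, 0].astype(int) + cand[:, 1].astype(int)
    score = (
        tree.log_init[cand[:, 0]]
        + tree.log_init[cand[:, 1]]
        + logdens[0, _PAIR_MODEL[pair_idx]]
    )
    cands = [cand]
    back: list[np.ndarray] = []
    for j in range(1, L):
        cand = candidates(j)
        prev = cands[-1]
        lt = tree.log_trans[j - 1]
        trans = lt[prev[:, 0][:, None], cand[None, :, 0]] + lt[prev[:, 1][:, None], cand[None, :, 1]]
        tot = score[:, None] + trans
        best = tot.max(axis=0)
        if restrict and not np.isfinite(best).any():
            # no member of the selected group is reachable: widen to all 36
            n_fallback += 1
            cand = ALL_PAIRS
            trans = lt[prev[:, 0][:, None], cand[None, :, 0]] + lt[prev[:, 1][:, None], cand[None, :, 1]]
            tot = score[:, None] + trans
            best = tot.max(axis=0)
        pair_idx = 6 * cand[:, 0].astype(int) + cand[:, 1].astype(int)
        score = best + logdens[j, _PAIR_MODEL[pair_idx]]
        back.append(tot.argmax(axis=0))
        cands.append(cand)

    states = np.empty((L, 2), dtype=np.int8)
    cum = np.empty(L)
    k = int(score.argmax())
    cum[L - 1] = score[k]
    states[L - 1] = cands[L - 1][k]
    for j in range(L - 2, -1, -1):
        k = int(back[j][k])
        states[j] = cands[j][k]
        cum[j] = np.nan  # filled below
    # cumulative score along the chosen path, for inspection
    cum[0] = (
        tree.log_init[states[0, 0]] + tree.log_init[states[0, 1]]
        + logdens[0, _PAIR_MODEL[6 * states[0, 0] + states[0, 1]]]
    )
    for j in range(1, L):
        lt = tree.log_trans[j - 1]
        cum[j] = (
            cum[j - 1]
            + lt[states[j - 1, 0], states[j, 0]]
            + lt[states[j - 1, 1], states[j, 1]]
            + logdens[j, _PAIR_MODEL[6 * states[j, 0] + states[j, 1]]]
        )
    return states, cum, n_fallback


def viterbi_decode(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    tree: BranchedTree,
    bank: ModelBank,
    restrict: bool = True,
) -> GenotypePath:
    """Maximum-probability genotype path for one sample on one chromosome.

    ``sample_a``/``sample_b`` are (L,) intensity vectors aligned with the
    tree's loci and ``bank``'s SNPs.
    """
    a = np.asarray(sample_a, dtype=float)[:, None]
    b = np.asarray(sample_b, dtype=float)[:, None]
    d2 = bank.distances_sq(a, b)[:, 0, :]  # (L, 11)
    logdens = bank.logdensity(a, b)[:, 0, :]
    groups = d2.argmin(axis=1)
    states, cum, n_fb = _viterbi_arrays(logdens, groups, tree, restrict)
    return GenotypePath(states, cum, groups, n_fb)


# ---------------------------------------------------------------------------
# pipeline


def _build_branched(genos_calls, snps_c, cfg, from_haplotypes=None) -> BranchedTree:
    """Tree construction step: EM (or phased-count) tables -> merge -> branch."""
    if from_haplotypes is None:
        genos = GenotypeMatrix(genos_calls)
        tables = pairwise_tables(genos, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        from .haplotype_tree import build_binary_tree

        tree = build_binary_tree(genos, tables)
    else:
        tables, marginals = tables_from_haplotypes(from_haplotypes)
        tree = _tree_from_tables(
            [t.c for t in tables], marginals[0], float(from_haplotypes.shape[0])
        )
    merge_tree(tree)
    return branch_aberrant(tree, snps_c, cfg.decay_params)


def run_pipeline(
    signals: SampleSignalSet,
    genotypes: GenotypeMatrix,
    seeds: SeedClusters,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full caller: impute, iterate tree/recognition, extract regions and CNs.

    Chromosomes are processed independently (the tree restarts on each).
    Reported regions are the filtered aberrant segments whose rounded mean
    total copy number is outside the normal band (<=1 for losses, >=3 for
    gains), following the integer-rounding convention used for event calls.
    """
    from .simulator import round_cn

    cfg = config or PipelineConfig()
    genos = impute_missing_genotypes(signals, genotypes, seeds)
    bank_all = seed_bank(seeds)
    L, nS = signals.n_snps, signals.n_samples
    paths_all = np.empty((nS, L, 2), dtype=np.int8)
    cn_a_all = np.empty((L, nS))
    cn_b_all = np.empty((L, nS))
    shaded_all = np.empty((L, nS), dtype=bool)
    log_scores = np.zeros(nS)
    regions_all: list = []
    means_fin = bank_all.means.copy()
    covs_fin = bank_all.covs.copy()

    for chrom, sl in signals.snps.chrom_slices():
        a_c, b_c = signals.a[sl], signals.b[sl]
        snps_c = SnpMap(
            signals.snps.probe_id[sl], signals.snps.chrom[sl], signals.snps.pos[sl]
        )
        bank_c = ModelBank(bank_all.means[sl], bank_all.covs[sl], bank_all.flagged[sl])
        btree = _build_branched(genos.calls[sl], snps_c, cfg)
        path_objs: list[GenotypePath] = []
        for it in range(cfg.global_iterations):
            path_objs = [
                viterbi_decode(a_c[:, s], b_c[:, s], btree, bank_c, cfg.restrict)
                for s in range(nS)
            ]
            paths = np.stack([p.states for p in path_objs])  # (S, Lc, 2)
            if it < cfg.global_iterations - 1:
                pair_idx = 6 * paths[:, :, 0].astype(int) + paths[:, :, 1].astype(int)
                assignments = _PAIR_MODEL[pair_idx].T  # (Lc, S)
                bank_c = update_models(bank_c, assignments, a_c, b_c)
                alleles = STATE_ALLELE[paths]  # (S, Lc, 2)
                hap_seqs = alleles.transpose(0, 2, 1).reshape(2 * nS, -1)
                btree = _build_branched(None, snps_c, cfg, from_haplotypes=hap_seqs)

        shaded_c = shaded_mask(bank_c, a_c, b_c, cfg.shaded_quantile)
        na_c, nb_c = postprocess.allelic_cn_matrix(bank_c, a_c, b_c)
        for s in range(nS):
            path = path_objs[s]
            log_scores[s] += path.log_score[-1]
            regions = postprocess.extract_regions(path.states, sample=s, chrom=chrom)
            regions = postprocess.filter_regions(regions, shaded_c[:, s])
            for r in regions:
                r.cn_a = na_c[r.start : r.end + 1, s]
                r.cn_b = nb_c[r.start : r.end + 1, s]
                r.hap_cn = postprocess.haplotype_cn_summary(r, path.states)
                r.total_cn = postprocess.total_cn(r)
                r.event = postprocess.call_event(r.total_cn)
                rounded = round_cn(r.total_cn) if np.isfinite(r.total_cn) else 2
                keep = (r.direction == "gain" and rounded >= 3) or (
                    r.direction == "loss" and rounded <= 1
                )
                if keep:
                    regions_all.append(r.shifted(sl.start))

        paths_all[:, sl] = paths
        cn_a_all[sl] = na_c
        cn_b_all[sl] = nb_c
        shaded_all[sl] = shaded_c
        means_fin[sl] = bank_c.means
        covs_fin[sl] = bank_c.covs

    bank_fin = ModelBank(means_fin, covs_fin, bank_all.flagged)
    return PipelineResult(
        signals.snps,
        list(signals.samples),
        paths_all,
        cn_a_all,
        cn_b_all,
        regions_all,
        shaded_all,
        bank_fin,
        log_scores,
    )
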