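"""Reading and writing of cohort intensity, genotype and seed-cluster tables.

All files are tab-delimited text.  Coordinates are 1-based inclusive
throughout; CNV region start/end are the base-pair positions of the first and
last member SNP.

File layouts
------------
``signals.tsv``
    ``probe_id  chrom  pos  <sample>.A  <sample>.B  ...`` — one row per SNP,
    one ``.A``/``.B`` column pair per sample carrying the allele-specific
    intensity summaries (s_A, s_B).
``genotypes.tsv``
    ``probe_id  <sample> ...`` with calls in ``{AA, AB, BB, NC}``.
``seeds.tsv``
    ``probe_id`` followed by, for each of AA/AB/BB, five numbers: mean_A,
    mean_B, var_A, cov_AB, var_B (the three free entries of the symmetric
    2x2 covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "SampleSignalSet",
    "GenotypeMatrix",
    "SeedClusters",
    "ParseError",
    "read_signals",
    "read_genotypes",
    "read_seeds",
    "impute_missing_genotypes",
    "write_calls",
    "read_calls",
]

#: genotype call codes used throughout the package
CODE_NOCALL, CODE_AA, CODE_AB, CODE_BB = 0, 1, 2, 3
_TOKEN_TO_CODE = {"AA": CODE_AA, "AB": CODE_AB, "BB": CODE_BB, "NC": CODE_NOCALL}
_CODE_TO_TOKEN = {v: k for k, v in _TOKEN_TO_CODE.items()}


class ParseError(ValueError):
    """Raised for malformed input tables; message names the offending cell."""


@dataclass
class SnpMap:
    """Probe identifiers with genomic coordinates, sorted by (chrom, pos)."""

    probe_id: np.ndarray  # (L,) str
    chrom: np.ndarray  # (L,) str
    pos: np.ndarray  # (L,) int, 1-based

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(set(self.probe_id)) != len(self.probe_id):
            raise ParseError("duplicate probe_id in SNP map")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ParseError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.probe_id)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, row-slice) blocks in map order."""
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        return out


@dataclass
class SampleSignalSet:
    """Per-SNP, per-sample paired allele intensities (s_A, s_B)."""

    snps: SnpMap
    samples: list[str]
    a: np.ndarray  # (L, S) A-allele intensity
    b: np.ndarray  # (L, S) B-allele intensity

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        L, S = len(self.snps), len(self.samples)
        if self.a.shape != (L, S) or self.b.shape != (L, S):
            raise ValueError("signal arrays must be (n_snps, n_samples)")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("non-finite intensity values")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class GenotypeMatrix:
    """Integer genotype calls: 1=AA, 2=AB, 3=BB, 0=no-call."""

    calls: np.ndarray  # (L, S) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not np.isin(self.calls, [0, 1, 2, 3]).all():
            raise ValueError("genotype codes must be in {0,1,2,3}")


@dataclass
class SeedClusters:
    """Per-SNP bivariate normal seed parameters for AA, AB, BB (in that order)."""

    means: np.ndarray  # (L, 3, 2)
    covs: np.ndarray  # (L, 3, 2, 2)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        if self.means.ndim != 3 or self.means.shape[1:] != (3, 2):
            raise ValueError("seed means must be (n_snps, 3, 2)")
        if self.covs.shape != self.means.shape[:2] + (2, 2):
            raise ValueError("seed covariances must be (n_snps, 3, 2, 2)")


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        r = int(bad[0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[r]!r} in column {col!r}, "
            f"line {r + 2} (probe {df.iloc[r, 0]!r})"
        )
    return vals


def read_signals(path) -> SampleSignalSet:
    """Read a cohort intensity table, returning data sorted by (chrom, pos)."""
    df = _read_tsv(path)
    if list(df.columns[:3]) != ["probe_id", "chrom", "pos"]:
        raise ParseError(
            f"{path}: header must start with 'probe_id\\tchrom\\tpos', got {list(df.columns[:3])}"
        )
    sig_cols = list(df.columns[3:])
    samples: list[str] = []
    for i in range(0, len(sig_cols), 2):
        if i + 1 >= len(sig_cols):
            raise ParseError(f"{path}: dangling signal column {sig_cols[i]!r}")
        ca, cb = sig_cols[i], sig_cols[i + 1]
        if not (ca.endswith(".A") and cb.endswith(".B") and ca[:-2] == cb[:-2]):
            raise ParseError(f"{path}: expected '<sample>.A\\t<sample>.B' pair, got {ca!r}, {cb!r}")
        samples.append(ca[:-2])
    if not samples:
        raise ParseError(f"{path}: no sample signal columns")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate probe {dup.iloc[0]!r}")

    pos = _numeric_column(df, "pos", path).astype(np.int64)
    order = np.lexsort((pos, df["chrom"].to_numpy()))
    a = np.column_stack([_numeric_column(df, f"{s}.A", path) for s in samples])[order]
    b = np.column_stack([_numeric_column(df, f"{s}.B", path) for s in samples])[order]
    snps = SnpMap(df["probe_id"].to_numpy()[order], df["chrom"].to_numpy()[order], pos[order])
    return SampleSignalSet(snps, samples, a, b)


def read_genotypes(path, snps: SnpMap | None = None) -> GenotypeMatrix:
    """Read genotype calls; rows are reordered to ``snps`` when given."""
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    if snps is not None:
        missing = set(snps.probe_id) - set(df.index)
        if missing:
            raise ParseError(f"{path}: missing probes {sorted(missing)[:3]}")
        df = df.loc[list(snps.probe_id)]
    calls = np.empty(df.shape, dtype=np.int8)
    vals = df.to_numpy()
    for (r, c), tok in np.ndenumerate(vals):
        code = _TOKEN_TO_CODE.get(tok)
        if code is None:
            raise ParseError(
                f"{path}: unknown genotype token {tok!r} at probe {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        calls[r, c] = code
    return GenotypeMatrix(calls)


_GENO_NAMES = ("AA", "AB", "BB")
_SEED_FIELDS = ("meanA", "meanB", "varA", "covAB", "varB")


def read_seeds(path, snps: SnpMap | None = None) -> SeedClusters:
    """Read per-SNP AA/AB/BB seed-cluster parameters."""
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id'")
    want = [f"{g}.{f}" for g in _GENO_NAMES for f in _SEED_FIELDS]
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing seed columns {missing[:3]}")
    cols = {c: _numeric_column(df, c, path) for c in want}
    if snps is not None:
        idx = {p: i for i, p in enumerate(df["probe_id"])}
        try:
            order = np.array([idx[p] for p in snps.probe_id])
        except KeyError as exc:
            raise ParseError(f"{path}: missing probe {exc.args[0]!r}") from exc
        cols = {c: v[order] for c, v in cols.items()}
    L = len(next(iter(cols.values())))
    means = np.empty((L, 3, 2))
    covs = np.empty((L, 3, 2, 2))
    for gi, g in enumerate(_GENO_NAMES):
        means[:, gi, 0] = cols[f"{g}.meanA"]
        means[:, gi, 1] = cols[f"{g}.meanB"]
        covs[:, gi, 0, 0] = cols[f"{g}.varA"]
        covs[:, gi, 0, 1] = covs[:, gi, 1, 0] = cols[f"{g}.covAB"]
        covs[:, gi, 1, 1] = cols[f"{g}.varB"]
    return SeedClusters(means, covs)


# ---------------------------------------------------------------------------
# genotype imputation


def impute_missing_genotypes(
    signals: SampleSignalSet, genos: GenotypeMatrix, seeds: SeedClusters
) -> GenotypeMatrix:
    """Replace no-calls with the genotype of smallest Mahalanobis distance.

    The distance of (s_A, s_B) to each of the AA/AB/BB seed models is
    compared; ties resolve to the lowest genotype code (AA < AB < BB) so the
    result is deterministic.  Idempotent: calls other than 0 are untouched.
    """
    calls = genos.calls.copy()
    rows, cols = np.nonzero(calls == CODE_NOCALL)
    if rows.size == 0:
        return GenotypeMatrix(calls)
    for snp in np.unique(rows):
        try:
            inv = np.linalg.inv(seeds.covs[snp])  # (3, 2, 2)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular seed covariance at SNP {signals.snps.probe_id[snp]!r}"
            ) from exc
        smp = cols[rows == snp]
        d = np.stack([signals.a[snp, smp], signals.b[snp, smp]], axis=-1)  # (k, 2)
        diff = d[:, None, :] - seeds.means[snp][None, :, :]  # (k, 3, 2)
        d2 = np.einsum("kgi,gij,kgj->kg", diff, inv, diff)
        calls[snp, smp] = np.argmin(d2, axis=1) + 1  # ties -> lowest code
    return GenotypeMatrix(calls)


# ---------------------------------------------------------------------------
# writers

_STATE_NAMES = ("A-", "A", "A+", "B-", "B", "B+")
_STATE_INDEX = {n: i for i, n in enumerate(_STATE_NAMES)}

CALLS_HEADER = ["sample", "probe_id", "chrom", "pos", "hap1", "hap2", "cn_a", "cn_b"]
REGIONS_HEADER = [
    "sample",
    "chrom",
    "start",
    "end",
    "snp_first",
    "snp_last",
    "direction",
    "cn_hap1",
    "cn_hap2",
    "total_cn",
    "n_snps",
]


def write_calls(calls_path, regions_path, snps: SnpMap, samples, paths, cn_a, cn_b, regions) -> None:
    """Write the per-SNP phased-state table and the BED-like region table.

    ``paths`` is an (S, L, 2) array of allelic-state codes, ``cn_a``/``cn_b``
    are (L, S) fractional allele copy numbers (NaN where flagged missing), and
    ``regions`` is a list of :class:`haplocn.postprocess.CNVRegion`.
    """
    paths = np.asarray(paths)
    with open(calls_path, "w") as fh:
        fh.write("\t".join(CALLS_HEADER) + "\n")
        for si, sample in enumerate(samples):
            for j in range(len(snps)):
                fh.write(
                    f"{sample}\t{snps.probe_id[j]}\t{snps.chrom[j]}\t{snps.pos[j]}\t"
                    f"{_STATE_NAMES[paths[si, j, 0]]}\t{_STATE_NAMES[paths[si, j, 1]]}\t"
                    f"{cn_a[j, si]:.6g}\t{cn_b[j, si]:.6g}\n"
                )
    with open(regions_path, "w") as fh:
        fh.write("\t".join(REGIONS_HEADER) + "\n")
        for r in regions:
            fh.write(
                f"{samples[r.sample]}\t{r.chrom}\t{snps.pos[r.start]}\t{snps.pos[r.end]}\t"
                f"{snps.probe_id[r.start]}\t{snps.probe_id[r.end]}\t{r.direction}\t"
                f"{r.hap_cn[0]:.6g}\t{r.hap_cn[1]:.6g}\t{r.total_cn:.6g}\t{r.n_snps}\n"
            )


def read_calls(path):
    """Read a table written by :func:`write_calls` back into arrays.

    Returns ``(snps, samples, paths, cn_a, cn_b)`` with the same shapes and
    conventions as the writer's arguments (round-trip exact for states).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "probe_id": str, "chrom": str})
    samples = list(dict.fromkeys(df["sample"]))
    first = df[df["sample"] == samples[0]]
    snps = SnpMap(first["probe_id"].to_numpy(), first["chrom"].to_numpy(), first["pos"].to_numpy())
    L, S = len(snps), len(samples)
    paths = np.empty((S, L, 2), dtype=np.int8)
    cn_a = np.empty((L, S))
    cn_b = np.empty((L, S))
    for si, sample in enumerate(samples):
        sub = df[df["sample"] == sample]
        paths[si, :, 0] = [_STATE_INDEX[s] for s in sub["hap1"]]
        paths[si, :, 1] = [_STATE_INDEX[s] for s in sub["hap2"]]
        cn_a[:, si] = sub["cn_a"].to_numpy()
        cn_b[:, si] = sub["cn_b"].to_numpy()
    return snps, samples, paths, cn_a, cn_b
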