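"""K-mer based heteroplasmy detection.

Builds libraries of discriminating k-mers between two mitotypes (k-mers of
one type at Hamming distance >= min_diff from every k-mer of the other,
excluding windows spanning alignment gaps), classifies raw reads by exact
k-mer identity, estimates the minor-type proportion H-hat, and provides
beta-distribution right-tail outlier calling plus a Mann-Whitney group test.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import Alignment, reverse_complement
from .recomb import TestResult
from .simulate import ReadSet


class LibraryError(ValueError):
    pass


class HeteroplasmyEstimationError(RuntimeError):
    pass


@dataclass
class KmerLibrary:
    type_x_id: str
    type_y_id: str
    k: int
    min_diff: int
    kmers: set[str]
    n_windows: int = 0  # positional windows kept (duplicates uncollapsed)

    @property
    def size(self) -> int:
        return len(self.kmers)

    def write(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            for km in sorted(self.kmers):
                fh.write(km + "\n")
        meta = {"type_x": self.type_x_id, "type_y": self.type_y_id,
                "k": self.k, "min_diff": self.min_diff, "size": self.size,
                "n_windows": self.n_windows}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, path) -> "KmerLibrary":
        path = str(path)
        with open(path) as fh:
            kmers = {line.strip() for line in fh if line.strip()}
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(type_x_id=meta["type_x"], type_y_id=meta["type_y"],
                   k=meta["k"], min_diff=meta["min_diff"], kmers=kmers,
                   n_windows=meta.get("n_windows", 0))


def _ungapped_with_columns(row: np.ndarray) -> tuple[str, np.ndarray]:
    keep = row != b"-"
    seq = row[keep].tobytes().decode()
    cols = np.nonzero(keep)[0]
    return seq, cols


def _circular_windows(seq: str, k: int) -> list[str]:
    doubled = seq + seq[:k - 1]
    return [doubled[i:i + k] for i in range(len(seq))]


def _hamming_lt(a: str, b: str, limit: int) -> bool:
    """True when Hamming(a, b) < limit (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d >= limit:
                return False
    return True


def build_kmer_library(aligned_assemblies: Alignment, type_x: str, type_y: str,
                       k: int = 251, min_diff: int = 2) -> KmerLibrary:
    """All circular k-mers of type x at Hamming distance >= min_diff from
    every circular k-mer of type y, skipping windows whose alignment
    footprint contains a gap column (gap in either row).

    Near-duplicate detection uses a pigeonhole split into ``min_diff``
    chunks: any y k-mer within distance < min_diff must agree exactly with
    the x k-mer on at least one chunk, so only chunk-collision candidates
    need explicit Hamming checks. Results equal brute-force enumeration.
    """
    xi = aligned_assemblies.sample_ids.index(type_x)
    yi = aligned_assemblies.sample_ids.index(type_y)
    xrow = aligned_assemblies.matrix[xi]
    yrow = aligned_assemblies.matrix[yi]
    xseq, xcols = _ungapped_with_columns(xrow)
    yseq, _ = _ungapped_with_columns(yrow)
    if k > len(xseq) or k > len(yseq):
        raise LibraryError(f"k={k} exceeds ungapped sequence length")

    L_aln = aligned_assemblies.length
    gapcol = (xrow == b"-") | (yrow == b"-")
    gap_csum = np.concatenate([[0], np.cumsum(gapcol.astype(int))])

    def footprint_has_gap(c_start: int, c_end: int) -> bool:
        # inclusive circular alignment-column interval
        if c_start <= c_end:
            return gap_csum[c_end + 1] - gap_csum[c_start] > 0
        return (gap_csum[L_aln] - gap_csum[c_start]) + gap_csum[c_end + 1] > 0

    nx = len(xseq)
    x_kmers_all = _circular_windows(xseq, k)
    kept_idx = []
    for i in range(nx):
        c_start = int(xcols[i])
        c_end = int(xcols[(i + k - 1) % nx])
        if not footprint_has_gap(c_start, c_end):
            kept_idx.append(i)

    y_kmers = _circular_windows(yseq, k)
    # pigeonhole chunk dictionaries over y k-mers
    bounds = np.linspace(0, k, min_diff + 1).astype(int)
    chunk_maps: list[dict[str, list[int]]] = []
    for c in range(min_diff):
        d: dict[str, list[int]] = {}
        lo, hi = bounds[c], bounds[c + 1]
        for j, km in enumerate(y_kmers):
            d.setdefault(km[lo:hi], []).append(j)
        chunk_maps.append(d)

    kept: list[str] = []
    for i in kept_idx:
        km = x_kmers_all[i]
        cand: set[int] = set()
        for c in range(min_diff):
            lo, hi = bounds[c], bounds[c + 1]
            cand.update(chunk_maps[c].get(km[lo:hi], ()))
        too_close = any(_hamming_lt(km, y_kmers[j], min_diff) for j in cand)
        if not too_close:
            kept.append(km)
    return KmerLibrary(type_x_id=type_x, type_y_id=type_y, k=k,
                       min_diff=min_diff, kmers=set(kept), n_windows=len(kept))


@dataclass
class CandidateRecord:
    candidate: str
    n_reads_iM: int
    n_kmers_iM: int
    n_reads_Mi: int
    n_kmers_Mi: int
    minor_rate: float          # #R_iM / #K_iM
    h_hat_i: float
    skipped: bool = False
    reason: str = ""
    zero_denominator: bool = False


@dataclass
class HeteroplasmyEstimate:
    sample_id: str
    major_type: str
    candidates: list[CandidateRecord]
    selected_candidate: str
    h_hat: float
    n_reads_wrong_length: int = 0
    ties: list[str] = field(default_factory=list)


def _count_matching_reads(reads: list[str], kmers: set[str],
                          match_revcomp: bool) -> int:
    n = 0
    for r in reads:
        if r in kmers or (match_revcomp and reverse_complement(r) in kmers):
            n += 1
    return n


def estimate_heteroplasmy(reads: ReadSet, major: str, candidates: list[str],
                          libraries: dict[tuple[str, str], KmerLibrary],
                          sample_id: str = "sample",
                          match_revcomp: bool = True) -> HeteroplasmyEstimate:
    """Estimate the minor-type proportion H-hat from discriminating reads.

    For each candidate i, the putative heteroplasmy is
    H_i = (#R_iM/#K_iM) / (#R_iM/#K_iM + #R_Mi/#K_Mi); the reported H-hat
    is H_i of the candidate with the largest normalized minor rate
    #R_iM/#K_iM (ties go to the lowest label and are recorded).
    """
    records: list[CandidateRecord] = []
    k = None
    for i in candidates:
        if i == major:
            continue
        lib_im = libraries.get((i, major))
        lib_mi = libraries.get((major, i))
        if lib_im is None or lib_mi is None:
            records.append(CandidateRecord(i, 0, 0, 0, 0, float("nan"), float("nan"),
                                           skipped=True, reason="missing library"))
            continue
        if lib_im.size == 0 or lib_mi.size == 0:
            records.append(CandidateRecord(
                i, 0, lib_im.size, 0, lib_mi.size, float("nan"), float("nan"),
                skipped=True, reason="empty k-mer library"))
            continue
        k = lib_im.k
        seqs = [s for _, s in reads.reads if len(s) == k]
        n_im = _count_matching_reads(seqs, lib_im.kmers, match_revcomp)
        n_mi = _count_matching_reads(seqs, lib_mi.kmers, match_revcomp)
        rate_i = n_im / lib_im.size
        rate_m = n_mi / lib_mi.size
        if rate_i + rate_m == 0:
            records.append(CandidateRecord(i, n_im, lib_im.size, n_mi, lib_mi.size,
                                           0.0, 0.0, zero_denominator=True))
            continue
        h_i = rate_i / (rate_i + rate_m)
        records.append(CandidateRecord(i, n_im, lib_im.size, n_mi, lib_mi.size,
                                       rate_i, h_i))
    usable = [r for r in records if not r.skipped]
    if not usable:
        raise HeteroplasmyEstimationError("all candidates skipped")
    best_rate = max(r.minor_rate for r in usable)
    best = sorted([r for r in usable if r.minor_rate == best_rate],
                  key=lambda r: r.candidate)
    n_wrong = 0
    if k is not None:
        n_wrong = sum(1 for _, s in reads.reads if len(s) != k)
    return HeteroplasmyEstimate(
        sample_id=sample_id, major_type=major, candidates=records,
        selected_candidate=best[0].candidate, h_hat=best[0].h_hat_i,
        n_reads_wrong_length=n_wrong,
        ties=[r.candidate for r in best[1:]])


# ---------------------------------------------------------------------------
# beta right-tail outlier detection
# ---------------------------------------------------------------------------

@dataclass
class BetaOutlierResult:
    flags: np.ndarray
    alpha: float
    beta: float
    degenerate: bool = False


def beta_outlier_detection(values, rho: float = 1.0, q_lo: float = 0.05,
                           q_hi: float = 0.95) -> BetaOutlierResult:
    """Flag right-tail outliers against a beta fit of the bulk.

    The beta distribution is fitted to the order statistics between the
    ``q_lo`` and ``q_hi`` empirical quantiles (least squares against model
    quantiles at the corresponding plotting positions); value v is an
    outlier when the expected count of observations >= v under the fit,
    N * (1 - F(v)), falls below ``rho``.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 5:
        raise ValueError("need >= 5 values")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("values must be proportions in [0, 1]")
    N = len(vals)
    if np.ptp(vals) == 0:
        return BetaOutlierResult(flags=np.zeros(N, dtype=bool), alpha=float("nan"),
                                 beta=float("nan"), degenerate=True)
    if rho >= N:
        # the expected-outlier budget covers the whole sample: degenerate
        # threshold, nothing can be called an outlier
        return BetaOutlierResult(flags=np.zeros(N, dtype=bool), alpha=float("nan"),
                                 beta=float("nan"), degenerate=True)
    order = np.argsort(vals)
    ranks = np.arange(1, N + 1)
    pp = (ranks - 0.5) / N
    bulk = (pp >= q_lo) & (pp <= q_hi)
    y = vals[order][bulk]
    p = pp[bulk]

    eps = 1e-9
    yc = np.clip(y, eps, 1 - eps)
    m, v = float(np.mean(yc)), float(np.var(yc))
    if v <= 0:
        v = max(m * (1 - m) / N, 1e-12)
    common = m * (1 - m) / v - 1
    a0 = max(m * common, 1e-3)
    b0 = max((1 - m) * common, 1e-3)

    def sse(logab):
        a, b = np.exp(logab)
        q = stats.beta.ppf(p, a, b)
        return float(np.sum((q - y) ** 2))

    res = optimize.minimize(sse, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    a, b = np.exp(res.x)
    expected_above = N * stats.beta.sf(vals, a, b)
    flags = expected_above < rho
    return BetaOutlierResult(flags=flags, alpha=float(a), beta=float(b))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney_test(group_a, group_b, exact_max_n: int = 12) -> TestResult:
    """Two-sided rank-sum test with tie correction.

    Exact enumeration of all assignments for combined n <= exact_max_n
    (two-sided by symmetric distance of U from its null mean), normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    n = na + nb
    ranks = stats.rankdata(pooled)
    U = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    if n <= exact_max_n:
        count = total = 0
        for comb in itertools.combinations(range(n), na):
            u = float(ranks[list(comb)].sum() - na * (na + 1) / 2.0)
            total += 1
            if abs(u - mu) >= abs(U - mu) - 1e-12:
                count += 1
        p = count / total
        method = "mann-whitney-exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "mann-whitney-normal"
    return TestResult(statistic=U, p_value=p, n_permutations=0, method=method)


def write_estimates_tsv(estimates: list[HeteroplasmyEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tmajor\tcandidate\tn_reads_iM\tn_kmers_iM\t"
                 "n_reads_Mi\tn_kmers_Mi\tminor_rate\th_hat_i\tselected\n")
        for est in estimates:
            for r in est.candidates:
                sel = int(r.candidate == est.selected_candidate)
                fh.write(f"{est.sample_id}\t{est.major_type}\t{r.candidate}\t"
                         f"{r.n_reads_iM}\t{r.n_kmers_iM}\t{r.n_reads_Mi}\t"
                         f"{r.n_kmers_Mi}\t{r.minor_rate:.6g}\t{r.h_hat_i:.6g}\t{sel}\n")
            fh.write(f"{est.sample_id}\t{est.major_type}\tSUMMARY\t-\t-\t-\t-\t-\t"
                     f"{est.h_hat:.6g}\t1\n")
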