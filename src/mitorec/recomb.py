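"""Recombination detectors on biallelic site tables.

Four-gamete scan with haplotype blocks, pairwise LD statistics (D, D', r2),
Mantel tests of LD decay with physical distance on linear chunks, the
maximum chi-square breakpoint test over sequence pairs, and a pairwise
homoplasy index (PHI) test. All permutation p-values use the add-one
estimator (1 + #{perm beats observed}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SiteTable, extract_biallelic_sites


class MonomorphicPairError(ValueError):
    """A site is monomorphic among the samples shared by the pair."""


@dataclass
class PairLD:
    site_a: int
    site_b: int
    distance: float
    D: float
    D_prime: float
    r2: float
    four_gametes: bool


@dataclass
class HaplotypeBlock:
    start_column: int
    end_column: int  # half-open; < start_column when the block wraps the origin
    n_sites: int
    site_indices: list[int] = field(default_factory=list)
    wraps: bool = False


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    window_params: dict = field(default_factory=dict)
    untestable: bool = False
    reason: str = ""


def _gamete_counts(table: SiteTable) -> tuple[np.ndarray, ...]:
    """All-pairs 2x2 haplotype counts over shared non-missing samples.

    Returns (c00, c01, c10, c11), each an SxS matrix; entry [i, j] counts
    samples carrying the given pair of alleles at sites i and j.
    """
    G = table.genotype_matrix()
    is0 = (G == 0).astype(np.int64)
    is1 = (G == 1).astype(np.int64)
    c00 = is0 @ is0.T
    c01 = is0 @ is1.T
    c10 = is1 @ is0.T
    c11 = is1 @ is1.T
    return c00, c01, c10, c11


def four_gamete_matrix(table: SiteTable) -> np.ndarray:
    """SxS boolean matrix: True where a site pair shows all four gametes."""
    c00, c01, c10, c11 = _gamete_counts(table)
    return (c00 > 0) & (c01 > 0) & (c10 > 0) & (c11 > 0)


def ld_statistics(site_a_idx: int, site_b_idx: int, table: SiteTable,
                  distance: float | None = None) -> PairLD:
    """D, D' and r2 for one site pair over shared non-missing samples."""
    a = table.sites[site_a_idx].binary()
    b = table.sites[site_b_idx].binary()
    shared = (a >= 0) & (b >= 0)
    a, b = a[shared], b[shared]
    n = len(a)
    if n == 0 or len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        raise MonomorphicPairError(
            f"pair ({site_a_idx}, {site_b_idx}) monomorphic among shared samples")
    pA = a.mean()
    pB = b.mean()
    pAB = float((a & b).sum()) / n
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    gametes = {(int(x), int(y)) for x, y in zip(a, b)}
    if distance is None:
        pa, pb = table.sites[site_a_idx].column, table.sites[site_b_idx].column
        distance = abs(pb - pa)
        if table.circular:
            distance = min(distance, table.alignment_length - distance)
    return PairLD(site_a=site_a_idx, site_b=site_b_idx, distance=float(distance),
                  D=float(D), D_prime=float(d_prime), r2=float(r2),
                  four_gametes=len(gametes) == 4)


def four_gamete_scan(table: SiteTable) -> tuple[list[PairLD], int, int]:
    """Evaluate every unordered site pair; count four-gamete violations."""
    S = len(table)
    if S < 2:
        return [], 0, 0
    pairs: list[PairLD] = []
    n_violating = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(S), 2):
        try:
            p = ld_statistics(i, j, table)
        except MonomorphicPairError:
            continue
        n_pairs += 1
        if p.four_gametes:
            n_violating += 1
        pairs.append(p)
    return pairs, n_violating, n_pairs


def violating_pair_percentage(n_violating: int, n_pairs: int, sigfigs: int = 2) -> float:
    """Reporting helper: percentage of four-gamete pairs, rounded to
    ``sigfigs`` significant figures."""
    from .diversity import round_sigfigs
    if n_pairs == 0:
        raise ValueError("no pairs")
    return round_sigfigs(100.0 * n_violating / n_pairs, sigfigs)


def haplotype_blocks(table: SiteTable) -> list[HaplotypeBlock]:
    """Greedy left-to-right maximal segmentation into <=3-gamete blocks.

    A block closes when the next site would form a four-gamete pair with a
    member; on circular data the first and last blocks merge when their
    union stays violation-free (the merged block wraps the origin).
    """
    S = len(table)
    if S == 0:
        return []
    viol = four_gamete_matrix(table)
    blocks: list[list[int]] = []
    current = [0]
    for k in range(1, S):
        if any(viol[k, m] for m in current):
            blocks.append(current)
            current = [k]
        else:
            current.append(k)
    blocks.append(current)

    wraps = False
    if table.circular and len(blocks) > 1:
        union = blocks[-1] + blocks[0]
        if not any(viol[i, j] for i, j in itertools.combinations(union, 2)):
            last = blocks.pop()
            blocks[0] = last + blocks[0]
            wraps = True

    out = []
    pos = table.positions()
    for bi, idxs in enumerate(blocks):
        is_wrap = wraps and bi == 0
        start = int(pos[idxs[0]])
        end = int(pos[idxs[-1]]) + 1
        out.append(HaplotypeBlock(start_column=start, end_column=end,
                                  n_sites=len(idxs), site_indices=list(idxs),
                                  wraps=is_wrap))
    return out


# ---------------------------------------------------------------------------
# Mantel LD-decay test
# ---------------------------------------------------------------------------

def _mantel_r(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def mantel_ld_distance(table: SiteTable, stat: str = "r2", n_perm: int = 999,
                       seed: int = 1, alternative: str = "negative") -> TestResult:
    """Mantel correlation between pairwise LD and physical distance for the
    sites of one linear chunk, with site-label permutation."""
    S = len(table)
    method = f"mantel-LD{stat}"
    if S < 3:
        return TestResult(float("nan"), float("nan"), 0, method,
                          untestable=True, reason=f"only {S} segregating sites")
    ld = np.full((S, S), np.nan)
    pos = table.positions().astype(float)
    dist = np.abs(pos[:, None] - pos[None, :])
    for i, j in itertools.combinations(range(S), 2):
        try:
            p = ld_statistics(i, j, table, distance=abs(pos[j] - pos[i]))
        except MonomorphicPairError:
            continue
        v = p.r2 if stat == "r2" else p.D_prime
        ld[i, j] = ld[j, i] = v
    iu = np.triu_indices(S, 1)
    valid = ~np.isnan(ld[iu])
    if valid.sum() < 3:
        return TestResult(float("nan"), float("nan"), 0, method,
                          untestable=True, reason="too few evaluable pairs")
    obs = _mantel_r(ld[iu][valid], dist[iu][valid])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(S)
        dp = dist[perm][:, perm]
        r = _mantel_r(ld[iu][valid], dp[iu][valid])
        if alternative == "negative":
            beat = r <= obs
        elif alternative == "positive":
            beat = r >= obs
        else:
            beat = abs(r) >= abs(obs)
        count += bool(beat)
    p = (1 + count) / (1 + n_perm)
    return TestResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      method=method, window_params={"alternative": alternative})


def ld_distance_mantel(aln: Alignment, chunk_size: int, stat: str = "r2",
                       min_minor_count: int = 1, n_perm: int = 999, seed: int = 1,
                       offset: int = 0,
                       alternative: str = "negative") -> list[TestResult]:
    """Cut the (circular) alignment into consecutive linear chunks and run
    one Mantel LD-vs-distance test per chunk."""
    L = aln.length
    if chunk_size > L:
        raise ValueError("chunk_size exceeds alignment length")
    mat = np.roll(aln.matrix, -offset, axis=1) if offset else aln.matrix
    rolled = Alignment(list(aln.sample_ids), mat, circular=False)
    rng = np.random.default_rng(seed)
    results = []
    n_chunks = L // chunk_size
    for c in range(n_chunks):
        sub = rolled.subset_columns(c * chunk_size, (c + 1) * chunk_size)
        st = extract_biallelic_sites(sub, min_minor_count=min_minor_count)
        res = mantel_ld_distance(st, stat=stat, n_perm=n_perm,
                                 seed=int(rng.integers(1, 2**31 - 1)),
                                 alternative=alternative)
        res.window_params.update({"chunk": c, "start": c * chunk_size + offset,
                                  "end": (c + 1) * chunk_size + offset})
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# maximum chi-square
# ---------------------------------------------------------------------------

def _chi2_2x2(a, b, c, d):
    """Vectorized Pearson chi-square of [[a, b], [c, d]] (0 on empty margins)."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return out


def _maxchi_statistic(D: np.ndarray, w: int, half: int) -> float:
    """Max chi-square over pairs (rows of D) and window starts."""
    P, S = D.shape
    cs = np.concatenate([np.zeros((P, 1)), np.cumsum(D, axis=1)], axis=1)
    starts = np.arange(0, S - w + 1)
    diff_l = cs[:, starts + half] - cs[:, starts]
    diff_r = cs[:, starts + w] - cs[:, starts + half]
    agree_l = half - diff_l
    agree_r = (w - half) - diff_r
    chi = _chi2_2x2(diff_l, agree_l, diff_r, agree_r)
    return float(chi.max())


def _maxchi_breakpoint(D: np.ndarray, w: int, half: int) -> int:
    P, S = D.shape
    cs = np.concatenate([np.zeros((P, 1)), np.cumsum(D, axis=1)], axis=1)
    starts = np.arange(0, S - w + 1)
    diff_l = cs[:, starts + half] - cs[:, starts]
    diff_r = cs[:, starts + w] - cs[:, starts + half]
    chi = _chi2_2x2(diff_l, half - diff_l, diff_r, (w - half) - diff_r)
    pi, si = np.unravel_index(int(np.argmax(chi)), chi.shape)
    return int(starts[si] + half)  # site index of the split


def max_chi2_test(aln: Alignment, window_fraction: float = 2.0 / 3.0,
                  n_perm: int = 999, seed: int = 1,
                  region: tuple[int, int] | None = None,
                  min_minor_count: int = 1) -> TestResult:
    """Maximum chi-square test for a recombination breakpoint.

    For every sequence pair a window of w = round(window_fraction * S)
    ordered segregating sites slides along the genome; each placement is
    split at its midpoint and the 2x2 contingency of (differ/agree) x
    (left/right) is scored. The statistic is the maximum chi-square over
    pairs and placements; significance is by permutation of the
    segregating-site order.
    """
    src = aln if region is None else aln.subset_columns(*region)
    table = extract_biallelic_sites(src, min_minor_count=min_minor_count)
    S = len(table)
    if S < 4:
        return TestResult(float("nan"), float("nan"), 0, "max-chi2",
                          untestable=True, reason=f"only {S} segregating sites")
    w = int(round(window_fraction * S))
    w = min(w, S)
    if w < 4:
        raise ValueError(f"window of {w} sites is too small (need >= 4)")
    half = w // 2
    G = table.genotype_matrix()  # S x n
    n = G.shape[1]
    pair_rows = []
    full = True
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = G[:, i], G[:, j]
        ok = (gi >= 0) & (gj >= 0)
        if not ok.all():
            full = False
        pair_rows.append(np.where(ok, (gi != gj).astype(float), np.nan))
    D = np.vstack(pair_rows)

    def stat_for(order: np.ndarray) -> float:
        Do = D[:, order]
        if full:
            return _maxchi_statistic(Do, w, half)
        best = 0.0
        for row in Do:
            r = row[~np.isnan(row)]
            if len(r) >= w:
                best = max(best, _maxchi_statistic(r[None, :], w, half))
        return best

    identity = np.arange(S)
    obs = stat_for(identity)
    bp_site = _maxchi_breakpoint(np.nan_to_num(D), w, half) if full else -1
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat_for(rng.permutation(S)) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    wp = {"window_sites": w, "n_sites": S, "n_splits_per_pair": S - w + 1}
    if bp_site >= 0:
        wp["breakpoint_site_index"] = bp_site
        wp["breakpoint_column"] = int(table.sites[bp_site].column)
    return TestResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      method="max-chi2", window_params=wp)


# ---------------------------------------------------------------------------
# PHI
# ---------------------------------------------------------------------------

def phi_test(aln: Alignment, window: int = 100, n_perm: int = 999, seed: int = 1,
             region: tuple[int, int] | None = None) -> TestResult:
    """Pairwise homoplasy index over informative sites within ``window`` bp.

    The incompatibility score of a biallelic pair is 0 when it passes the
    four-gamete condition and 1 otherwise; Phi_w averages the score over
    informative-site pairs at physical distance <= window. Significance is
    by permuting which genotype vector sits at which position: genealogical
    correlation of nearby sites under recombination makes the observed
    Phi_w *small* relative to the permutation distribution, so the test is
    one-sided toward low values.
    """
    src = aln if region is None else aln.subset_columns(*region)
    table = extract_biallelic_sites(src, min_minor_count=2)
    S = len(table)
    if S < 2:
        return TestResult(float("nan"), float("nan"), 0, "phi",
                          untestable=True, reason=f"only {S} informative sites")
    incompat = four_gamete_matrix(table).astype(float)
    pos = table.positions().astype(float)
    dist = np.abs(pos[:, None] - pos[None, :])
    if table.circular:
        dist = np.minimum(dist, table.alignment_length - dist)
    near = (dist <= window)
    iu = np.triu_indices(S, 1)
    sel = near[iu]
    if not sel.any():
        return TestResult(float("nan"), float("nan"), 0, "phi", untestable=True,
                          reason="no informative site pairs within window")
    obs = float(incompat[iu][sel].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(S)
        count += float(incompat[perm][:, perm][iu][sel].mean()) <= obs
    p = (1 + count) / (1 + n_perm)
    return TestResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      method="phi", window_params={"window_bp": window,
                                                   "n_informative_sites": S})


def write_blocks_bed(blocks: list[HaplotypeBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"block\t{b.start_column}\t{b.end_column}\n")


def write_test_results(results: list[TestResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tchunk\tstatistic\tp_value\tn_perm\tuntestable\treason\n")
        for r in results:
            chunk = r.window_params.get("chunk", "")
            fh.write(f"{r.method}\t{chunk}\t{r.statistic:.6g}\t{r.p_value:.6g}\t"
                     f"{r.n_permutations}\t{int(r.untestable)}\t{r.reason}\n")
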