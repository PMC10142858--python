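"""Composite-likelihood estimation of the population recombination parameter.

A two-locus sample-configuration likelihood table is estimated by Monte
Carlo coalescent simulation over a rho grid (rather than the exact
recursion), a constant-rho estimator maximizes the composite likelihood
over site pairs and reports r/m both as rho/theta_w and rho/pi, and a
variable-rho map is sampled by a change-point MCMC with a block penalty.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import msprime
import numpy as np

from .alignment import SiteTable


class EstimationError(RuntimeError):
    pass


def default_rho_grid(n_points: int = 101, rho_min: float = 0.01,
                     rho_max: float = 100.0) -> np.ndarray:
    """0 plus a geometric ladder spanning (rho_min, rho_max]."""
    return np.concatenate([[0.0], np.geomspace(rho_min, rho_max, n_points - 1)])


def canonical_config(n00: int, n01: int, n10: int, n11: int) -> tuple[int, int, int, int]:
    """Canonical form under allele relabeling at either locus and locus swap."""
    best = None
    for cfg in ((n00, n01, n10, n11),):
        a, b, c, d = cfg
        images = [
            (a, b, c, d),
            (c, d, a, b),      # swap alleles at locus 1
            (b, a, d, c),      # swap alleles at locus 2
            (d, c, b, a),      # both
        ]
        images += [(x[0], x[2], x[1], x[3]) for x in images]  # swap loci
        cand = min(images)
        best = cand if best is None else min(best, cand)
    return best


@dataclass
class LookupTable:
    n: int
    theta_site: float
    rho_grid: np.ndarray
    configs: list[tuple[int, int, int, int]]
    log_likelihood: np.ndarray  # (n_configs, n_grid)
    n_sims_per_gridpoint: int
    seed: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {cfg: i for i, cfg in enumerate(self.configs)}
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)

    @property
    def floor_loglik(self) -> float:
        return float(np.log(0.5 / self.n_sims_per_gridpoint))

    def row(self, config: tuple[int, int, int, int]) -> np.ndarray:
        """Log-likelihood over the grid for a (raw, uncanonicalized) config;
        unobserved configs get the pseudocount floor at every grid point."""
        cfg = canonical_config(*config)
        i = self._index.get(cfg)
        if i is None:
            return np.full(len(self.rho_grid), self.floor_loglik)
        return self.log_likelihood[i]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = {"n": self.n, "theta_site": self.theta_site,
                      "rho_grid": self.rho_grid.tolist(),
                      "n_sims_per_gridpoint": self.n_sims_per_gridpoint,
                      "seed": self.seed}
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("n00\tn01\tn10\tn11\t" +
                     "\t".join(f"rho_{g:g}" for g in self.rho_grid) + "\n")
            for cfg, row in zip(self.configs, self.log_likelihood):
                fh.write("\t".join(map(str, cfg)) + "\t" +
                         "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "LookupTable":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            fh.readline()
            configs, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                configs.append(tuple(int(x) for x in parts[:4]))
                rows.append([float(x) for x in parts[4:]])
        return cls(n=header["n"], theta_site=header["theta_site"],
                   rho_grid=np.array(header["rho_grid"]), configs=configs,
                   log_likelihood=np.array(rows),
                   n_sims_per_gridpoint=header["n_sims_per_gridpoint"],
                   seed=header["seed"])


def _sample_branch_leaves(tree, rng: np.random.Generator, n: int) -> np.ndarray:
    """Place one mutation uniformly on the tree (branch chosen proportional
    to length); return the boolean derived vector over samples."""
    nodes = []
    lengths = []
    for u in tree.nodes():
        bl = tree.branch_length(u)
        if bl > 0:
            nodes.append(u)
            lengths.append(bl)
    lengths = np.asarray(lengths)
    pick = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
    derived = np.zeros(n, dtype=bool)
    for s in tree.samples(pick):
        derived[s] = True
    return derived


def build_two_locus_table(n: int, theta_site: float = 0.003,
                          rho_grid: np.ndarray | None = None,
                          n_sims: int = 2000, seed: int = 1) -> LookupTable:
    """Estimate P(two-locus config | rho, n) by coalescent simulation.

    For each grid rho, two loci one map unit apart are simulated and a
    single mutation is placed uniformly on each marginal tree
    (infinite-sites, so both loci segregate by construction); the resulting
    haplotype-count configurations are tabulated in canonical form.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    if rho_grid[0] != 0 or np.any(np.diff(rho_grid) <= 0):
        raise ValueError("rho_grid must be sorted and start at 0")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, int, int, int], np.ndarray] = {}
    for gi, rho in enumerate(rho_grid):
        msp_seed = int(rng.integers(1, 2**31 - 1))
        reps = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1, sequence_length=2,
            recombination_rate=rho / 2.0, num_replicates=n_sims,
            random_seed=msp_seed)
        for ts in reps:
            left = _sample_branch_leaves(ts.at(0.5), rng, n)
            right = _sample_branch_leaves(ts.at(1.5), rng, n)
            n11 = int((left & right).sum())
            n10 = int((left & ~right).sum())
            n01 = int((~left & right).sum())
            n00 = n - n11 - n10 - n01
            cfg = canonical_config(n00, n01, n10, n11)
            if cfg not in counts:
                counts[cfg] = np.zeros(len(rho_grid), dtype=np.int64)
            counts[cfg][gi] += 1
    if not counts:
        raise EstimationError("no segregating configurations observed")
    configs = sorted(counts)
    mat = np.vstack([counts[c] for c in configs]).astype(float)
    mat = np.maximum(mat, 0.5)
    loglik = np.log(mat / n_sims)
    return LookupTable(n=n, theta_site=theta_site, rho_grid=rho_grid,
                       configs=configs, log_likelihood=loglik,
                       n_sims_per_gridpoint=n_sims, seed=seed)


# ---------------------------------------------------------------------------
# composite likelihood over site pairs
# ---------------------------------------------------------------------------

def _pair_data(sites: SiteTable, table: LookupTable, circular: bool):
    """Per usable pair: lookup row matrix and physical distance vector."""
    G = sites.genotype_matrix()
    pos = sites.positions()
    L = sites.alignment_length
    rows, dists = [], []
    n_skipped = 0
    for i, j in itertools.combinations(range(len(sites)), 2):
        gi, gj = G[i], G[j]
        ok = (gi >= 0) & (gj >= 0)
        if int(ok.sum()) != table.n:
            n_skipped += 1
            continue
        a, b = gi[ok], gj[ok]
        if a.min() == a.max() or b.min() == b.max():
            n_skipped += 1
            continue
        n11 = int((a & b).sum())
        n10 = int((a & (1 - b)).sum())
        n01 = int(((1 - a) & b).sum())
        n00 = table.n - n11 - n10 - n01
        rows.append(table.row((n00, n01, n10, n11)))
        d = abs(int(pos[j]) - int(pos[i]))
        if circular:
            d = min(d, L - d)
        dists.append(float(d))
    if not rows:
        raise EstimationError("no usable biallelic site pairs")
    return np.vstack(rows), np.asarray(dists), n_skipped


def _composite_loglik(rowmat: np.ndarray, dists: np.ndarray, grid: np.ndarray,
                      rho_site: float | np.ndarray) -> np.ndarray:
    """CL(rho_site) via linear interpolation of per-pair log-likelihood in
    the pair's total rho = rho_site * distance (clamped to the grid)."""
    rho_site = np.atleast_1d(np.asarray(rho_site, dtype=float))
    out = np.empty(len(rho_site))
    P = len(dists)
    for k, rs in enumerate(rho_site):
        rt = np.clip(rs * dists, grid[0], grid[-1])
        hi = np.clip(np.searchsorted(grid, rt), 1, len(grid) - 1)
        lo = hi - 1
        w = (rt - grid[lo]) / (grid[hi] - grid[lo])
        ll = rowmat[np.arange(P), lo] * (1 - w) + rowmat[np.arange(P), hi] * w
        out[k] = ll.sum()
    return out


def watterson_theta(sites: SiteTable, n: int) -> float:
    a_n = sum(1.0 / i for i in range(1, n))
    return len(sites) / (a_n * sites.alignment_length)


def pairwise_pi(sites: SiteTable, n: int) -> float:
    tot = 0.0
    for s in sites.sites:
        p = s.minor_count / n
        tot += 2 * p * (1 - p) * n / (n - 1)
    return tot / sites.alignment_length


@dataclass
class ConstantRhoEstimate:
    rho_site: float
    r_over_m: dict[str, float]
    composite_loglik: float
    n_pairs: int
    n_pairs_skipped: int


def estimate_constant_rho(sites: SiteTable, table: LookupTable,
                          circular: bool | None = None,
                          n_candidates: int = 400) -> ConstantRhoEstimate:
    """Grid-interpolated argmax of the composite likelihood CL(rho_site).

    Pairs whose shared non-missing sample count differs from the table's n
    are skipped (counted). r/m is reported both as rho/theta_w and rho/pi.
    """
    if circular is None:
        circular = sites.circular
    rowmat, dists, n_skipped = _pair_data(sites, table, circular)
    grid = table.rho_grid
    d_min, d_max = dists.min(), dists.max()
    lo = max(grid[1] / d_max, 1e-12)
    hi = grid[-1] / max(d_min, 1.0)
    cands = np.concatenate([[0.0], np.geomspace(lo, hi, n_candidates - 1)])
    cl = _composite_loglik(rowmat, dists, grid, cands)
    best = int(np.argmax(cl))
    rho_hat = float(cands[best])
    theta_w = watterson_theta(sites, table.n)
    pi = pairwise_pi(sites, table.n)
    rm = {"rho_over_theta_w": rho_hat / theta_w if theta_w > 0 else float("nan"),
          "rho_over_pi": rho_hat / pi if pi > 0 else float("nan")}
    return ConstantRhoEstimate(rho_site=rho_hat, r_over_m=rm,
                               composite_loglik=float(cl[best]),
                               n_pairs=len(dists), n_pairs_skipped=n_skipped)


# ---------------------------------------------------------------------------
# variable-rho map (change-point MCMC with block penalty)
# ---------------------------------------------------------------------------

@dataclass
class RhoMap:
    windows: list[tuple[int, int, float, float, float]]  # start, end, mean, lo, hi
    global_mean_rho: float
    global_ci: tuple[float, float]
    r_over_m: dict[str, float]
    n_samples_retained: int
    n_changepoints_mean: float
    acceptance_rate: float
    warning: str = ""

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\tmean_rho\tci_low\tci_high\n")
            for s, e, m, lo, hi in self.windows:
                fh.write(f"{s}\t{e}\t{m:.6g}\t{lo:.6g}\t{hi:.6g}\n")


def estimate_variable_rho(sites: SiteTable, table: LookupTable,
                          block_penalty: float = 5.0, n_iter: int = 100_000,
                          thin: int = 500, burnin_fraction: float = 0.25,
                          window: int = 2000, seed: int = 1,
                          circular: bool | None = None,
                          rho_bounds: tuple[float, float] | None = None) -> RhoMap:
    """Sample piecewise-constant rho maps between segregating sites.

    The state is a set of change points at inter-site gap boundaries with a
    log-uniform rho on each segment; the prior charges ``block_penalty``
    per change point. The posterior is summarized per ``window`` bp as the
    mean and central 95% credible interval.
    """
    if circular is None:
        circular = sites.circular
    if n_iter < thin:
        raise ValueError("n_iter must be >= thin")
    S = len(sites)
    if S < 3:
        raise EstimationError("need >= 3 segregating sites")
    pos = sites.positions().astype(float)
    L = sites.alignment_length
    G = sites.genotype_matrix()
    grid = table.rho_grid

    # per-pair lookup rows and the gap-overlap structure: the rho distance of
    # pair (i, j) is the sum over gaps k in [i, j) of rho_k * gap_len_k
    gap_len = np.diff(pos)  # S-1 gaps
    pair_i, pair_j, rows = [], [], []
    for i, j in itertools.combinations(range(S), 2):
        gi, gj = G[i], G[j]
        ok = (gi >= 0) & (gj >= 0)
        if int(ok.sum()) != table.n:
            continue
        a, b = gi[ok], gj[ok]
        if a.min() == a.max() or b.min() == b.max():
            continue
        n11 = int((a & b).sum())
        n10 = int((a & (1 - b)).sum())
        n01 = int(((1 - a) & b).sum())
        n00 = table.n - n11 - n10 - n01
        rows.append(table.row((n00, n01, n10, n11)))
        pair_i.append(i)
        pair_j.append(j)
    if not rows:
        raise EstimationError("no usable biallelic site pairs")
    rowmat = np.vstack(rows)
    pair_i = np.asarray(pair_i)
    pair_j = np.asarray(pair_j)
    P = len(pair_i)

    rng = np.random.default_rng(seed)

    def loglik(gap_rho: np.ndarray) -> float:
        cum = np.concatenate([[0.0], np.cumsum(gap_rho * gap_len)])
        rt = np.clip(cum[pair_j] - cum[pair_i], grid[0], grid[-1])
        hi_idx = np.clip(np.searchsorted(grid, rt), 1, len(grid) - 1)
        lo_idx = hi_idx - 1
        w = (rt - grid[lo_idx]) / (grid[hi_idx] - grid[lo_idx])
        ll = rowmat[np.arange(P), lo_idx] * (1 - w) + rowmat[np.arange(P), hi_idx] * w
        return float(ll.sum())

    # initial state: one segment at the constant-rho estimate; the
    # log-uniform rho prior spans three decades either side of it unless
    # explicit bounds are given
    init = estimate_constant_rho(sites, table, circular=circular,
                                 n_candidates=150).rho_site
    init = max(init, 1e-7)
    if rho_bounds is None:
        rho_bounds = (init / 1e3, init * 1e3)
    log_lo, log_hi = np.log(rho_bounds[0]), np.log(rho_bounds[1])
    init = float(np.clip(init, rho_bounds[0], rho_bounds[1]))
    n_gaps = S - 1
    changepts: list[int] = []          # sorted gap indices where a new segment starts
    seg_rho = [init]                   # len(changepts) + 1 values

    def expand(cps, vals) -> np.ndarray:
        gap_rho = np.empty(n_gaps)
        bounds = [0] + list(cps) + [n_gaps]
        for s_idx in range(len(vals)):
            gap_rho[bounds[s_idx]:bounds[s_idx + 1]] = vals[s_idx]
        return gap_rho

    cur_ll = loglik(expand(changepts, seg_rho))
    n_accept = 0
    n_prop = 0
    retained_gap_rho = []
    retained_k = []
    burnin = int(n_iter * burnin_fraction)

    for it in range(1, n_iter + 1):
        move = rng.random()
        n_prop += 1
        if move < 0.6 or n_gaps < 2:
            # perturb one segment's rho on the log scale (mixed step sizes)
            s_idx = int(rng.integers(0, len(seg_rho)))
            old = seg_rho[s_idx]
            step = 0.5 if rng.random() < 0.5 else 2.0
            prop = float(np.exp(np.log(old) + rng.uniform(-step, step)))
            if not (rho_bounds[0] <= prop <= rho_bounds[1]):
                pass
            else:
                seg_rho[s_idx] = prop
                new_ll = loglik(expand(changepts, seg_rho))
                if np.log(rng.random()) < new_ll - cur_ll:
                    cur_ll = new_ll
                    n_accept += 1
                else:
                    seg_rho[s_idx] = old
        elif move < 0.8:
            # birth: add a change point, draw the new right-segment rho from prior
            avail = sorted(set(range(1, n_gaps)) - set(changepts))
            if avail:
                cp = int(avail[int(rng.integers(0, len(avail)))])
                idx = int(np.searchsorted(changepts, cp))
                new_rho = float(np.exp(rng.uniform(log_lo, log_hi)))
                cps = changepts[:idx] + [cp] + changepts[idx:]
                vals = seg_rho[:idx + 1] + [new_rho] + seg_rho[idx + 1:]
                new_ll = loglik(expand(cps, vals))
                if np.log(rng.random()) < new_ll - cur_ll - block_penalty:
                    changepts, seg_rho, cur_ll = cps, vals, new_ll
                    n_accept += 1
        else:
            # death: remove a change point, merge into the left segment
            if changepts:
                idx = int(rng.integers(0, len(changepts)))
                cps = changepts[:idx] + changepts[idx + 1:]
                vals = seg_rho[:idx + 1] + seg_rho[idx + 2:]
                new_ll = loglik(expand(cps, vals))
                if np.log(rng.random()) < new_ll - cur_ll + block_penalty:
                    changepts, seg_rho, cur_ll = cps, vals, new_ll
                    n_accept += 1
        if it > burnin and (it - burnin) % thin == 0:
            retained_gap_rho.append(expand(changepts, seg_rho).copy())
            retained_k.append(len(changepts))

    acc = n_accept / max(n_prop, 1)
    warning = ""
    if acc < 0.01:
        warning = f"low MCMC acceptance rate ({acc:.4f}); chain may not have mixed"
    draws = np.vstack(retained_gap_rho) if retained_gap_rho else np.empty((0, n_gaps))

    # per-window posterior summaries: overlap-weighted mean rho per draw
    windows = []
    starts = np.arange(0, L, window)
    for ws in starts:
        we = min(ws + window, L)
        lo_edge = np.maximum(pos[:-1], ws)
        hi_edge = np.minimum(pos[1:], we)
        ov = np.clip(hi_edge - lo_edge, 0, None)
        if ov.sum() == 0 or draws.size == 0:
            windows.append((int(ws), int(we), float("nan"), float("nan"), float("nan")))
            continue
        per_draw = (draws * ov).sum(axis=1) / ov.sum()
        windows.append((int(ws), int(we), float(per_draw.mean()),
                        float(np.quantile(per_draw, 0.025)),
                        float(np.quantile(per_draw, 0.975))))
    if draws.size:
        global_per_draw = (draws * gap_len).sum(axis=1) / gap_len.sum()
        global_mean = float(global_per_draw.mean())
        global_ci = (float(np.quantile(global_per_draw, 0.025)),
                     float(np.quantile(global_per_draw, 0.975)))
    else:
        global_mean = float("nan")
        global_ci = (float("nan"), float("nan"))
    theta_w = watterson_theta(sites, table.n)
    pi = pairwise_pi(sites, table.n)
    rm = {"rho_over_theta_w": global_mean / theta_w if theta_w > 0 else float("nan"),
          "rho_over_pi": global_mean / pi if pi > 0 else float("nan")}
    return RhoMap(windows=windows, global_mean_rho=global_mean,
                  global_ci=global_ci, r_over_m=rm,
                  n_samples_retained=len(retained_k),
                  n_changepoints_mean=float(np.mean(retained_k)) if retained_k else 0.0,
                  acceptance_rate=acc, warning=warning)


def retained_sample_count(n_iter: int, thin: int, burnin_fraction: float) -> int:
    """Number of MCMC draws kept after burn-in at the given thinning."""
    burnin = int(n_iter * burnin_fraction)
    return (n_iter - burnin) // thin
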