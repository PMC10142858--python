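"""End-to-end orchestration of the recombination suite and the
heteroplasmy survey from a single INI-style config, with per-stage
logging, derived sub-seeds and a config hash stamped into every output.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alignment as aln_mod
from . import heteroplasmy as het_mod
from . import recomb, rho
from .simulate import ReadSet

log = logging.getLogger("mitorec")


@dataclass
class RunConfig:
    alignment_path: str = ""
    circular: bool = True
    chunk_sizes: list[int] = field(default_factory=lambda: [10000, 20000])
    region: tuple[int, int] | None = None
    maxchi_window_fraction: float = 2.0 / 3.0
    phi_window: int = 100
    rho_map_window: int = 2000
    n_perm: int = 999
    seed: int = 1
    outdir: str = "mitorec_out"
    # rho estimation
    rho_table_path: str = ""
    rho_n_sims: int = 1000
    rho_grid_points: int = 21
    rho_mcmc_iter: int = 100_000
    rho_mcmc_thin: int = 500
    rho_block_penalty: float = 5.0
    rho_burnin_fraction: float = 0.25
    # heteroplasmy
    assemblies_path: str = ""
    samples_table: str = ""   # TSV: sample_id, fastq, major_type, group
    candidates: list[str] = field(default_factory=list)
    kmer_length: int = 251
    min_diff: int = 2
    outlier_rho: float = 1.0

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(str(path))
        cfg = cls()
        g = cp["general"] if "general" in cp else {}
        cfg.seed = int(g.get("seed", cfg.seed))
        cfg.outdir = g.get("outdir", cfg.outdir)
        cfg.n_perm = int(g.get("n_perm", cfg.n_perm))
        if "input" in cp:
            i = cp["input"]
            cfg.alignment_path = i.get("alignment", cfg.alignment_path)
            cfg.circular = i.getboolean("circular", cfg.circular)
            cfg.assemblies_path = i.get("assemblies", cfg.assemblies_path)
            cfg.samples_table = i.get("samples", cfg.samples_table)
        if "recomb" in cp:
            r = cp["recomb"]
            if "chunk_sizes" in r:
                cfg.chunk_sizes = [int(x) for x in r["chunk_sizes"].split(",")]
            if "region" in r and r["region"]:
                lo, hi = r["region"].replace("-", ":").split(":")
                cfg.region = (int(lo), int(hi))
            cfg.maxchi_window_fraction = r.getfloat(
                "maxchi_window_fraction", cfg.maxchi_window_fraction)
            cfg.phi_window = r.getint("phi_window", cfg.phi_window)
        if "rho" in cp:
            r = cp["rho"]
            cfg.rho_table_path = r.get("table", cfg.rho_table_path)
            cfg.rho_n_sims = r.getint("n_sims", cfg.rho_n_sims)
            cfg.rho_grid_points = r.getint("grid_points", cfg.rho_grid_points)
            cfg.rho_mcmc_iter = r.getint("mcmc_iter", cfg.rho_mcmc_iter)
            cfg.rho_mcmc_thin = r.getint("mcmc_thin", cfg.rho_mcmc_thin)
            cfg.rho_block_penalty = r.getfloat("block_penalty", cfg.rho_block_penalty)
            cfg.rho_map_window = r.getint("map_window", cfg.rho_map_window)
        if "het" in cp:
            h = cp["het"]
            if "candidates" in h:
                cfg.candidates = [x.strip() for x in h["candidates"].split(",")]
            cfg.kmer_length = h.getint("kmer_length", cfg.kmer_length)
            cfg.min_diff = h.getint("min_diff", cfg.min_diff)
            cfg.outlier_rho = h.getfloat("outlier_rho", cfg.outlier_rho)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for h in list(log.handlers):
        log.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(fh)
    log.addHandler(sh)
    log.setLevel(logging.INFO)


def _stamp(path: Path, cfg_hash: str) -> None:
    text = path.read_text()
    path.write_text(f"# config_hash={cfg_hash}\n" + text)


def run_recombination_suite(config: RunConfig) -> dict:
    """Four-gamete scan + blocks, Mantel (both statistics, all chunk
    sizes), max-chi2 (whole + region), PHI (region) and rho estimation.

    Stage failures are logged and marked in the report; later stages run.
    """
    outdir = Path(config.outdir)
    _setup_logging(outdir)
    cfg_hash = config.hash()
    ss = np.random.SeedSequence(config.seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31 - 1) + 1) for s in ss.spawn(16)]
    log.info("recombination suite start; config_hash=%s seed=%d", cfg_hash, config.seed)
    report: dict = {"config_hash": cfg_hash, "stages": {}}

    aln = aln_mod.load_alignment(config.alignment_path, circular=config.circular)
    table = aln_mod.extract_biallelic_sites(aln)
    log.info("alignment: %d samples x %d columns; %d biallelic sites",
             aln.n_samples, aln.length, len(table))

    def stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
            # timings go to the log only, keeping the report byte-reproducible
            report["stages"][name] = {"status": "ok"}
            log.info("stage %s ok (%.1fs)", name, time.time() - t0)
            return out
        except Exception as exc:  # noqa: BLE001 - per-stage isolation is the contract
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", name, exc)
            return None

    def fourgamete():
        _, n_viol, n_pairs = recomb.four_gamete_scan(table)
        blocks = recomb.haplotype_blocks(table)
        recomb.write_blocks_bed(blocks, outdir / "haplotype_blocks.bed")
        _stamp(outdir / "haplotype_blocks.bed", cfg_hash)
        pct = recomb.violating_pair_percentage(n_viol, n_pairs) if n_pairs else float("nan")
        return {"n_violating": n_viol, "n_pairs": n_pairs,
                "percent": pct, "n_blocks": len(blocks)}

    fg = stage("four_gamete", fourgamete)
    if fg:
        report["four_gamete"] = fg

    mantel_rows = []

    def mantel():
        out = {}
        si = 0
        for chunk in config.chunk_sizes:
            for stat in ("r2", "Dprime"):
                res = recomb.ld_distance_mantel(
                    aln, chunk_size=chunk, stat=stat, n_perm=config.n_perm,
                    seed=subseeds[si])
                si += 1
                tested = [r for r in res if not r.untestable]
                nsig = sum(1 for r in tested if r.p_value < 0.05)
                out[f"LD{stat}_{chunk}bp"] = {
                    "significant": nsig, "tested": len(tested), "total": len(res)}
                for r in res:
                    r.method = f"mantel-LD{stat}-{chunk}bp"
                mantel_rows.extend(res)
        recomb.write_test_results(mantel_rows, outdir / "mantel_tests.tsv")
        _stamp(outdir / "mantel_tests.tsv", cfg_hash)
        return out

    mt = stage("mantel", mantel)
    if mt:
        report["mantel"] = mt

    def maxchi():
        out = {}
        res = recomb.max_chi2_test(aln, window_fraction=config.maxchi_window_fraction,
                                   n_perm=config.n_perm, seed=subseeds[8])
        out["whole"] = {"statistic": res.statistic, "p": res.p_value}
        rows = [res]
        if config.region:
            res_r = recomb.max_chi2_test(
                aln, window_fraction=config.maxchi_window_fraction,
                n_perm=config.n_perm, seed=subseeds[9], region=config.region)
            out["region"] = {"statistic": res_r.statistic, "p": res_r.p_value}
            rows.append(res_r)
        recomb.write_test_results(rows, outdir / "maxchi_tests.tsv")
        _stamp(outdir / "maxchi_tests.tsv", cfg_hash)
        return out

    mc = stage("max_chi2", maxchi)
    if mc:
        report["max_chi2"] = mc

    def phi():
        res = recomb.phi_test(aln, window=config.phi_window, n_perm=config.n_perm,
                              seed=subseeds[10], region=config.region)
        recomb.write_test_results([res], outdir / "phi_test.tsv")
        _stamp(outdir / "phi_test.tsv", cfg_hash)
        return {"statistic": res.statistic, "p": res.p_value,
                "untestable": res.untestable}

    ph = stage("phi", phi)
    if ph:
        report["phi"] = ph

    def rho_stage():
        if config.rho_table_path:
            lut = rho.LookupTable.read_tsv(config.rho_table_path)
        else:
            grid = rho.default_rho_grid(n_points=config.rho_grid_points)
            lut = rho.build_two_locus_table(n=aln.n_samples, rho_grid=grid,
                                            n_sims=config.rho_n_sims,
                                            seed=subseeds[11])
            lut.write_tsv(outdir / "two_locus_table.tsv")
        const = rho.estimate_constant_rho(table, lut)
        rmap = rho.estimate_variable_rho(
            table, lut, block_penalty=config.rho_block_penalty,
            n_iter=config.rho_mcmc_iter, thin=config.rho_mcmc_thin,
            burnin_fraction=config.rho_burnin_fraction,
            window=config.rho_map_window, seed=subseeds[12])
        rmap.write_tsv(outdir / "rho_map.tsv")
        _stamp(outdir / "rho_map.tsv", cfg_hash)
        return {"constant_rho": const.rho_site, "r_over_m": const.r_over_m,
                "map_global_mean": rmap.global_mean_rho,
                "acceptance_rate": rmap.acceptance_rate}

    rh = stage("rho", rho_stage)
    if rh:
        report["rho"] = rh

    _write_recomb_summary(report, outdir / "summary.txt", config)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "config_used.json").write_text(
        json.dumps(config.__dict__, indent=1, sort_keys=True, default=str))
    log.info("recombination suite done")
    return report


def _write_recomb_summary(report: dict, path: Path, config: RunConfig) -> None:
    lines = [f"# config_hash={report['config_hash']}",
             "Tests for recombination in the mitochondrial genome",
             ""]
    header = f"{'test':<22}{'whole alignment':<20}{'region':<12}"
    lines.append(header)
    mt = report.get("mantel", {})
    for key, d in mt.items():
        lines.append(f"{key:<22}{d['significant']}/{d['tested']:<18}{'-':<12}")
    mc = report.get("max_chi2", {})
    if mc:
        whole = f"{mc['whole']['p']:.3g}"
        reg = f"{mc['region']['p']:.3g}" if "region" in mc else "-"
        lines.append(f"{'Maximum chi^2':<22}{whole:<20}{reg:<12}")
    ph = report.get("phi", {})
    if ph:
        p = "-" if ph.get("untestable") else f"{ph['p']:.3g}"
        lines.append(f"{'PHI':<22}{'-':<20}{p:<12}")
    fg = report.get("four_gamete", {})
    if fg:
        lines.append("")
        lines.append(f"four-gamete violating pairs: {fg['n_violating']}/{fg['n_pairs']}"
                     f" ({fg['percent']}%)")
        lines.append(f"haplotype blocks: {fg['n_blocks']}")
    rh = report.get("rho", {})
    if rh:
        lines.append(f"constant rho per site: {rh['constant_rho']:.4g}")
        lines.append(f"r/m (rho/theta_w): {rh['r_over_m']['rho_over_theta_w']:.4g}"
                     f"; (rho/pi): {rh['r_over_m']['rho_over_pi']:.4g}")
    path.write_text("\n".join(lines) + "\n")


def _read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((h.strip().lstrip("@"), seq))
    return reads


def run_heteroplasmy_survey(config: RunConfig) -> dict:
    """Per-sample H-hat, beta outlier flags, group medians and the
    Mann-Whitney comparison between the two groups in the samples table."""
    outdir = Path(config.outdir)
    _setup_logging(outdir)
    cfg_hash = config.hash()
    log.info("heteroplasmy survey start; config_hash=%s", cfg_hash)
    report: dict = {"config_hash": cfg_hash, "stages": {}}

    assemblies = aln_mod.load_alignment(config.assemblies_path, circular=True)
    samples = []
    with open(config.samples_table) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            samples.append(dict(zip(header, line.strip().split("\t"))))
    candidates = config.candidates or list(assemblies.sample_ids)

    libraries: dict[tuple[str, str], het_mod.KmerLibrary] = {}
    needed = set()
    for s in samples:
        for c in candidates:
            if c != s["major_type"]:
                needed.add((c, s["major_type"]))
                needed.add((s["major_type"], c))
    for x, y in sorted(needed):
        libraries[(x, y)] = het_mod.build_kmer_library(
            assemblies, x, y, k=config.kmer_length, min_diff=config.min_diff)
        log.info("library K(%s,%s): %d k-mers", x, y, libraries[(x, y)].size)

    estimates = []
    groups: dict[str, list[float]] = {}
    for s in samples:
        reads = _read_fastq(s["fastq"])
        if not reads:
            log.warning("sample %s: no reads", s["sample_id"])
            continue
        rlen = len(reads[0][1])
        rs = ReadSet(reads=[r for r in reads if len(r[1]) == rlen], read_length=rlen)
        try:
            est = het_mod.estimate_heteroplasmy(
                rs, major=s["major_type"], candidates=candidates,
                libraries=libraries, sample_id=s["sample_id"])
        except het_mod.HeteroplasmyEstimationError as exc:
            log.error("sample %s: %s", s["sample_id"], exc)
            continue
        estimates.append(est)
        groups.setdefault(s.get("group", "all"), []).append(est.h_hat)
    het_mod.write_estimates_tsv(estimates, outdir / "heteroplasmy.tsv")
    _stamp(outdir / "heteroplasmy.tsv", cfg_hash)
    report["n_samples"] = len(estimates)

    all_h = [e.h_hat for e in estimates]
    if len(all_h) >= 5:
        out = het_mod.beta_outlier_detection(all_h, rho=config.outlier_rho)
        report["outliers"] = [estimates[i].sample_id
                              for i in np.nonzero(out.flags)[0]]
    else:
        report["outliers"] = None
        log.info("too few samples for outlier detection")

    report["group_medians"] = {g: float(np.median(v)) for g, v in groups.items()}
    gnames = sorted(groups)
    if len(gnames) == 2 and all(len(groups[g]) >= 1 for g in gnames) \
            and len(all_h) >= 2 and min(len(groups[g]) for g in gnames) >= 1 \
            and len(groups[gnames[0]]) + len(groups[gnames[1]]) >= 3:
        res = het_mod.mann_whitney_test(groups[gnames[0]], groups[gnames[1]])
        report["mann_whitney"] = {"U": res.statistic, "p": res.p_value,
                                  "method": res.method, "groups": gnames}
    else:
        report["mann_whitney"] = {"skipped": True,
                                  "reason": "need two groups with enough samples"}
        log.info("Mann-Whitney skipped: %s", report["mann_whitney"]["reason"])

    (outdir / "het_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("heteroplasmy survey done")
    return report
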