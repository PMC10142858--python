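"""Nucleotide diversity and selection-efficacy statistics.

Per-site pi with pairwise deletion, Ne*mu under uniparental/biparental
inheritance, nonsynonymous/synonymous diversity by the modified
Nei-Gojobori method (transition/transversion-weighted site counts), and a
codon-bootstrap comparison of pi_n/pi_s ratios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .alignment import Alignment

_ACGT = (b"A", b"C", b"G", b"T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class CodonAlignmentError(ValueError):
    pass


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero (the
    convention used in printed reports)."""
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_UP, Decimal
    d = Decimal(str(x))
    quantum = Decimal(1).scaleb(d.adjusted() - sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class DiversityResult:
    pi: float
    n_sequences: int
    n_sites_used: float
    window_values: list[tuple[int, int, float]] | None = None


@dataclass
class NeMuEstimate:
    ne_mu: float
    inheritance: str

    @property
    def rounded(self) -> float:
        return round_sigfigs(self.ne_mu, 2)


@dataclass
class CodonDiversityResult:
    pi_n: float
    pi_s: float
    n_syn_sites: float
    n_nonsyn_sites: float

    @property
    def ratio(self) -> float | None:
        if self.pi_s == 0:
            return None
        return self.pi_n / self.pi_s


@dataclass
class BootstrapResult:
    support: float
    n_boot: int
    n_undefined: int
    replicates: list[tuple[float | None, float | None]] = field(default_factory=list)


def _pair_diff_count(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    usable = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    return int((a[usable] != b[usable]).sum()), int(usable.sum())


def nucleotide_diversity(aln: Alignment, window: int | None = None) -> DiversityResult:
    """Average pairwise per-site diversity with pairwise deletion of gaps/N."""
    if aln.n_samples < 2:
        raise ValueError("need >=2 sequences")
    pairs = list(itertools.combinations(range(aln.n_samples), 2))
    props, comp = [], []
    for i, j in pairs:
        d, c = _pair_diff_count(aln.matrix[i], aln.matrix[j])
        if c > 0:
            props.append(d / c)
            comp.append(c)
    if not props:
        raise ValueError("no comparable (non-gap) columns in alignment")
    pi = float(np.mean(props))
    windows = None
    if window is not None:
        windows = []
        for start in range(0, aln.length, window):
            end = min(start + window, aln.length)
            sub_props = []
            for i, j in pairs:
                d, c = _pair_diff_count(aln.matrix[i, start:end], aln.matrix[j, start:end])
                if c > 0:
                    sub_props.append(d / c)
            wpi = float(np.mean(sub_props)) if sub_props else float("nan")
            windows.append((start, end, wpi))
    return DiversityResult(pi=pi, n_sequences=aln.n_samples,
                           n_sites_used=float(np.mean(comp)), window_values=windows)


def ne_mu(pi: float, inheritance: str) -> NeMuEstimate:
    """Ne*mu from per-site diversity: theta = 2*Ne*mu (uniparental haploid)
    or 4*Ne*mu (biparental diploid)."""
    if pi < 0:
        raise ValueError("pi must be >= 0")
    if inheritance == "uniparental_haploid":
        return NeMuEstimate(ne_mu=pi / 2.0, inheritance=inheritance)
    if inheritance == "biparental_diploid":
        return NeMuEstimate(ne_mu=pi / 4.0, inheritance=inheritance)
    raise ValueError(f"unknown inheritance mode: {inheritance!r}")


# ---------------------------------------------------------------------------
# modified Nei-Gojobori
# ---------------------------------------------------------------------------

_CODE_IDS = {"standard": 1, "mold_mito": 4}


def _codon_to_aa(code: str) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[_CODE_IDS[code]]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _site_weights(tstv: float) -> dict[bool, float]:
    # per position: one transition, two transversions; weights sum to 1
    return {True: tstv / (tstv + 2.0), False: 1.0 / (tstv + 2.0)}


def syn_site_count(codon: str, tstv: float, aa: dict[str, str]) -> float:
    """Fractional synonymous sites of one codon (mutations to stops count
    as nonsynonymous; total sites per codon is exactly 3)."""
    if aa.get(codon, "*") == "*":
        raise CodonAlignmentError(f"stop or invalid codon {codon!r}")
    w = _site_weights(tstv)
    s = 0.0
    for pos in range(3):
        ref = codon[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if aa[mutant] != "*" and aa[mutant] == aa[codon]:
                s += w[_TRANSITION[ref] == alt]
    return s


def codon_path_differences(c1: str, c2: str, aa: dict[str, str]) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all orderings of single-step mutational paths; paths through stop
    codons are excluded when any stop-free path exists."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if aa[nxt] == "*":
                through_stop = True
            if aa[nxt] == aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    clean = [(sd, nd) for ts, sd, nd in paths if not ts]
    use = clean if clean else [(sd, nd) for _, sd, nd in paths]
    sd = float(np.mean([x[0] for x in use]))
    nd = float(np.mean([x[1] for x in use]))
    return sd, nd


def _codon_rows(aln: Alignment) -> list[list[str]]:
    if aln.length % 3 != 0:
        raise CodonAlignmentError(f"alignment length {aln.length} not divisible by 3")
    rows = []
    for seq in aln.sequences():
        rows.append([seq[i:i + 3] for i in range(0, len(seq), 3)])
    return rows


def _validate_no_internal_stops(rows: list[list[str]], aa: dict[str, str]) -> None:
    for r, codons in enumerate(rows):
        for k, c in enumerate(codons[:-1]):
            if all(ch in "ACGT" for ch in c) and aa[c] == "*":
                raise CodonAlignmentError(
                    f"internal stop codon {c} at codon {k} in row {r}")


def pn_ps(codon_aln: Alignment, tstv: float = 2.0, code: str = "mold_mito",
          check_stops: bool = True) -> CodonDiversityResult:
    """Modified Nei-Gojobori pi_n and pi_s.

    Synonymous/nonsynonymous site counts are weighted by the mutation
    probabilities implied by ``tstv`` (transition weight tstv/(tstv+2) per
    position); differences average over all single-step pathway orderings.
    Codons with gaps or N are excluded pairwise. No multiple-hit correction
    is applied.
    """
    aa = _codon_to_aa(code)
    rows = _codon_rows(codon_aln)
    if check_stops:
        _validate_no_internal_stops(rows, aa)
    n = len(rows)
    if n < 2:
        raise ValueError("need >=2 sequences")
    site_cache: dict[str, float] = {}

    def s_count(c: str) -> float:
        if c not in site_cache:
            site_cache[c] = syn_site_count(c, tstv, aa)
        return site_cache[c]

    ps_vals, pn_vals, s_sites_all, n_sites_all = [], [], [], []
    for i, j in itertools.combinations(range(n), 2):
        Sd = Nd = S = N = 0.0
        for c1, c2 in zip(rows[i], rows[j]):
            if not (all(ch in "ACGT" for ch in c1) and all(ch in "ACGT" for ch in c2)):
                continue
            if aa[c1] == "*" or aa[c2] == "*":
                continue
            s1, s2 = s_count(c1), s_count(c2)
            S += (s1 + s2) / 2.0
            N += 3.0 - (s1 + s2) / 2.0
            sd, nd = codon_path_differences(c1, c2, aa)
            Sd += sd
            Nd += nd
        if S + N == 0:
            continue
        ps_vals.append(Sd / S if S > 0 else 0.0)
        pn_vals.append(Nd / N if N > 0 else 0.0)
        s_sites_all.append(S)
        n_sites_all.append(N)
    if not ps_vals:
        raise CodonAlignmentError("no comparable codons between any pair")
    return CodonDiversityResult(
        pi_n=float(np.mean(pn_vals)), pi_s=float(np.mean(ps_vals)),
        n_syn_sites=float(np.mean(s_sites_all)),
        n_nonsyn_sites=float(np.mean(n_sites_all)))


def _resample_codons(aln: Alignment, rng: np.random.Generator) -> Alignment:
    n_codons = aln.length // 3
    idx = rng.integers(0, n_codons, size=n_codons)
    cols = np.concatenate([np.arange(3 * k, 3 * k + 3) for k in idx])
    return Alignment(list(aln.sample_ids), aln.matrix[:, cols])


def bootstrap_ratio_comparison(mito_codon_aln: Alignment, nuclear_codon_aln: Alignment,
                               n_boot: int = 100, seed: int = 1, tstv: float = 2.0,
                               mito_code: str = "mold_mito",
                               nuclear_code: str = "standard") -> BootstrapResult:
    """Fraction of codon-bootstrap replicates with mitochondrial
    pi_n/pi_s > nuclear pi_n/pi_s.

    Codon columns are resampled with replacement independently in each
    alignment; replicates with an undefined ratio on either side count as
    non-support and are tallied separately.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    support = 0
    undefined = 0
    replicates: list[tuple[float | None, float | None]] = []
    for _ in range(n_boot):
        m = pn_ps(_resample_codons(mito_codon_aln, rng), tstv=tstv,
                  code=mito_code, check_stops=False)
        u = pn_ps(_resample_codons(nuclear_codon_aln, rng), tstv=tstv,
                  code=nuclear_code, check_stops=False)
        replicates.append((m.ratio, u.ratio))
        if m.ratio is None or u.ratio is None:
            undefined += 1
        elif m.ratio > u.ratio:
            support += 1
    return BootstrapResult(support=support / n_boot, n_boot=n_boot,
                           n_undefined=undefined, replicates=replicates)
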