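"""Synthetic data generation.

Coalescent haplotype alignments (ancestral recombination graph via msprime,
infinite-sites mutations by default), read sets mixing two mitotypes at a
known minor fraction, and large structural edits. Everything is seeded and
bit-for-bit reproducible.

Scaling convention: haploid samples with population_size=1, so the per-site
population mutation parameter theta equals 2*N*u = u*2 and we pass
``theta_site/2`` (likewise ``rho_site/2``) to msprime.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .alignment import Alignment

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


class ParameterError(ValueError):
    pass


@dataclass
class SimulationParams:
    n_samples: int
    seq_length: int
    theta_site: float
    rho_site: float = 0.0
    circular: bool = True
    seed: int = 1
    finite_sites: bool = False  # Jukes-Cantor on a discrete genome when True

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if self.seq_length < 1:
            raise ParameterError("seq_length must be >= 1")
        if self.theta_site < 0 or self.rho_site < 0:
            raise ParameterError("theta_site and rho_site must be >= 0")


@dataclass
class SimulationTruth:
    """Sidecar truth table for a simulated alignment."""

    n_recombination_events: int
    breakpoints: list[float]
    mutation_positions: list[int]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_recombination_events\t{self.n_recombination_events}\n")
            fh.write("breakpoints\t" + ",".join(f"{b:g}" for b in self.breakpoints) + "\n")
            fh.write("mutation_positions\t"
                     + ",".join(str(p) for p in self.mutation_positions) + "\n")


@dataclass
class ReadSet:
    reads: list[tuple[str, str]]  # (identifier, sequence)
    read_length: int
    source_labels: list[str] | None = None  # "major"/"minor" per read

    def __post_init__(self) -> None:
        for _, seq in self.reads:
            if len(seq) != self.read_length:
                raise ParameterError("read length contract violated")
        if self.source_labels is not None and len(self.source_labels) != len(self.reads):
            raise ParameterError("labels must cover every read")

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource\n")
            labels = self.source_labels or ["?"] * len(self.reads)
            for (rid, _), lab in zip(self.reads, labels):
                fh.write(f"{rid}\t{lab}\n")


def _assign_columns(positions: np.ndarray, length: int) -> np.ndarray:
    """Map continuous mutation positions to distinct integer columns."""
    cols = np.floor(positions).astype(int)
    used: set[int] = set()
    out = np.empty(len(cols), dtype=int)
    for i, c in enumerate(cols):
        c = int(c) % length
        while c in used:
            c = (c + 1) % length
        used.add(c)
        out[i] = c
    if len(used) > length:
        raise ParameterError("more mutations than columns")
    return out


def simulate_haplotypes(params: SimulationParams) -> Alignment:
    """Simulate aligned haplotypes under the coalescent with recombination.

    Returns an Alignment of ``n_samples`` rows; the realized number of
    recombination breakpoints and the mutated columns are attached as
    ``alignment.truth`` (a SimulationTruth).
    """
    if not isinstance(params, SimulationParams):
        raise ParameterError("expected SimulationParams")
    rng = np.random.default_rng(params.seed)
    anc_seed, mut_seed = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=params.n_samples, ploidy=1, population_size=1,
        sequence_length=params.seq_length,
        recombination_rate=params.rho_site / 2.0,
        random_seed=anc_seed)
    mts = msprime.sim_mutations(
        ts, rate=params.theta_site / 2.0, random_seed=mut_seed,
        model=msprime.JC69(), discrete_genome=params.finite_sites)

    L = params.seq_length
    background = _BASES[rng.integers(0, 4, size=L)]
    matrix = np.tile(background, (params.n_samples, 1))

    variant_cols: list[int] = []
    if params.finite_sites:
        for var in mts.variants():
            col = int(var.site.position)
            alleles = np.array([a.encode() for a in var.alleles], dtype="S1")
            matrix[:, col] = alleles[var.genotypes]
            variant_cols.append(col)
    else:
        positions = np.array([s.position for s in mts.sites()])
        if len(positions):
            cols = _assign_columns(positions, L)
            for var, col in zip(mts.variants(), cols):
                alleles = np.array([a.encode() for a in var.alleles], dtype="S1")
                matrix[:, int(col)] = alleles[var.genotypes]
                variant_cols.append(int(col))

    ids = [f"s{i}" for i in range(params.n_samples)]
    aln = Alignment(ids, matrix, circular=params.circular)
    breakpoints = [b for b in ts.breakpoints() if 0 < b < L]
    aln.truth = SimulationTruth(
        n_recombination_events=len(breakpoints),
        breakpoints=breakpoints,
        mutation_positions=sorted(variant_cols))
    return aln


def simulate_mixture_reads(major: str, minor: str, minor_fraction: float,
                           depth: float, read_length: int, error_rate: float = 0.0,
                           seed: int = 1) -> ReadSet:
    """Draw circular shotgun reads from a two-mitotype mixture.

    Each read comes from ``minor`` with probability ``minor_fraction``,
    starts uniformly on the circle (wrapping the origin), and accumulates
    independent substitution errors at ``error_rate`` per base.
    """
    if not (0.0 <= minor_fraction <= 1.0):
        raise ParameterError("minor_fraction must be in [0, 1]")
    if read_length > len(major) or read_length > len(minor):
        raise ParameterError("read_length longer than source sequence")
    if depth <= 0:
        raise ParameterError("depth must be > 0")
    rng = np.random.default_rng(seed)
    sources = {"major": major.upper(), "minor": minor.upper()}
    n_reads = int(round(depth * len(major) / read_length))
    reads: list[tuple[str, str]] = []
    labels: list[str] = []
    for i in range(n_reads):
        label = "minor" if rng.random() < minor_fraction else "major"
        src = sources[label]
        start = int(rng.integers(0, len(src)))
        doubled = src + src[:read_length]
        seq = doubled[start:start + read_length]
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(read_length) < error_rate)[0]
            for h in hits:
                choices = _BASES[_BASES != arr[h]]
                arr[h] = choices[rng.integers(0, len(choices))]
            seq = arr.tobytes().decode()
        reads.append((f"read_{i:06d}", seq))
        labels.append(label)
    return ReadSet(reads=reads, read_length=read_length, source_labels=labels)


def apply_structural_variant(seq: str, kind: str, position: int,
                             payload_or_length) -> str:
    """Apply a large insertion or deletion at ``position`` (0-based).

    Insertions take a nucleotide payload string; deletions take a length.
    """
    if not (0 <= position <= len(seq)):
        raise ParameterError(f"position {position} outside sequence of length {len(seq)}")
    if kind == "insertion":
        payload = str(payload_or_length)
        return seq[:position] + payload + seq[position:]
    if kind == "deletion":
        length = int(payload_or_length)
        if length < 0 or position + length > len(seq):
            raise ParameterError("deletion extends past end of sequence")
        return seq[:position] + seq[position + length:]
    raise ParameterError(f"unknown structural variant kind: {kind!r}")


def watterson_expected_segregating_sites(n: int, length: int, theta_site: float) -> float:
    """E[S] = theta * L * sum_{i=1}^{n-1} 1/i under the neutral coalescent."""
    a_n = sum(1.0 / i for i in range(1, n))
    return theta_site * length * a_n
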