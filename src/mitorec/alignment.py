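"""Whole-mitogenome alignment handling.

Loading aligned FASTA, rotating circular assemblies onto a common origin,
collapsing samples into mitotypes, extracting biallelic segregating sites
and building minimum-spanning haplotype networks.

Coordinates are 0-based, half-open internally; only rendered reports use
1-based positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

VALID_CHARS = frozenset(b"ACGT-N")
MISSING = frozenset(b"-N")


class AlignmentFormatError(ValueError):
    """Raised for ragged, empty or otherwise malformed alignment input."""


class RotationError(RuntimeError):
    """Raised when no acceptable anchor placement exists."""


@dataclass
class Alignment:
    """Gapped multi-sequence matrix over {A,C,G,T,-,N}.

    ``matrix`` is an (n_samples, n_columns) array of single-byte characters.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    circular: bool = False
    coordinate_origin: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("sample_ids do not match matrix rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentFormatError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.matrix[self.sample_ids.index(sample_id)]

    def sequence(self, sample_id: str) -> str:
        return self.row(sample_id).tobytes().decode()

    def sequences(self) -> list[str]:
        return [r.tobytes().decode() for r in self.matrix]

    def subset_columns(self, start: int, end: int) -> "Alignment":
        """Linear column slice [start, end) as a non-circular alignment."""
        return Alignment(list(self.sample_ids), self.matrix[:, start:end],
                         circular=False, coordinate_origin=start)

    @classmethod
    def from_sequences(cls, sample_ids, seqs, circular: bool = False) -> "Alignment":
        seqs = [s.upper().replace("U", "T") for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged sequence lengths: {sorted(lengths)}")
        mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
        return cls(list(sample_ids), mat.copy(), circular=circular)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.sample_ids, self.matrix):
                fh.write(f">{sid}\n")
                seq = row.tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


@dataclass
class Mitotype:
    """A class of samples with identical sequence on unmasked columns."""

    id: str
    representative_sequence: str
    member_sample_ids: list[str]


@dataclass
class Site:
    """One biallelic segregating column."""

    column: int
    major_allele: str
    minor_allele: str
    allele_vector: np.ndarray  # one byte per sequence; b'-'/b'N' => missing
    minor_count: int

    def binary(self) -> np.ndarray:
        """0 = major, 1 = minor, -1 = missing."""
        out = np.full(self.allele_vector.shape, -1, dtype=np.int8)
        out[self.allele_vector == self.major_allele.encode()] = 0
        out[self.allele_vector == self.minor_allele.encode()] = 1
        return out


@dataclass
class SiteTable:
    sites: list[Site]
    alignment_length: int
    circular: bool = False
    sample_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s.column for s in self.sites], dtype=int)

    def genotype_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) int8 matrix of 0/1/-1."""
        if not self.sites:
            return np.empty((0, len(self.sample_ids)), dtype=np.int8)
        return np.vstack([s.binary() for s in self.sites])


@dataclass
class NetworkEdge:
    from_mitotype: str
    to_mitotype: str
    n_differences: int


def load_alignment(path, circular: bool = False) -> Alignment:
    """Read an aligned FASTA file; uppercase, U->T, preserve record order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: need >=2 records, found {len(records)}")
    ids = [r.id for r in records]
    return Alignment.from_sequences(ids, [str(r.seq) for r in records],
                                    circular=circular)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn-", "TGCAtgcaNn-"))[::-1]


def _anchor_scores(doubled: np.ndarray, anchor: np.ndarray, n_offsets: int) -> np.ndarray:
    """Identity counts of anchor against every rotation of a circular sequence."""
    scores = np.zeros(n_offsets, dtype=np.int64)
    for j in range(len(anchor)):
        scores += doubled[j:j + n_offsets] == anchor[j]
    return scores


def rotate_to_reference(seq: str, ref: str, anchor_length: int = 1000,
                        min_identity: float = 0.8) -> str:
    """Rotate a circular sequence so it starts where ``ref`` starts.

    The first ``anchor_length`` bases of ``ref`` are located in ``seq``
    (exact match preferred, highest-identity placement as a fallback; the
    reverse strand is tried when it beats the forward strand).
    """
    if anchor_length > len(seq):
        raise RotationError("anchor longer than sequence")
    anchor = ref[:anchor_length].upper()
    best = None  # (score, strand, offset)
    for strand, s in (("+", seq.upper()), ("-", reverse_complement(seq).upper())):
        doubled = s + s[:anchor_length]
        pos = doubled.find(anchor)
        if pos != -1 and pos < len(s):
            best = (anchor_length, strand, pos)
            break
        arr = np.frombuffer(doubled.encode(), dtype="S1")
        anc = np.frombuffer(anchor.encode(), dtype="S1")
        scores = _anchor_scores(arr, anc, len(s))
        off = int(np.argmax(scores))
        cand = (int(scores[off]), strand, off)
        if best is None or cand[0] > best[0]:
            best = cand
    score, strand, off = best
    if score < min_identity * anchor_length:
        raise RotationError(
            f"no anchor placement above identity {min_identity:.2f} "
            f"(best {score}/{anchor_length} on strand {strand} at offset {off})")
    s = seq.upper() if strand == "+" else reverse_complement(seq).upper()
    return s[off:] + s[:off]


def _consensus(matrix: np.ndarray) -> np.ndarray:
    """Column-wise modal character (gaps included as characters)."""
    cons = np.empty(matrix.shape[1], dtype="S1")
    for j in range(matrix.shape[1]):
        vals, counts = np.unique(matrix[:, j], return_counts=True)
        cons[j] = vals[np.argmax(counts)]
    return cons


def masked_columns(aln: Alignment, homopolymer_min: int = 5,
                   gappy_window: int = 11, gappy_fraction: float = 0.2) -> np.ndarray:
    """Boolean mask of columns to ignore when comparing samples.

    A column is masked when it lies inside, or immediately flanks, a
    homopolymer run of length >= homopolymer_min in the column-consensus,
    or when it falls in any window of ``gappy_window`` columns whose gap
    fraction is >= ``gappy_fraction``.
    """
    L = aln.length
    mask = np.zeros(L, dtype=bool)
    cons = _consensus(aln.matrix)

    # homopolymer runs on the consensus, ignoring gap runs
    j = 0
    while j < L:
        k = j
        while k < L and cons[k] == cons[j]:
            k += 1
        if k - j >= homopolymer_min and cons[j] not in (b"-", b"N"):
            lo = max(0, j - 1)
            hi = min(L, k + 1)
            mask[lo:hi] = True
        j = k

    # gappy windows
    if L >= 1:
        w = min(gappy_window, L)
        gaps = (aln.matrix == b"-").mean(axis=0)
        csum = np.concatenate([[0.0], np.cumsum(gaps)])
        for start in range(0, L - w + 1):
            frac = (csum[start + w] - csum[start]) / w
            if frac >= gappy_fraction:
                mask[start:start + w] = True
    return mask


def collapse_mitotypes(aln: Alignment, homopolymer_min: int = 5,
                       gappy_window: int = 11,
                       gappy_fraction: float = 0.2) -> list[Mitotype]:
    """Merge samples identical on unmasked columns into mitotypes.

    The masked columns are those adjacent to single-nucleotide repeats or
    inside gappy windows; remaining differences define distinct mitotypes.
    """
    mask = masked_columns(aln, homopolymer_min, gappy_window, gappy_fraction)
    keep = ~mask
    keys: dict[bytes, list[int]] = {}
    for i in range(aln.n_samples):
        key = aln.matrix[i, keep].tobytes()
        keys.setdefault(key, []).append(i)
    groups = sorted(keys.values(), key=lambda g: (-len(g), g[0]))
    mitotypes = []
    for rank, idxs in enumerate(groups, start=1):
        # representative: modal full-length sequence among members
        full = {}
        for i in idxs:
            full.setdefault(aln.matrix[i].tobytes(), []).append(i)
        rep = max(full.items(), key=lambda kv: (len(kv[1]), -kv[1][0]))[0]
        mitotypes.append(Mitotype(
            id=f"MT{rank}",
            representative_sequence=rep.decode(),
            member_sample_ids=[aln.sample_ids[i] for i in idxs],
        ))
    return mitotypes


def extract_biallelic_sites(source, min_minor_count: int = 1) -> SiteTable:
    """Biallelic columns (exactly two of A/C/G/T among non-missing entries).

    ``source`` is an Alignment or a list of Mitotype (one row per mitotype).
    Gap and N entries are recorded as missing, never as alleles.
    """
    if isinstance(source, Alignment):
        mat = source.matrix
        ids = list(source.sample_ids)
        circular = source.circular
    else:
        mts = list(source)
        ids = [m.id for m in mts]
        mat = np.frombuffer("".join(m.representative_sequence for m in mts).encode(),
                            dtype="S1").reshape(len(mts), -1)
        circular = False
    n, L = mat.shape
    sites: list[Site] = []
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    for j in range(L):
        col = mat[:, j]
        counts = [(int((col == b).sum()), b) for b in bases]
        present = [(c, b) for c, b in counts if c > 0]
        if len(present) != 2:
            continue
        present.sort(key=lambda cb: (-cb[0], cb[1]))
        (maj_c, maj_b), (min_c, min_b) = present
        if min_c < min_minor_count:
            continue
        sites.append(Site(column=j, major_allele=maj_b.decode(),
                          minor_allele=min_b.decode(),
                          allele_vector=col.copy(), minor_count=min_c))
    return SiteTable(sites=sites, alignment_length=L, circular=circular,
                     sample_ids=ids)


def _pairwise_hamming(a: np.ndarray, b: np.ndarray) -> int:
    usable = ~(np.isin(a, (b"-", b"N")) | np.isin(b, (b"-", b"N")))
    return int((a[usable] != b[usable]).sum())


def haplotype_network(mitotypes: list[Mitotype]) -> list[NetworkEdge]:
    """Minimum-spanning network on pairwise Hamming distances.

    All edges belonging to *some* minimum spanning tree are retained, so
    ties at equal distance are kept (Kruskal with per-weight-class union).
    """
    if len(mitotypes) < 2:
        raise ValueError("need >=2 mitotypes for a network")
    seqs = [np.frombuffer(m.representative_sequence.encode(), dtype="S1")
            for m in mitotypes]
    n = len(mitotypes)
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        edges.append((_pairwise_hamming(seqs[i], seqs[j]), i, j))
    edges.sort(key=lambda e: e[0])

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    result: list[NetworkEdge] = []
    k = 0
    while k < len(edges):
        w = edges[k][0]
        group = []
        while k < len(edges) and edges[k][0] == w:
            group.append(edges[k])
            k += 1
        # an edge is in some MST iff its endpoints are in different components
        # of the graph built from strictly lighter edges
        accepted = [(w, i, j) for w, i, j in group if find(i) != find(j)]
        for w_, i, j in accepted:
            result.append(NetworkEdge(mitotypes[i].id, mitotypes[j].id, w_))
        for _, i, j in accepted:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return result


def write_site_table(table: SiteTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tmajor\tminor\tminor_count\talleles\n")
        for s in table.sites:
            alle = s.allele_vector.tobytes().decode()
            fh.write(f"{s.column}\t{s.major_allele}\t{s.minor_allele}\t"
                     f"{s.minor_count}\t{alle}\n")


def write_sites_vcf(table: SiteTable, path, contig: str = "mito") -> None:
    """Minimal VCF body (CHROM POS REF ALT) for the biallelic sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={table.alignment_length}>\n")
        fh.write("#CHROM\tPOS\tREF\tALT\n")
        for s in table.sites:
            fh.write(f"{contig}\t{s.column + 1}\t{s.major_allele}\t{s.minor_allele}\n")
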