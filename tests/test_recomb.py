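import itertools

import numpy as np
import pytest

from mitorec.alignment import Alignment, extract_biallelic_sites
from mitorec.recomb import (MonomorphicPairError, four_gamete_matrix,
                            four_gamete_scan, haplotype_blocks,
                            ld_distance_mantel, ld_statistics,
                            mantel_ld_distance, max_chi2_test, phi_test,
                            violating_pair_percentage)
from mitorec.simulate import SimulationParams, simulate_haplotypes
from tests.conftest import mutate_positions, random_sequence


def _aln_from_columns(columns):
    """Build an alignment whose j-th column is the j-th string."""
    n = len(columns[0])
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return Alignment.from_sequences([f"s{i}" for i in range(n)], seqs)


class TestFourGameteScan:
    def test_all_four_gametes_detected(self):
        aln = _aln_from_columns(["AAGG", "CTCT"])
        table = extract_biallelic_sites(aln)
        pairs, n_viol, n_pairs = four_gamete_scan(table)
        assert n_pairs == 1
        assert n_viol == 1
        assert pairs[0].four_gametes

    def test_nested_sites_pass(self):
        # haplotypes {AC, AT, GT}: three gametes only
        aln = _aln_from_columns(["AAG", "CTT"])
        table = extract_biallelic_sites(aln)
        _, n_viol, n_pairs = four_gamete_scan(table)
        assert (n_viol, n_pairs) == (0, 1)

    def test_rho_zero_simulation_clean(self):
        for seed in range(5):
            aln = simulate_haplotypes(
                SimulationParams(8, 8000, 0.003, 0.0, seed=300 + seed))
            _, n_viol, _ = four_gamete_scan(extract_biallelic_sites(aln))
            assert n_viol == 0

    def test_invariant_to_sample_order_and_allele_labels(self):
        aln = simulate_haplotypes(SimulationParams(8, 5000, 0.004, 2e-3, seed=1))
        table = extract_biallelic_sites(aln)
        _, n_viol, n_pairs = four_gamete_scan(table)
        perm = np.random.default_rng(0).permutation(aln.n_samples)
        shuffled = Alignment([aln.sample_ids[i] for i in perm], aln.matrix[perm],
                             circular=aln.circular)
        _, n_viol2, n_pairs2 = four_gamete_scan(extract_biallelic_sites(shuffled))
        assert (n_viol, n_pairs) == (n_viol2, n_pairs2)
        # relabel alleles: complement every base
        comp = str.maketrans("ACGT", "TGCA")
        relabeled = Alignment.from_sequences(
            list(aln.sample_ids), [s.translate(comp) for s in aln.sequences()])
        _, n_viol3, n_pairs3 = four_gamete_scan(extract_biallelic_sites(relabeled))
        assert (n_viol, n_pairs) == (n_viol3, n_pairs3)

    def test_percentage_reporting(self):
        assert violating_pair_percentage(17095, 303810) == 5.6
        assert violating_pair_percentage(0, 10) == 0.0
        with pytest.raises(ValueError):
            violating_pair_percentage(0, 0)


def _min_segmentation_oracle(viol, S):
    """DP oracle: minimal number of contiguous violation-free blocks."""
    compatible = [[True] * S for _ in range(S)]
    for i in range(S):
        for j in range(S):
            compatible[i][j] = not viol[i, j]
    ok = [[all(not viol[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1))
           for j in range(S)] for i in range(S)]
    INF = 10 ** 9
    best = [INF] * (S + 1)
    best[0] = 0
    for j in range(1, S + 1):
        for i in range(j):
            if ok[i][j - 1]:
                best[j] = min(best[j], best[i] + 1)
    return best[S]


class TestHaplotypeBlocks:
    def test_no_violations_single_block(self):
        aln = simulate_haplotypes(SimulationParams(6, 5000, 0.003, 0.0, seed=5))
        table = extract_biallelic_sites(aln)
        blocks = haplotype_blocks(table)
        assert len(blocks) == 1
        assert blocks[0].n_sites == len(table)

    def test_single_violation_two_blocks(self):
        aln = _aln_from_columns(["AAGG", "CTCT"])
        table = extract_biallelic_sites(aln)
        blocks = haplotype_blocks(table)
        assert len(blocks) == 2

    def test_blocks_tile_sites(self):
        aln = simulate_haplotypes(SimulationParams(10, 8000, 0.003, 3e-3, seed=6))
        table = extract_biallelic_sites(aln)
        blocks = haplotype_blocks(table)
        covered = sorted(i for b in blocks for i in b.site_indices)
        assert covered == list(range(len(table)))

    def test_mosaic_splice_boundary_and_count(self):
        # 8 samples; left 15 sites partition {0..3}|{4..7}, right 15 sites
        # partition {0,1,4,5}|{2,3,6,7}: every cross pair shows 4 gametes
        left = "AAAAGGGG"
        right = "CCTTCCTT"
        cols = [left] * 15 + [right] * 15
        aln = _aln_from_columns(cols)
        table = extract_biallelic_sites(aln)
        assert len(table) == 30
        blocks = haplotype_blocks(table)
        viol = four_gamete_matrix(table)
        assert len(blocks) == _min_segmentation_oracle(viol, 30)
        boundary = blocks[0].site_indices[-1]
        assert abs(boundary - 14) <= 1

    def test_circular_merge(self):
        # violation only between middle sites: first/last blocks merge around
        # the origin on circular data
        left = "AAAAGGGG"
        right = "CCTTCCTT"
        cols = [left] * 3 + [right] * 3
        aln = _aln_from_columns(cols)
        lin = extract_biallelic_sites(aln)
        assert len(haplotype_blocks(lin)) == 2
        circ = extract_biallelic_sites(aln)
        circ.circular = True
        blocks = haplotype_blocks(circ)
        assert len(blocks) == 2  # merging would join violating sites; stays 2
        # now make ends compatible with each other but not with the middle
        cols2 = [left] * 2 + [right] * 2 + [left] * 2
        aln2 = _aln_from_columns(cols2)
        t2 = extract_biallelic_sites(aln2)
        t2.circular = True
        blocks2 = haplotype_blocks(t2)
        assert len(blocks2) == 2
        assert any(b.wraps for b in blocks2)


class TestLdStatistics:
    def test_complete_ld(self):
        aln = _aln_from_columns(["AAGG", "CCTT"])
        table = extract_biallelic_sites(aln)
        p = ld_statistics(0, 1, table)
        assert p.r2 == pytest.approx(1.0)
        assert p.D_prime == pytest.approx(1.0)

    def test_independence(self):
        aln = _aln_from_columns(["AAGG", "CTCT"])
        table = extract_biallelic_sites(aln)
        p = ld_statistics(0, 1, table)
        assert p.D == pytest.approx(0.0)
        assert p.r2 == pytest.approx(0.0)

    def test_hand_enumerated_counts(self):
        # AB=4, Ab=1, aB=1, ab=4
        col1 = "A" * 5 + "G" * 5
        col2 = "C" * 4 + "T" + "C" + "T" * 4
        aln = _aln_from_columns([col1, col2])
        p = ld_statistics(0, 1, extract_biallelic_sites(aln))
        assert p.D == pytest.approx(0.15)
        assert p.D_prime == pytest.approx(0.6)
        assert p.r2 == pytest.approx(0.36)

    def test_monomorphic_pair_signaled(self):
        # both sites are biallelic overall, but restricting to the samples
        # non-missing at both leaves the second site monomorphic
        aln = _aln_from_columns(["--AG", "TCCC"])
        table = extract_biallelic_sites(aln)
        assert len(table) == 2
        with pytest.raises(MonomorphicPairError):
            ld_statistics(0, 1, table)

    def test_exhaustive_small_count_tables(self):
        # oracle: direct arithmetic from the 2x2 table definition for every
        # table with cell counts <= 3 and both loci polymorphic
        checked = 0
        for nAB, nAb, naB, nab in itertools.product(range(4), repeat=4):
            n = nAB + nAb + naB + nab
            if n == 0:
                continue
            pA = (nAB + nAb) / n
            pB = (nAB + naB) / n
            if pA in (0, 1) or pB in (0, 1):
                continue
            col1 = "A" * (nAB + nAb) + "G" * (naB + nab)
            col2 = "C" * nAB + "T" * nAb + "C" * naB + "T" * nab
            table = extract_biallelic_sites(_aln_from_columns([col1, col2]))
            p = ld_statistics(0, 1, table)
            pAB = nAB / n
            D = pAB - pA * pB
            if D > 0:
                dmax = min(pA * (1 - pB), (1 - pA) * pB)
            else:
                dmax = min(pA * pB, (1 - pA) * (1 - pB))
            dprime = abs(D) / dmax if dmax > 0 else 0.0
            r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
            # allele labeling inside the site table may flip D's sign but
            # never |D|, D' or r2
            assert abs(p.D) == pytest.approx(abs(D), abs=1e-12)
            assert p.D_prime == pytest.approx(dprime, abs=1e-12)
            assert p.r2 == pytest.approx(r2, abs=1e-12)
            assert p.four_gametes == (min(nAB, nAb, naB, nab) > 0)
            checked += 1
        assert checked > 80


class TestMantel:
    def test_constant_ld_no_signal(self):
        # perfect LD everywhere: correlation 0, p >= 0.5
        cols = ["AAGG"] * 6
        aln = _aln_from_columns(cols)
        table = extract_biallelic_sites(aln)
        res = mantel_ld_distance(table, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value >= 0.5

    def test_chunking_and_untestable(self):
        aln = simulate_haplotypes(SimulationParams(8, 9000, 0.002, 0, seed=9))
        results = ld_distance_mantel(aln, chunk_size=3000, n_perm=49, seed=2)
        assert len(results) == 3
        invariant = Alignment.from_sequences(["a", "b", "c"], ["ACGT" * 750] * 3)
        res2 = ld_distance_mantel(invariant, chunk_size=1000, n_perm=49, seed=3)
        assert all(r.untestable for r in res2)

    def test_high_rho_power(self):
        sig = 0
        for seed in range(10):
            aln = simulate_haplotypes(
                SimulationParams(20, 10000, 0.003, 5e-3, seed=700 + seed))
            table = extract_biallelic_sites(aln)
            res = mantel_ld_distance(table, stat="r2", n_perm=99, seed=seed)
            sig += (not res.untestable) and res.p_value < 0.05
        assert sig >= 7

    def test_offset_shifts_chunks(self):
        aln = simulate_haplotypes(SimulationParams(8, 6000, 0.003, 0, seed=10))
        r0 = ld_distance_mantel(aln, chunk_size=3000, n_perm=9, seed=1, offset=0)
        r1 = ld_distance_mantel(aln, chunk_size=3000, n_perm=9, seed=1, offset=500)
        assert r0[0].window_params["start"] == 0
        assert r1[0].window_params["start"] == 500


def _planted_recombinant(seed=1, L=2000, per_half=10):
    rng = np.random.default_rng(seed)
    base = random_sequence(L, seed)
    pos_left = list(range(50, L // 2 - 50, (L // 2 - 100) // per_half))[:per_half]
    pos_right = list(range(L // 2 + 50, L - 50, (L // 2 - 100) // per_half))[:per_half]
    p1 = base
    p2 = mutate_positions(base, pos_left + pos_right)
    child = p1[:L // 2] + p2[L // 2:]
    return Alignment.from_sequences(["p1", "p2", "child"], [p1, p2, child]), L // 2


class TestMaxChi2:
    def test_planted_breakpoint(self):
        aln, splice = _planted_recombinant(seed=3)
        res = max_chi2_test(aln, n_perm=999, seed=5)
        assert res.p_value <= 0.01
        # located breakpoint within 2 sites of the splice
        bp_col = res.window_params["breakpoint_column"]
        table = extract_biallelic_sites(aln)
        pos = table.positions()
        splice_idx = int(np.searchsorted(pos, splice))
        bp_idx = res.window_params["breakpoint_site_index"]
        assert abs(bp_idx - splice_idx) <= 2

    def test_window_arithmetic(self):
        cols = ["AAGG", "AGAG"] * 15  # 30 sites
        aln = _aln_from_columns(cols)
        res = max_chi2_test(aln, window_fraction=2 / 3, n_perm=19, seed=1)
        assert res.window_params["window_sites"] == 20
        assert res.window_params["n_splits_per_pair"] == 30 - 20 + 1

    def test_null_calibration(self):
        high_p = 0
        n = 30
        for seed in range(n):
            aln = simulate_haplotypes(
                SimulationParams(8, 3000, 0.006, 0, seed=520 + seed))
            if len(extract_biallelic_sites(aln)) < 8:
                high_p += 1
                continue
            res = max_chi2_test(aln, n_perm=99, seed=seed)
            if res.untestable:
                high_p += 1
            else:
                high_p += res.p_value > 0.05
        assert high_p >= int(0.9 * n)

    def test_too_few_sites_untestable(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT" * 10] * 2)
        res = max_chi2_test(aln, n_perm=9, seed=1)
        assert res.untestable


class TestPhi:
    def test_tree_compatible_phi_zero_p_one(self):
        aln = simulate_haplotypes(SimulationParams(10, 5000, 0.003, 0, seed=30))
        res = phi_test(aln, window=1000, n_perm=99, seed=1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_toy_matches_bruteforce_oracle(self):
        cols = ["AAGG", "CTCT", "AAGG", "CCTT", "ACTG", "AATT"]
        # informative biallelic columns only; compute Phi_w by exhaustive
        # enumeration of qualifying pairs
        aln = _aln_from_columns(cols)
        res = phi_test(aln, window=100, n_perm=9, seed=1)
        table = extract_biallelic_sites(aln, min_minor_count=2)
        pos = [s.column for s in table.sites]
        scores = []
        for i, j in itertools.combinations(range(len(table)), 2):
            if abs(pos[j] - pos[i]) <= 100:
                gi = table.sites[i].binary()
                gj = table.sites[j].binary()
                gametes = {(a, b) for a, b in zip(gi, gj) if a >= 0 and b >= 0}
                scores.append(1.0 if len(gametes) == 4 else 0.0)
        assert res.statistic == pytest.approx(np.mean(scores))

    def test_power_and_null(self):
        sig = 0
        for seed in range(10):
            aln = simulate_haplotypes(SimulationParams(
                20, 5000, 0.01, 5e-3, seed=900 + seed, finite_sites=True))
            res = phi_test(aln, window=500, n_perm=99, seed=seed)
            sig += (not res.untestable) and res.p_value < 0.05
        assert sig >= 7
        rej = 0
        for seed in range(10):
            aln = simulate_haplotypes(SimulationParams(
                20, 5000, 0.003, 0, seed=940 + seed))
            res = phi_test(aln, window=500, n_perm=99, seed=seed)
            rej += (not res.untestable) and res.p_value <= 0.05
        assert rej <= 1

    def test_no_pairs_within_window_untestable(self):
        cols = ["AAGG", "CCTT"]
        aln = _aln_from_columns([cols[0]] + ["A" * 4] * 500 + [cols[1]])
        res = phi_test(aln, window=100, n_perm=9, seed=1)
        assert res.untestable
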