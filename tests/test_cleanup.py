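import numpy as np
import pytest

from estkit.cleanup import (
    TrimParams, TrimResult, classify_insertless, dedup_resequenced,
    detect_polya, low_complexity_fraction, mask_vector,
    propagate_sister_status, quality_trim, run_cleanup, screen_contaminants,
)
from estkit.annotate import StrongMatchConfig
from estkit.seqio import CloneRecord, Direction, ESTRecord, HitRow, Status
from estkit.simdata import (
    DEFAULT_VECTOR, SimConfig, make_contaminant_hits, simulate_library,
    simulate_transcriptome,
)

from conftest import random_dna

P = TrimParams()


# ---------------------------------------------------------------- oracles

def brute_force_quality_trim(quals, p):
    """Enumerate every interval; valid if all full windows inside it pass,
    or (for intervals shorter than the window) its own mean passes.
    Longest wins, ties to the 5'-most."""
    n = len(quals)
    best = None
    for s in range(n):
        for e in range(s + 1, n + 1):
            length = e - s
            if length >= p.window:
                valid = all(
                    sum(quals[i:i + p.window]) / p.window >= p.qual_threshold
                    for i in range(s, e - p.window + 1)
                )
            else:
                valid = sum(quals[s:e]) / length >= p.qual_threshold
            if valid and (best is None or length > best[1] - best[0]):
                best = (s, e)
    return best


def two_clause_insertless(vec5, gap, p):
    return vec5 >= p.insertless_vector_5p or (
        vec5 < p.insertless_vector_5p and gap < p.insertless_insert_max
    )


# ---------------------------------------------------------------- vector mask

class TestMaskVector:
    def test_exact_prefix(self):
        rng = np.random.default_rng(0)
        read = DEFAULT_VECTOR[-40:] + random_dna(rng, 400)
        assert mask_vector(read, [DEFAULT_VECTOR]) == [(0, 40)]

    def test_no_match(self):
        rng = np.random.default_rng(1)
        read = random_dna(rng, 300)
        # a random read is vanishingly unlikely to carry a 20 bp vector hit
        assert mask_vector(read, [DEFAULT_VECTOR]) == []

    def test_prefix_with_one_mismatch(self):
        rng = np.random.default_rng(2)
        prefix = list(DEFAULT_VECTOR[-40:])
        prefix[25] = "A" if prefix[25] != "A" else "C"
        read = "".join(prefix) + random_dna(rng, 400)
        iv = mask_vector(read, [DEFAULT_VECTOR], max_mismatch_rate=0.05)
        assert iv and iv[0][0] == 0 and iv[0][1] == 40

    def test_three_prime_anchor(self):
        rng = np.random.default_rng(3)
        read = random_dna(rng, 400) + DEFAULT_VECTOR[:35]
        assert (400, 435) in mask_vector(read, [DEFAULT_VECTOR])

    def test_empty_vector_list_rejected(self):
        with pytest.raises(ValueError):
            mask_vector("ACGT" * 50, [])


# ------------------------------------------------------------ insertless

class TestClassifyInsertless:
    def test_long_5p_vector_run(self):
        assert classify_insertless([(0, 250)], 700, P) is True

    def test_short_vector_then_short_insert(self):
        assert classify_insertless([(0, 150), (230, 700)], 700, P) is True

    def test_short_vector_then_long_insert(self):
        assert classify_insertless([(0, 150)], 700, P) is False

    def test_exhaustive_two_clause_equivalence(self):
        """Pure function of (5' masked run, following unmasked run) over the
        full {0..400}^2 grid."""
        for vec5 in range(0, 401, 1):
            for gap in range(0, 401, 7):  # stride keeps this subsecond
                read_len = vec5 + gap + 50
                mask = [(0, vec5)] if vec5 else []
                if gap + 50 > 0:
                    mask = mask + [(vec5 + gap, read_len)]
                got = classify_insertless(mask, read_len, P)
                assert got == two_clause_insertless(vec5, gap, P), (vec5, gap)

    def test_exhaustive_full_grid_coarse_readlen(self):
        # full cartesian grid with open 3' end (no trailing mask)
        for vec5 in range(0, 401, 3):
            for gap in range(0, 401, 3):
                mask = [(0, vec5)] if vec5 else []
                got = classify_insertless(mask, vec5 + gap, P)
                assert got == two_clause_insertless(vec5, gap, P), (vec5, gap)


# ------------------------------------------------------------ quality trim

class TestQualityTrim:
    def test_all_high_quality(self):
        assert quality_trim([40] * 200, P) == (0, 200)

    def test_clean_prefix_then_junk(self):
        got = quality_trim([30] * 150 + [2] * 60, P)
        assert got == brute_force_quality_trim([30] * 150 + [2] * 60, P)

    def test_short_high_quality_returned_not_filtered_here(self):
        got = quality_trim([40] * 90, P)
        assert got == (0, 90)  # length rule is the caller's job

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_reads(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(5, 120))
            # mixture profile: stretches of good and bad quality
            quals = []
            while len(quals) < n:
                level = int(rng.choice([2, 10, 16, 30, 45]))
                quals.extend([level + int(rng.integers(-2, 3))] * int(rng.integers(3, 25)))
            quals = [max(0, q) for q in quals[:n]]
            assert quality_trim(quals, P) == brute_force_quality_trim(quals, P), quals


# ------------------------------------------------------------ polyA

class TestDetectPolya:
    def test_canonical_3p_tail(self):
        rng = np.random.default_rng(4)
        bases = random_dna(rng, 400).rstrip("A") + "A" * 25
        flag, iv = detect_polya(bases, P)
        assert flag and iv == (len(bases) - 25, len(bases))

    def test_5p_T_tail(self):
        rng = np.random.default_rng(5)
        # guard flank without T so the tolerant run cannot stretch past 25
        bases = "T" * 25 + "GC" * 10 + random_dna(rng, 380)
        flag, iv = detect_polya(bases, P)
        assert flag and iv == (0, 25)

    def test_interior_run_outside_end_window_not_flagged(self):
        rng = np.random.default_rng(6)
        left, right = random_dna(rng, 200), random_dna(rng, 285)
        bases = left.rstrip("A") + "A" * 15 + right.lstrip("A")
        # guard: flanks must not themselves contain a qualifying tail
        flag, _ = detect_polya(bases, P)
        assert flag is False

    def test_tolerates_one_interruption_per_12(self):
        rng = np.random.default_rng(7)
        prefix = random_dna(rng, 300).rstrip("A")
        tail = "A" * 11 + "G" + "A" * 12  # 24-base run, 1 non-A <= 24//12
        bases = prefix + tail
        flag, iv = detect_polya(bases, P)
        assert flag and iv == (len(prefix), len(bases))


# ------------------------------------------------------------ low complexity

def brute_force_low_complexity(bases):
    n = len(bases)
    covered = set()
    for s in range(n):
        for e in range(s + 5, n + 1):  # homopolymers >= 5
            if len(set(bases[s:e])) == 1:
                covered.update(range(s, e))
    for period in (2, 3):
        for s in range(n):
            e = s + period
            while e < n and bases[e] == bases[e - period]:
                e += 1
            if (e - s) // period >= 4:
                covered.update(range(s, e))
    return len(covered) / n


class TestLowComplexity:
    def test_pure_homopolymer(self):
        assert low_complexity_fraction("A" * 100) == 1.0

    def test_random_sequence_below_threshold(self):
        rng = np.random.default_rng(8)
        below = sum(
            low_complexity_fraction(random_dna(rng, 400)) < 0.5 for _ in range(1000)
        )
        assert below == 1000

    def test_dinucleotide_run_coverage(self):
        rng = np.random.default_rng(9)
        bases = "AC" * 30 + random_dna(rng, 40)
        frac = low_complexity_fraction(bases)
        assert frac >= 0.6
        assert frac == pytest.approx(brute_force_low_complexity(bases))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        parts = []
        for _ in range(4):
            kind = rng.integers(0, 3)
            if kind == 0:
                parts.append(random_dna(rng, int(rng.integers(5, 40))))
            elif kind == 1:
                parts.append("ACGT"[int(rng.integers(0, 4))] * int(rng.integers(3, 12)))
            else:
                unit = random_dna(rng, int(rng.integers(2, 4)))
                parts.append(unit * int(rng.integers(2, 8)))
        bases = "".join(parts)
        assert low_complexity_fraction(bases) == pytest.approx(
            brute_force_low_complexity(bases)
        )


# ------------------------------------------------------------ clone logic

def _result(est_id, status=Status.PASS, kept=(0, 400)):
    return TrimResult(est_id, kept=kept if status is Status.PASS else None, status=status)


class TestScreenContaminants:
    def _records(self):
        return [ESTRecord("c1.b", "c1", Direction.FWD_5P, "ACGT" * 100, [40] * 400)]

    def _hit(self, evalue, subject="phage1"):
        return HitRow("c1.b", subject, 99.0, 400, 0, 0, 1, 400, 1, 400, evalue, 700.0)

    def test_strong_hit_to_listed_subject(self):
        recs = screen_contaminants(self._records(), [self._hit(1e-30)], {"phage1"})
        assert recs[0].status is Status.CONTAMINANT

    def test_strong_hit_to_unlisted_subject(self):
        recs = screen_contaminants(self._records(), [self._hit(1e-30, "rRNA_x")], {"phage1"})
        assert recs[0].status is Status.PASS

    def test_weak_hit_to_listed_subject(self):
        recs = screen_contaminants(self._records(), [self._hit(1e-3)], {"phage1"})
        assert recs[0].status is Status.PASS


class TestDedupResequenced:
    def test_longest_kept_wins(self):
        clone = CloneRecord("c1", fwd_est_ids=["c1.b", "c1.b2"])
        results = {"c1.b": _result("c1.b", kept=(0, 400)), "c1.b2": _result("c1.b2", kept=(0, 500))}
        retained = dedup_resequenced(clone, results)
        assert retained[Direction.FWD_5P] == "c1.b2"
        assert results["c1.b"].status is Status.DUPLICATE

    def test_single_read_unchanged(self):
        clone = CloneRecord("c1", fwd_est_ids=["c1.b"])
        results = {"c1.b": _result("c1.b")}
        dedup_resequenced(clone, results)
        assert results["c1.b"].status is Status.PASS

    def test_tie_broken_lexicographically(self):
        clone = CloneRecord("c1", fwd_est_ids=["c1.b", "c1.b2"])
        results = {"c1.b": _result("c1.b"), "c1.b2": _result("c1.b2")}
        retained = dedup_resequenced(clone, results)
        assert retained[Direction.FWD_5P] == "c1.b"
        assert results["c1.b2"].status is Status.DUPLICATE


class TestPropagateSisterStatus:
    def _clone(self):
        return CloneRecord("c1", fwd_est_ids=["c1.b"], rev_est_ids=["c1.g"])

    def test_insertless_propagates(self):
        results = {"c1.b": _result("c1.b", Status.INSERTLESS), "c1.g": _result("c1.g")}
        propagate_sister_status(self._clone(), results)
        assert results["c1.g"].status is Status.INSERTLESS
        assert results["c1.g"].kept is None

    def test_low_quality_does_not_propagate(self):
        results = {"c1.b": _result("c1.b", Status.LOW_QUALITY), "c1.g": _result("c1.g")}
        propagate_sister_status(self._clone(), results)
        assert results["c1.g"].status is Status.PASS

    def test_both_pass_unchanged(self):
        results = {"c1.b": _result("c1.b"), "c1.g": _result("c1.g")}
        propagate_sister_status(self._clone(), results)
        assert all(r.status is Status.PASS for r in results.values())

    def test_conflicting_propagating_statuses_kept(self, caplog):
        results = {
            "c1.b": _result("c1.b", Status.INSERTLESS),
            "c1.g": _result("c1.g", Status.CONTAMINANT),
        }
        with caplog.at_level("WARNING"):
            propagate_sister_status(self._clone(), results)
        assert results["c1.b"].status is Status.INSERTLESS
        assert results["c1.g"].status is Status.CONTAMINANT
        assert "conflicting" in caplog.text


# ------------------------------------------------------------ full cascade

class TestRunCleanup:
    def test_clean_library_passes_everything(self, small_library):
        cfg, _, records, _, _ = small_library
        import copy

        results, stats = run_cleanup(copy.deepcopy(records), [cfg.vector_seq])
        assert all(r.status is Status.PASS for r in results.values())
        row = stats.iloc[0]
        assert row["pct_ests_passing"] == 100.0

    def test_idempotent_on_trimmed_output(self, small_library):
        cfg, _, records, _, _ = small_library
        import copy

        records = copy.deepcopy(records)
        results, _ = run_cleanup(records, [cfg.vector_seq])
        trimmed = [
            ESTRecord(r.est_id, r.clone_id, r.direction,
                      r.bases[results[r.est_id].kept[0]:results[r.est_id].kept[1]],
                      r.quals[results[r.est_id].kept[0]:results[r.est_id].kept[1]],
                      library=r.library)
            for r in records
        ]
        results2, _ = run_cleanup(trimmed, [cfg.vector_seq])
        for r in trimmed:
            res = results2[r.est_id]
            assert res.status is Status.PASS
            assert res.kept == (0, len(r.bases))

    def test_status_monotonicity_no_return_to_pass(self):
        # a read that fails quality can at most change to a propagating status
        rng = np.random.default_rng(10)
        bad = ESTRecord("c1.b", "c1", Direction.FWD_5P, random_dna(rng, 200), [2] * 200)
        good_bases = DEFAULT_VECTOR[-40:] * 10  # fully vector: insertless
        sister = ESTRecord("c1.g", "c1", Direction.REV_3P, good_bases[:300], [40] * 300)
        results, _ = run_cleanup([bad, sister], [DEFAULT_VECTOR])
        assert results["c1.b"].status in (Status.LOW_QUALITY, Status.INSERTLESS)
        assert results["c1.g"].status is Status.INSERTLESS
        assert results["c1.b"].status is not Status.PASS

    def test_planted_artifact_sensitivity(self):
        """Injected vector-only clones, polyA tails and low-complexity reads
        are flagged at high sensitivity at default parameters."""
        cfg = SimConfig(
            seed=77, n_transcripts=10, n_clones=200,
            frac_insertless=0.05, frac_contaminant=0.0, frac_low_complexity=0.05,
        )
        records, clones, truth = simulate_library(simulate_transcriptome(cfg), cfg)
        results, _ = run_cleanup(records, [cfg.vector_seq])
        ins_found = sum(
            any(results[i].status is Status.INSERTLESS for i in (f"{c}.b", f"{c}.g"))
            for c in truth.clones_with("insertless")
        )
        low_found = sum(
            any(results[i].status is Status.LOW_COMPLEXITY for i in (f"{c}.b", f"{c}.g"))
            for c in truth.clones_with("low_complexity")
        )
        polya = sum(
            results[f"{c}.b"].polyA_flag or results[f"{c}.g"].polyA_flag
            for c, t in truth.clones.items() if t.artifact is None
        )
        n_clean = sum(t.artifact is None for t in truth.clones.values())
        assert ins_found == len(truth.clones_with("insertless"))
        assert low_found == len(truth.clones_with("low_complexity"))
        assert polya >= 0.99 * n_clean

    def test_stats_totals_are_column_sums(self):
        cfg1 = SimConfig(seed=1, n_transcripts=5, n_clones=30, library="LIB1")
        cfg2 = SimConfig(seed=2, n_transcripts=5, n_clones=20, library="LIB2")
        recs1, _, _ = simulate_library(simulate_transcriptome(cfg1), cfg1)
        recs2, _, _ = simulate_library(simulate_transcriptome(cfg2), cfg2)
        _, stats = run_cleanup(recs1 + recs2, [cfg1.vector_seq])
        assert len(stats) == 3
        total = stats.iloc[-1]
        for col in ("attempted_ests", "attempted_clones", "insertless_clones",
                    "contaminated_clones", "clones_passing", "ests_passing"):
            assert total[col] == stats.iloc[:-1][col].sum()

    def test_contaminant_screen_and_propagation(self):
        cfg = SimConfig(seed=21, n_transcripts=5, n_clones=100,
                        frac_insertless=0.0, frac_contaminant=0.05,
                        frac_low_complexity=0.0)
        records, clones, truth = simulate_library(simulate_transcriptome(cfg), cfg)
        hits, subjects = make_contaminant_hits(truth)
        # hand the screen only the 5' read hits: propagation must catch sisters
        fwd_hits = [h for h in hits if h.query_id.endswith(".b")]
        results, stats = run_cleanup(
            records, [cfg.vector_seq],
            contaminant_hits=fwd_hits, contaminant_subjects=subjects,
        )
        for c in truth.clones_with("contaminant"):
            assert results[f"{c}.b"].status is Status.CONTAMINANT
            assert results[f"{c}.g"].status is Status.CONTAMINANT
        assert stats.iloc[0]["contaminated_clones"] == len(truth.clones_with("contaminant"))
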