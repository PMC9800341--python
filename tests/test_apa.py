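"""APA quantification: assignment, ratios, classification, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polwave.apa as apa
import polwave.io as pio
from conftest import brute_force_assign


def _pas(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "rank", "is_distal", "strand"])


def _ends(rows):
    return pd.DataFrame(rows, columns=pio.BED6_COLUMNS)


# --------------------------------------------------------------- trimming


def test_trim_keeps_last_window_and_short_reads_unchanged(tmp_path):
    fq = tmp_path / "in.fastq"
    long_seq = "A" * 150 + "C" * 200
    fq.write_text(
        f"@r1\n{long_seq}\n+\n{'I' * 350}\n@r2\n{'G' * 150}\n+\n{'B' * 150}\n"
    )
    out = list(apa.trim_to_3prime(pio.read_fastq(fq), keep_last=200))
    assert str(out[0].seq) == "C" * 200 and out[0].id == "r1"
    assert out[0].letter_annotations["phred_quality"] == [40] * 200
    assert str(out[1].seq) == "G" * 150  # shorter than window: untouched


def test_trim_empty_file_round_trip(tmp_path):
    src = tmp_path / "e.fastq"
    src.write_text("")
    dst = tmp_path / "o.fastq"
    n = pio.write_fastq(apa.trim_to_3prime(pio.read_fastq(src)), dst)
    assert n == 0 and dst.read_text() == ""


# ---------------------------------------------------------- end extraction


def test_three_prime_ends_from_sam_alignments(tmp_path):
    """BAM/SAM route: forward reads end at reference_end-1, reverse reads at
    reference_start; secondary alignments are dropped."""
    sam = tmp_path / "a.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:chr1\tLN:10000\n"
        "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*\n"     # fwd [100,150)
        "r2\t16\tchr1\t201\t60\t50M\t*\t0\t0\t*\t*\n"    # rev [200,250)
        "r3\t256\tchr1\t301\t60\t50M\t*\t0\t0\t*\t*\n"   # secondary
    )
    ends, n_skipped = apa.extract_three_prime_ends_bam(sam)
    assert n_skipped == 1
    assert list(ends["start"]) == [149, 200]
    assert list(ends["strand"]) == ["+", "-"]


def test_three_prime_end_conventions():
    spans = _ends(
        [
            ("chr1", 100, 250, "a", "0", "+"),
            ("chr1", 100, 250, "b", "0", "-"),
            ("chr1", 10, 20, "c", "0", "."),
        ]
    )
    ends, n_skipped = apa.extract_three_prime_ends(spans)
    assert n_skipped == 1
    assert list(ends["start"]) == [249, 100]
    assert (ends["end"] - ends["start"] == 1).all()


# ----------------------------------------------------------- assignment


class TestAssign:
    PAS = _pas(
        [
            ("chr1", 1000, "g1", 1, False, "+"),
            ("chr1", 1050, "g1", 2, True, "+"),
            ("chr1", 5000, "g2", 1, False, "-"),
        ]
    )

    def test_exact_hit_boundary_and_tie(self):
        ends = _ends(
            [
                ("chr1", 1000, 1001, "exact", "0", "+"),
                ("chr1", 949, 950, "at_51", "0", "+"),  # 51 bp from rank 1
                ("chr1", 1025, 1026, "tie", "0", "+"),  # 25 bp from both
                ("chr1", 950, 951, "at_50", "0", "+"),
            ]
        )
        got = apa.assign_to_pas(ends, self.PAS, window=50)
        assert got[0] == 0  # exact position
        assert got[1] == -1  # beyond the window
        assert got[2] == 1  # equidistant: distal-ward wins
        assert got[3] == 0  # exactly at the window edge: assigned

    def test_minus_strand_tie_prefers_smaller_coordinate(self):
        pas = _pas(
            [
                ("chr1", 2000, "g", 1, False, "-"),
                ("chr1", 1950, "g", 2, True, "-"),
            ]
        )
        ends = _ends([("chr1", 1975, 1976, "t", "0", "-")])
        assert apa.assign_to_pas(ends, pas, window=50)[0] == 1

    def test_strand_must_match(self):
        ends = _ends([("chr1", 1000, 1001, "wrong", "0", "-")])
        assert apa.assign_to_pas(ends, self.PAS, window=50)[0] == -1

    def test_conservation_assigned_plus_unassigned(self, small_genome, small_config):
        import polwave.simulate as sim

        genes, pas, sizes = small_genome
        ends, _, _ = sim.simulate_reads(genes, pas, small_config, "control", 1, sizes)
        counts, n_un = apa.pas_usage_table(ends, pas, "s")
        assert counts["count"].sum() + n_un == len(ends)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_pas = data.draw(st.integers(2, 6))
        positions = sorted(
            data.draw(
                st.lists(st.integers(0, 3000), min_size=n_pas, max_size=n_pas, unique=True)
            )
        )
        strand = data.draw(st.sampled_from("+-"))
        ranks = range(1, n_pas + 1) if strand == "+" else range(n_pas, 0, -1)
        pas = _pas(
            [
                ("chr1", p, "g", r, r == n_pas, strand)
                for p, r in zip(positions, ranks)
            ]
        )
        epos = data.draw(st.lists(st.integers(0, 3000), min_size=1, max_size=40))
        ends = _ends([("chr1", p, p + 1, f"e{i}", "0", strand) for i, p in enumerate(epos)])
        window = data.draw(st.integers(0, 200))
        np.testing.assert_array_equal(
            apa.assign_to_pas(ends, pas, window), brute_force_assign(ends, pas, window)
        )

    def test_strand_mirror_symmetry(self, small_genome, small_config):
        """Mirroring all coordinates and strands leaves the counts unchanged."""
        import polwave.simulate as sim

        genes, pas, sizes = small_genome
        ends, _, _ = sim.simulate_reads(genes, pas, small_config, "case", 1, sizes)
        ends = ends.iloc[:400]
        L = sizes[small_config.chrom_name]
        flip = {"+": "-", "-": "+"}
        m_ends = ends.assign(
            start=L - 1 - ends["start"], end=L - ends["start"],
            strand=ends["strand"].map(flip),
        )
        m_pas = pas.assign(pos=L - 1 - pas["pos"], strand=pas["strand"].map(flip))
        c1, u1 = apa.pas_usage_table(ends, pas, "s")
        c2, u2 = apa.pas_usage_table(m_ends, m_pas, "s")
        assert u1 == u2
        merged = c1.merge(c2, on=["gene_id", "rank"])
        assert (merged["count_x"] == merged["count_y"]).all()


# -------------------------------------------------- toy table, hand-derived


def toy_counts(spec: dict[str, list[tuple[int, bool]]]) -> pd.DataFrame:
    rows = []
    for gid, pas_counts in spec.items():
        for rank, (count, is_distal) in enumerate(pas_counts, start=1):
            rows.append((gid, rank, is_distal, count, "s"))
    return pd.DataFrame(rows, columns=["gene_id", "rank", "is_distal", "count", "sample_id"])


CONTROL = toy_counts(
    {
        "gA": [(10, False), (10, True)],
        "gB": [(10, False), (10, True)],
        "gC": [(12, False), (10, True)],
        "gD": [(9, False), (12, True)],
        "gE": [(30, True)],
        "gF": [(15, False), (5, False), (20, True)],
    }
)
CASE = toy_counts(
    {
        "gA": [(30, False), (10, True)],
        "gB": [(10, False), (15, True)],
        "gC": [(14, False), (10, True)],
        "gD": [(9, False), (4, True)],
        "gE": [(30, True)],
        "gF": [(30, False), (10, False), (20, True)],
    }
)


class TestToyTable:
    def test_testability_rules(self):
        s = apa.select_testable(apa.usage_summary(CASE)).set_index("gene_id")
        assert not s.at["gE", "testable"]  # single PAS
        assert not s.at["gD", "testable"]  # 4 distal reads < 5
        assert s.at["gA", "testable"] and s.at["gF", "testable"]
        ctrl = apa.select_testable(apa.usage_summary(CONTROL)).set_index("gene_id")
        assert ctrl.at["gD", "testable"]  # 12 distal reads: testable in control only

    def test_ratios_under_policies(self):
        s = apa.usage_summary(CONTROL).set_index("gene_id")
        assert s.at["gA", "ratio"] == 1.0
        assert s.at["gF", "ratio"] == (15 + 5) / 20  # sum_upstream
        most = apa.usage_summary(CONTROL, "most_proximal").set_index("gene_id")
        assert most.at["gF", "ratio"] == 15 / 20
        mx = apa.usage_summary(CASE, "max_upstream").set_index("gene_id")
        assert mx.at["gF", "ratio"] == 30 / 20

    def test_classification_matches_hand_computation(self):
        cls = apa.classify_genes(
            apa.usage_summary(CASE), apa.usage_summary(CONTROL)
        ).set_index("gene_id")
        assert cls.at["gA", "category"] == "proximal_dependent"  # fold 3.0
        assert cls.at["gA", "fold"] == pytest.approx(3.0)
        assert cls.at["gB", "category"] == "distal_dependent"  # fold 2/3
        assert cls.at["gC", "category"] == "independent"  # fold 1.4/1.2
        assert cls.at["gD", "category"] == "untestable"
        assert cls.at["gE", "category"] == "untestable"
        assert cls.at["gF", "category"] == "proximal_dependent"  # 2.0 vs 1.0
        assert cls.at["gF", "fold"] == pytest.approx(2.0)

    def test_zero_ratio_conventions(self):
        assert apa.classify_fold(0.0, 0.0) == (1.0, "independent")
        f, cat = apa.classify_fold(0.5, 0.0)
        assert np.isinf(f) and cat == "proximal_dependent"
        assert apa.classify_fold(0.0, 1.0)[1] == "distal_dependent"

    def test_boundary_folds(self):
        assert apa.classify_fold(1.6, 1.0)[1] == "proximal_dependent"
        assert apa.classify_fold(1.5, 1.0)[1] == "proximal_dependent"  # f >= tau
        assert apa.classify_fold(1.0, 1.0)[1] == "independent"
        assert apa.classify_fold(0.6, 1.0)[1] == "distal_dependent"


def test_threshold_monotonicity():
    """Raising tau can only shrink dependent sets; raising the distal-read
    floor can only shrink the testable set."""
    rng = np.random.default_rng(12)
    genes = {f"g{i}": [(int(rng.integers(0, 40)), False), (int(rng.integers(0, 40)), True)]
             for i in range(60)}
    case, ctrl = toy_counts(genes), toy_counts(
        {g: [(int(rng.integers(0, 40)), False), (int(rng.integers(0, 40)), True)]
         for g in genes}
    )
    prev_dep, prev_testable = None, None
    for tau in (1.2, 1.5, 2.0, 3.0):
        cls = apa.classify_genes(apa.usage_summary(case), apa.usage_summary(ctrl), tau=tau)
        dep = set(cls.loc[cls["category"].isin(["proximal_dependent", "distal_dependent"]), "gene_id"])
        if prev_dep is not None:
            assert dep <= prev_dep
        prev_dep = dep
    for floor in (0, 5, 10, 20):
        t = apa.select_testable(apa.usage_summary(case), min_distal_reads=floor)
        cur = set(t.loc[t["testable"], "gene_id"])
        if prev_testable is not None:
            assert cur <= prev_testable
        prev_testable = cur


# ----------------------------------------------------------- intersection


class TestIntersection:
    @staticmethod
    def _cls(dep, ind=()):
        rows = [(g, 2.0, 1.0, 2.0, "proximal_dependent") for g in dep]
        rows += [(g, 1.0, 1.0, 1.0, "independent") for g in ind]
        return pd.DataFrame(
            rows, columns=["gene_id", "ratio_case", "ratio_control", "fold", "category"]
        )

    def test_three_replicate_intersection(self):
        res = apa.intersect_replicates(
            [self._cls("ABC"), self._cls("BCD"), self._cls("BC")]
        )
        assert res["consensus_dependent"] == {"B", "C"}
        venn = res["venn_proximal_dependent"]
        assert venn["111"] == 2 and venn["100"] == 1 and venn["010"] == 1

    def test_single_replicate_is_identity(self):
        res = apa.intersect_replicates([self._cls("XY", ind="Z")])
        assert res["consensus_dependent"] == {"X", "Y"}
        assert res["consensus_independent"] == {"Z"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apa.intersect_replicates([])

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        reps = []
        truth = []
        for _ in range(4):
            dep = {f"g{i}" for i in rng.choice(30, size=12, replace=False)}
            truth.append(dep)
            reps.append(self._cls(sorted(dep)))
        res = apa.intersect_replicates(reps)
        brute = {g for g in truth[0] if all(g in t for t in truth)}
        assert res["consensus_dependent"] == brute


# ------------------------------------------------------------- expression


class TestExpression:
    def test_simple_folds_and_flags(self):
        case = pd.Series({"a": 10, "b": 20, "c": 0})
        ctrl = pd.Series({"a": 20, "b": 20, "c": 5})
        out = apa.expression_fold_change(case, ctrl, fold=1.5).set_index("gene_id")
        # library sizes are within 5/45 of each other; folds follow rpm
        assert out.at["a", "fold"] == pytest.approx((20 / 45) / (10 / 30), rel=1e-9)
        assert np.isinf(out.at["c", "fold"]) and out.at["c", "reduced"]
        assert not out.at["b", "reduced"]

    def test_equal_rpm_gene_not_flagged(self):
        case = pd.Series({"a": 10, "b": 10})
        ctrl = pd.Series({"a": 30, "b": 30})
        out = apa.expression_fold_change(case, ctrl).set_index("gene_id")
        assert (out["fold"] == 1.0).all() and not out["reduced"].any()

    def test_recovery_of_simulated_reductions(self):
        """1000 genes, 50 with a true 2-fold drop at 200 reads/gene:
        >=90% of true reductions flagged, <=5% false flags."""
        rng = np.random.default_rng(21)
        n, n_true, depth = 1000, 50, 200
        ctrl = pd.Series(rng.poisson(depth, n), index=[f"g{i}" for i in range(n)])
        lam = np.full(n, float(depth))
        lam[:n_true] /= 2.0
        case = pd.Series(rng.poisson(lam), index=ctrl.index)
        out = apa.expression_fold_change(case, ctrl, fold=1.5).set_index("gene_id")
        flagged = set(out.index[out["reduced"]])
        true_set = {f"g{i}" for i in range(n_true)}
        assert len(flagged & true_set) >= 0.90 * n_true
        assert len(flagged - true_set) <= 0.05 * (n - n_true)
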