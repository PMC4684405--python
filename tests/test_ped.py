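import warnings

import numpy as np
import pytest

from xhwtest import GenotypeCounts, analyze_file, counts_from_founders, read_ped
from xhwtest.ped import reports_to_frame


def write_ped(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def trio_file(tmp_path):
    # founder couple + child; one marker
    return write_ped(tmp_path / "trio.ped", [
        "F1 dad 0 0 1 0  A A",
        "F1 mom 0 0 2 0  A B",
        "F1 kid dad mom 2 0  A A",
    ])


class TestReadPed:
    def test_trio(self, trio_file):
        recs = read_ped(trio_file)
        assert len(recs) == 3
        assert [r.is_founder for r in recs] == [True, True, False]
        assert recs[0].sex == 1 and recs[1].sex == 2

    def test_empty_file_warns(self, tmp_path):
        p = write_ped(tmp_path / "empty.ped", [""])
        with pytest.warns(UserWarning, match="no usable records"):
            assert read_ped(p) == []

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = write_ped(tmp_path / "bad.ped", [
            "F1 a 0 0 1 0 A A",
            "F1 b 0 0 2 0 A",  # odd allele count
            "F1 c 0 0 2 0 A B",
        ])
        with pytest.warns(UserWarning, match="bad.ped:2"):
            recs = read_ped(p)
        assert len(recs) == 2

    def test_unknown_sex_excluded(self, tmp_path):
        p = write_ped(tmp_path / "sex.ped", [
            "F1 a 0 0 3 0 A A",
            "F1 b 0 0 2 0 A B",
        ])
        with pytest.warns(UserWarning, match="unknown sex"):
            recs = read_ped(p)
        assert len(recs) == 1


class TestCountsFromFounders:
    def test_direct_count_with_fixed_coding(self, tmp_path):
        p = write_ped(tmp_path / "c.ped", [
            "F1 m1 0 0 1 0 A A",
            "F2 m2 0 0 1 0 A A",
            "F3 m3 0 0 1 0 B B",
            "F4 f1 0 0 2 0 A A",
            "F5 f2 0 0 2 0 A B",
            "F6 f3 0 0 2 0 B B",
        ])
        c = counts_from_founders(read_ped(p), 0, m1_allele="A")
        assert c.as_tuple() == (2, 1, 1, 1, 1)

    def test_minor_allele_default(self, tmp_path):
        # B is rarer: 1 male + 1 het + 2 hom = 4 copies vs 5 A copies
        p = write_ped(tmp_path / "c.ped", [
            "F1 m1 0 0 1 0 A A",
            "F2 m2 0 0 1 0 A A",
            "F3 m3 0 0 1 0 B B",
            "F4 f1 0 0 2 0 A A",
            "F5 f2 0 0 2 0 A B",
            "F6 f3 0 0 2 0 B B",
        ])
        c = counts_from_founders(read_ped(p), 0)
        assert c.as_tuple() == (1, 2, 1, 1, 1)  # M1 = B

    def test_coding_swap_flips_counts(self, tmp_path):
        p = write_ped(tmp_path / "c.ped", [
            "F1 m1 0 0 1 0 A A",
            "F2 f1 0 0 2 0 A B",
            "F3 f2 0 0 2 0 B B",
        ])
        recs = read_ped(p)
        a = counts_from_founders(recs, 0, m1_allele="A")
        b = counts_from_founders(recs, 0, m1_allele="B")
        assert b == a.swap_alleles()

    def test_non_founders_never_contribute(self, trio_file):
        c = counts_from_founders(read_ped(trio_file), 0, m1_allele="A")
        assert c.Nf == 1  # kid (AA female) not counted

    def test_missing_genotype_excluded_per_marker(self, tmp_path):
        p = write_ped(tmp_path / "m.ped", [
            "F1 f1 0 0 2 0  0 A  A B",
            "F2 f2 0 0 2 0  A B  A B",
        ])
        recs = read_ped(p)
        assert counts_from_founders(recs, 0, m1_allele="A").Nf == 1
        assert counts_from_founders(recs, 1, m1_allele="A").Nf == 2

    def test_heterozygous_male_excluded_with_warning(self, tmp_path):
        p = write_ped(tmp_path / "h.ped", [
            "F1 m1 0 0 1 0 A B",
            "F2 m2 0 0 1 0 A A",
        ])
        recs = read_ped(p)
        with pytest.warns(UserWarning, match="heterozygous"):
            c = counts_from_founders(recs, 0, m1_allele="A")
        assert c.Nm == 1

    def test_round_trip_from_known_counts(self, tmp_path):
        target = GenotypeCounts(3, 2, 2, 3, 1)
        lines = []
        i = 0
        for n, geno, sex in [(3, "A A", 1), (2, "B B", 1), (2, "A A", 2),
                             (3, "A B", 2), (1, "B B", 2)]:
            for _ in range(n):
                i += 1
                lines.append(f"F{i} i{i} 0 0 {sex} 0 {geno}")
        p = write_ped(tmp_path / "r.ped", lines)
        c = counts_from_founders(read_ped(p), 0, m1_allele="A")
        assert c == target


class TestAnalyzeFile:
    @pytest.fixture
    def two_marker_file(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = []
        # marker 1: exact HWE at p=0.5 among females; marker 2: no hets
        genos_f = ["A A", "A B", "A B", "B B"]
        genos_f2 = ["A A", "A A", "B B", "B B"]
        i = 0
        for gf, gf2 in zip(genos_f, genos_f2):
            i += 1
            lines.append(f"F{i} f{i} 0 0 2 0 {gf} {gf2}")
        for gm in ["A A", "B B"]:
            i += 1
            lines.append(f"F{i} m{i} 0 0 1 0 {gm} {gm}")
        return write_ped(tmp_path / "two.ped", lines)

    def test_reports_and_output(self, tmp_path, two_marker_file):
        out = tmp_path / "results.txt"
        reports, thr = analyze_file(two_marker_file, tests=["Z1", "Z2", "LRT2"],
                                    seed=1, out_path=out)
        assert len(reports) == 2
        assert thr == pytest.approx(0.05 / 2)
        text = out.read_text()
        assert "Bonferroni" in text
        assert "P_LRT2" in text

    def test_exact_null_locus(self, tmp_path):
        lines = []
        i = 0
        for n, geno, sex in [(3, "A A", 1), (7, "B B", 1), (9, "A A", 2),
                             (42, "A B", 2), (49, "B B", 2)]:
            for _ in range(n):
                i += 1
                lines.append(f"F{i} i{i} 0 0 {sex} 0 {geno}")
        p = write_ped(tmp_path / "null.ped", lines)
        reports, _ = analyze_file(p, tests=["LRT0", "LRT1", "LRT2", "Z1"], seed=1)
        res = reports[0].results
        for name in ("LRT0", "LRT1", "LRT2"):
            assert res[name].statistic == pytest.approx(0.0, abs=1e-9)
        assert res["Z1"].p_value == pytest.approx(1.0)

    def test_deterministic_under_seed(self, two_marker_file):
        a, _ = analyze_file(two_marker_file, tests=["LRT2b"], boot_b=100, seed=5)
        b, _ = analyze_file(two_marker_file, tests=["LRT2b"], boot_b=100, seed=5)
        pa = [r.results["LRT2b"].p_value for r in a]
        pb = [r.results["LRT2b"].p_value for r in b]
        assert pa == pb

    def test_monomorphic_marker_flagged_not_dropped(self, tmp_path):
        p = write_ped(tmp_path / "mono.ped", [
            "F1 f1 0 0 2 0 A A",
            "F2 f2 0 0 2 0 A A",
            "F3 m1 0 0 1 0 A A",
        ])
        reports, _ = analyze_file(p, tests=["Z2", "LRT2"], seed=1)
        rep = reports[0]
        assert rep.results["Z2"] is None
        assert rep.notes  # flagged
        frame = reports_to_frame(reports, ["Z2", "LRT2"])
        assert len(frame) == 1
        assert np.isnan(frame.loc[0, "P_Z2"])
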