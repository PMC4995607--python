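"""Genotype container, PED/MAP round trips, allele frequencies and QC rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import altisweep as aw
from altisweep.genotypes import minor_allele_frequencies


def _write_read(matrix, tmp_path):
    ped, mp = tmp_path / "p.ped", tmp_path / "p.map"
    aw.write_genotypes(matrix, ped, mp)
    return aw.read_genotypes(ped, mp)


class TestPedMapIO:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        back = _write_read(tiny_matrix, tmp_path)
        assert [s.id for s in back.samples] == [s.id for s in tiny_matrix.samples]
        assert [s.altitude_class for s in back.samples] == \
               [s.altitude_class for s in tiny_matrix.samples]
        assert [(l.id, l.chrom, l.pos) for l in back.loci] == \
               [(l.id, l.chrom, l.pos) for l in tiny_matrix.loci]
        np.testing.assert_array_equal(back.dosage, tiny_matrix.dosage)

    def test_round_trip_with_missing(self, random_matrix, tmp_path):
        back = _write_read(random_matrix, tmp_path)
        np.testing.assert_array_equal(back.dosage, random_matrix.dosage)

    def test_missing_code_reads_as_missing(self, tmp_path):
        (tmp_path / "x.map").write_text("1 s1 0 100\n")
        (tmp_path / "x.ped").write_text("fam1 ind1 0 0 0 -9 0 0\n")
        m = aw.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")
        assert m.dosage[0, 0] == aw.MISSING

    def test_dosage_counts_second_allele(self, tmp_path):
        # sample1 "A A, A G" -> dosages (0, 1) when a2=G at both loci
        (tmp_path / "x.map").write_text("1 s1 0 100\n1 s2 0 200\n")
        (tmp_path / "x.ped").write_text(
            "f i1 0 0 0 -9 A A A G\nf i2 0 0 0 -9 A G G G\n")
        m = aw.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")
        np.testing.assert_array_equal(m.dosage, [[0, 1], [1, 2]])
        assert m.loci[0].allele_a2 == "G"

    def test_loci_sorted_after_loading(self, tmp_path):
        (tmp_path / "x.map").write_text("2 b 0 50\n1 a 0 300\n1 c 0 100\n")
        (tmp_path / "x.ped").write_text("f i 0 0 0 -9 A G C T A A\n")
        m = aw.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")
        assert [(l.chrom, l.pos) for l in m.loci] == [("1", 100), ("1", 300), ("2", 50)]

    def test_malformed_line_names_line_number(self, tmp_path):
        (tmp_path / "x.map").write_text("1 s1 0 100\n")
        (tmp_path / "x.ped").write_text("f i1 0 0 0 -9 A\n")
        with pytest.raises(aw.genotypes.GenotypeParseError, match=":1"):
            aw.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")

    def test_duplicate_locus_id_rejected(self, tmp_path):
        (tmp_path / "x.map").write_text("1 s1 0 100\n1 s1 0 200\n")
        (tmp_path / "x.ped").write_text("f i 0 0 0 -9 A G A G\n")
        with pytest.raises(aw.genotypes.GenotypeParseError, match="duplicate"):
            aw.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")

    def test_empty_locus_matrix(self, tmp_path):
        m = aw.GenotypeMatrix(samples=[aw.SampleInfo("i", "p")], loci=[],
                              dosage=np.zeros((1, 0), dtype=np.int8))
        aw.write_genotypes(m, tmp_path / "e.ped", tmp_path / "e.map")
        assert [l for l in (tmp_path / "e.map").read_text().splitlines()
                if not l.startswith("#")] == []
        assert (tmp_path / "e.ped").read_text().split() == ["p", "i", "0", "0", "0", "-9"]


class TestAlleleFrequency:
    @pytest.mark.parametrize("counts,expect_pct", [
        ((15, 0, 0), 100.0),     # fixed: 30 of 30 copies
        ((12, 11, 8), 56.45),    # 35 of 62 copies
        ((23, 4, 1), 10.71),     # 50 of 56 copies -> other allele 6/56
        ((19, 1, 0), 2.5),       # counted from the rare side: 1 of 40
    ])
    def test_frequency_from_genotype_counts(self, counts, expect_pct):
        """Genotype counts (AA, AT, TT) give allele frequencies (2*AA+AT)/2n
        for A; the reported percentage is whichever allele matches."""
        n_aa, n_at, n_tt = counts
        n = sum(counts)
        dosage = np.array([[0]] * n_aa + [[1]] * n_at + [[2]] * n_tt, dtype=np.int8)
        m = aw.GenotypeMatrix(
            samples=[aw.SampleInfo(f"i{k}", "pop") for k in range(n)],
            loci=[aw.LocusInfo("s", "7", 57_843_681, "A", "T")],
            dosage=dosage)
        fa = aw.allele_frequency(m, "pop", "s", "A")
        ft = aw.allele_frequency(m, "pop", "s", "T")
        assert fa.copies == 2 * n_aa + n_at and ft.copies == 2 * n_tt + n_at
        assert min(abs(fa.frequency * 100 - expect_pct),
                   abs(ft.frequency * 100 - expect_pct)) < 0.005
        assert fa.chromosomes == 2 * n

    def test_frequencies_of_both_alleles_sum_to_one(self, random_matrix):
        fa = aw.allele_frequency(random_matrix, "popA", "m3", "A")
        fg = aw.allele_frequency(random_matrix, "popA", "m3", "G")
        assert fa.frequency + fg.frequency == pytest.approx(1.0)
        assert fa.copies + fg.copies == fa.chromosomes

    def test_all_missing_population_flagged_undefined(self):
        m = aw.GenotypeMatrix(
            samples=[aw.SampleInfo("i1", "p1"), aw.SampleInfo("i2", "p2")],
            loci=[aw.LocusInfo("s", "1", 1, "A", "G")],
            dosage=np.array([[aw.MISSING], [2]], dtype=np.int8))
        res = aw.allele_frequency(m, "p1", "s", "A")
        assert not res.defined and np.isnan(res.frequency)


class TestQC:
    def _panel(self, dosage, chroms=None):
        dosage = np.asarray(dosage, dtype=np.int8)
        n, k = dosage.shape
        chroms = chroms or ["1"] * k
        return aw.GenotypeMatrix(
            samples=[aw.SampleInfo(f"i{j}", "p") for j in range(n)],
            loci=[aw.LocusInfo(f"s{j}", chroms[j], 100 * (j + 1), "A", "G")
                  for j in range(k)],
            dosage=dosage)

    def test_low_call_rate_locus_removed(self):
        # locus s0 genotyped in 17/20 samples (call rate 0.85 < 0.90); the
        # affected samples each miss only 1/20 loci so they survive the
        # sample-missingness step that runs first
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(20, 20)).astype(np.int8)
        dosage[:3, 0] = aw.MISSING
        m = self._panel(dosage)
        out, report = aw.qc_filter(m, aw.QCThresholds(min_maf=0.0))
        assert out.n_samples == 20
        assert "s0" not in [l.id for l in out.loci]
        assert any(i == "s0" and "call_rate" in r for i, r in report.removed_loci)

    def test_maf_boundary_strict(self):
        # locus A: MAF 0.04 -> removed; locus B: exactly 0.05 -> retained
        col_a = [1] * 4 + [0] * 46       # 4/100 copies
        col_b = [1] * 5 + [0] * 45       # 5/100 copies
        m = self._panel(np.array([col_a, col_b]).T)
        out, _ = aw.qc_filter(m, aw.QCThresholds())
        assert [l.id for l in out.loci] == ["s1"]

    def test_high_missing_sample_removed(self):
        dosage = np.ones((3, 50), dtype=np.int8)
        dosage[0, :6] = aw.MISSING        # 12% missing
        m = self._panel(dosage)
        out, report = aw.qc_filter(m, aw.QCThresholds())
        assert out.n_samples == 2
        assert report.removed_samples[0][0] == "i0"

    def test_autosome_restriction_uses_config_labels(self):
        m = self._panel(np.array([[0, 1, 2], [1, 1, 1], [2, 1, 0], [1, 2, 1]],
                                 dtype=np.int8), chroms=["1", "X", "2"])
        out, report = aw.qc_filter(
            m, aw.QCThresholds(autosomes_only=True, autosomes=("1", "2"), min_maf=0.0))
        assert {l.chrom for l in out.loci} == {"1", "2"}

    def test_qc_idempotent(self, random_matrix):
        once, _ = aw.qc_filter(random_matrix, aw.QCThresholds())
        twice, report2 = aw.qc_filter(once, aw.QCThresholds())
        assert not report2.removed_loci and not report2.removed_samples
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            aw.QCThresholds(min_maf=1.2)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(min_value=-1, max_value=2), min_size=6, max_size=30))
def test_allele_flip_symmetry(dosages):
    """Recoding a1<->a2 maps frequency f to 1-f and leaves MAF unchanged."""
    dosage = np.array(dosages, dtype=np.int8).reshape(-1, 1)
    m = aw.GenotypeMatrix(
        samples=[aw.SampleInfo(f"i{k}", "p") for k in range(dosage.shape[0])],
        loci=[aw.LocusInfo("s", "1", 1, "A", "G")], dosage=dosage)
    flipped = aw.flip_alleles(m, "s")
    if (dosage != aw.MISSING).any():
        from altisweep.genotypes import alt_allele_frequencies

        # a2 frequency maps f -> 1-f under recoding ...
        assert alt_allele_frequencies(m.dosage)[0] + \
            alt_allele_frequencies(flipped.dosage)[0] == pytest.approx(1.0)
        # ... while the frequency of a *named* allele is invariant
        f = aw.allele_frequency(m, "p", "s", "G")
        g = aw.allele_frequency(flipped, "p", "s", "G")
        assert f.frequency == pytest.approx(g.frequency)
    np.testing.assert_allclose(minor_allele_frequencies(m.dosage),
                               minor_allele_frequencies(flipped.dosage))
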