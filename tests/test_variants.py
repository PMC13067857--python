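"""Variant filtering, allele frequencies, candidate gates, reporter flanks,
and assay concordance."""

import numpy as np
import pandas as pd
import pytest

from ribofuse import io as rio
from ribofuse import variants as vr
from ribofuse.seq_features import TranscriptModel


def table_from_dosages(dosages, pops=("popA", "popB"), positions=None):
    """dosages: list of per-variant dosage lists (-1 = missing)."""
    n_samples = len(dosages[0])
    half = n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    pop_of = pd.Series([pops[0]] * half + [pops[1]] * (n_samples - half), index=samples)
    records = pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": positions if positions is not None else np.arange(1, len(dosages) + 1) * 100,
            "ref": "A",
            "alt": "G",
            "variant_id": [f"v{i}" for i in range(len(dosages))],
        }
    )
    geno = pd.DataFrame(dosages, columns=samples)
    geno.index = pd.Index(records["variant_id"], name="variant_id")
    return vr.VariantTable(records, geno, pop_of)


class TestFilterVariants:
    def test_boundary_maf_retained(self):
        # 10 diploids, 1 alt allele of 20: MAF exactly 0.05, inclusive
        table = table_from_dosages([[1] + [0] * 9])
        assert len(vr.filter_variants(table)) == 1

    def test_excess_missingness_dropped(self):
        table = table_from_dosages([[-1, -1, -1] + [1] * 7])  # 30% missing
        assert len(vr.filter_variants(table)) == 0

    def test_toy_vcf_matches_hand_filter(self):
        # Hand application of MAF >= 0.05 and missing <= 0.2 over 6 records
        # (10 samples each): kept are v0 (MAF .05), v2 (MAF .5, 20% missing),
        # v5 (MAF .45); dropped v1 (MAF 0), v3 (30% missing), v4 (MAF .045...
        # = 1 alt of 22? no: 0 alt) -> see dosages.
        dosages = [
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],    # keep: MAF 1/20 = 0.05
            [0] * 10,                           # drop: MAF 0
            [2, 2, 1, 1, 0, 0, 0, 0, -1, -1],  # keep: miss 0.2, MAF 6/16=0.375
            [1, 1, 1, 0, 0, 0, 0, -1, -1, -1], # drop: miss 0.3
            [2] * 10,                           # drop: MAF 0 (all alt)
            [2, 2, 2, 1, 1, 1, 0, 0, 0, 0],    # keep: MAF 9/20 = 0.45
        ]
        table = table_from_dosages(dosages)
        kept = vr.filter_variants(table)
        assert list(kept.records["variant_id"]) == ["v0", "v2", "v5"]

    def test_round_trip_through_vcf(self, tmp_path):
        table = table_from_dosages(
            [[1, 0, 2, 0, 1, 0, 2, 0, 1, 0], [-1, 1, 1, 0, 0, 0, 0, 0, 0, 0]]
        )
        path = tmp_path / "toy.vcf"
        rio.write_vcf(table.records, table.genotypes, path)
        back = vr.read_vcf(str(path), table.pop_of)
        pd.testing.assert_frame_equal(
            back.genotypes, table.genotypes, check_names=False
        )


class TestPopulationAF:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 0, 0], 0.0), ([2, 2, 2], 1.0), ([0, 1, 2], 0.5)],
    )
    def test_examples(self, dosages, expected):
        table = table_from_dosages([dosages * 2])
        afs = vr.population_af(table)
        assert afs.iloc[0, 0] == pytest.approx(expected)

    def test_fully_missing_population_is_nan(self):
        table = table_from_dosages([[-1, -1, -1, 0, 1, 2]])
        afs = vr.population_af(table)
        assert np.isnan(afs.iloc[0, 0])
        assert afs.iloc[0, 1] == pytest.approx(0.5)


class TestDifferentiation:
    def test_strict_threshold(self):
        afs = pd.DataFrame(
            {"popA": [0.9, 0.6, 0.3], "popB": [0.5, 0.4, 0.0]},
            index=["big", "small", "exact"],
        )
        out = vr.differentiated_variants(afs, 0.3)
        assert out == ["big"]  # 0.4 in, 0.2 out, exactly 0.3 out (strict)


def utr5_model(gene="g1", lo=1000, hi=1299, seq=None):
    seq = seq or ("A" * 300)
    return TranscriptModel(
        gene, f"{gene}.t1", "chrS", "+", (lo, hi), (hi + 1, hi + 30), (hi + 31, hi + 60),
        seq, "ATG" + "C" * 24 + "TAA", "G" * 30,
    )


class TestAnnotateCandidates:
    def _setup(self, pos, gwas_start1):
        models = {"g1": utr5_model()}
        table = table_from_dosages([[2] * 6 + [0] * 6], positions=[pos])
        afs = pd.DataFrame({"popA": [1.0], "popB": [0.0]}, index=["v0"])
        gwas = pd.DataFrame(
            {"chrom": ["chrS"], "start": [gwas_start1 - 1], "end": [gwas_start1], "name": ["L"]}
        )
        return table, models, afs, gwas

    def test_window_boundary_inclusive(self):
        pos = 1100
        table, models, afs, gwas = self._setup(pos, pos + 20000)
        out = vr.annotate_candidates(table, models, {"g1"}, gwas, set(), afs=afs)
        assert bool(out.loc["v0", "candidate"])

    def test_just_outside_window(self):
        pos = 1100
        table, models, afs, gwas = self._setup(pos, pos + 20001)
        out = vr.annotate_candidates(table, models, {"g1"}, gwas, set(), afs=afs)
        assert not bool(out.loc["v0", "candidate"])

    def test_regulator_gene_rescues_gwas_free_variant(self):
        pos = 1100
        table, models, afs, gwas = self._setup(pos, pos + 500000)
        out = vr.annotate_candidates(table, models, {"g1"}, gwas, {"g1"}, afs=afs)
        assert bool(out.loc["v0", "candidate"])

    def test_every_single_gate_is_required(self):
        pos = 1100
        table, models, afs, gwas = self._setup(pos, pos + 1000)
        base = dict(table=table, models=models, gwas_loci=gwas, afs=afs)
        # fails detg/sub-MF gate
        out = vr.annotate_candidates(
            base["table"], models, set(), gwas, {"g1"}, afs=afs
        )
        assert not out["candidate"].any()
        # fails delta-AF gate
        afs_flat = pd.DataFrame({"popA": [0.6], "popB": [0.5]}, index=["v0"])
        out = vr.annotate_candidates(table, models, {"g1"}, gwas, {"g1"}, afs=afs_flat)
        assert not out["candidate"].any()
        # fails 5'UTR gate (variant in CDS)
        table_cds = table_from_dosages([[2] * 6 + [0] * 6], positions=[1310])
        out = vr.annotate_candidates(table_cds, models, {"g1"}, gwas, {"g1"}, afs=afs)
        assert not out["candidate"].any()

    def test_window_monotonicity(self):
        pos = 1100
        table, models, afs, gwas = self._setup(pos, pos + 15000)
        small = vr.annotate_candidates(
            table, models, {"g1"}, gwas, set(), afs=afs, window=10000
        )
        large = vr.annotate_candidates(
            table, models, {"g1"}, gwas, set(), afs=afs, window=20000
        )
        assert large["candidate"].sum() >= small["candidate"].sum()

    def test_chromosome_mismatch_errors(self):
        table, models, afs, gwas = self._setup(1100, 2000)
        table.records["chrom"] = "chrX"
        with pytest.raises(ValueError, match="chrX"):
            vr.annotate_candidates(table, models, {"g1"}, gwas, set(), afs=afs)


class TestReporterFlank:
    def test_center_of_long_utr_gives_101nt(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 300))
        m = utr5_model(seq=seq)
        variant = pd.Series({"chrom": "chrS", "pos": 1099, "ref": seq[99], "alt": "T"})
        ref_seq, alt_seq = vr.reporter_flank(variant, m)
        assert len(ref_seq) == len(alt_seq) == 101

    def test_clipped_at_utr_start(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 300))
        m = utr5_model(seq=seq)
        variant = pd.Series({"chrom": "chrS", "pos": 1019, "ref": seq[19], "alt": "T"})
        ref_seq, alt_seq = vr.reporter_flank(variant, m)
        assert len(ref_seq) == 70  # 19 upstream + variant + 50 downstream

    def test_single_position_difference(self):
        seq = "A" * 300
        m = utr5_model(seq=seq)
        variant = pd.Series({"chrom": "chrS", "pos": 1100, "ref": "A", "alt": "C"})
        ref_seq, alt_seq = vr.reporter_flank(variant, m)
        diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
        assert len(diffs) == 1

    def test_outside_utr_errors(self):
        m = utr5_model()
        variant = pd.Series({"chrom": "chrS", "pos": 1400, "ref": "A", "alt": "C"})
        with pytest.raises(ValueError, match="outside"):
            vr.reporter_flank(variant, m)


class TestConcordance:
    def _assay(self, directions, genes=None):
        genes = genes or [f"g{i}" for i in range(len(directions))]
        return pd.DataFrame(
            {"gene": genes, "direction": directions},
            index=[f"v{i}" for i in range(len(directions))],
        )

    def test_alt_up_alt_frequent_in_high_te_breed_is_concordant(self):
        assay = self._assay(["up"])
        afs = pd.DataFrame({"popA": [0.9], "popB": [0.2]}, index=["v0"])
        flags, rate = vr.assess_concordance(assay, pd.Series({"g0": "popA"}), afs)
        assert flags.loc["v0", "status"] == "concordant"
        assert rate == 100.0

    def test_alt_up_alt_frequent_in_low_te_breed_is_discordant(self):
        assay = self._assay(["up"])
        afs = pd.DataFrame({"popA": [0.9], "popB": [0.2]}, index=["v0"])
        flags, rate = vr.assess_concordance(assay, pd.Series({"g0": "popB"}), afs)
        assert flags.loc["v0", "status"] == "discordant"
        assert rate == 0.0

    def test_equal_afs_are_undetermined_and_excluded(self):
        assay = self._assay(["up", "down"])
        afs = pd.DataFrame({"popA": [0.5, 0.9], "popB": [0.5, 0.1]}, index=["v0", "v1"])
        flags, rate = vr.assess_concordance(
            assay, pd.Series({"g0": "popA", "g1": "popB"}), afs
        )
        assert flags.loc["v0", "status"] == "undetermined"
        # only v1 counts: alt lowers TE and ref is the frequent allele in the
        # high-TE population, so it is concordant
        assert flags.loc["v1", "status"] == "concordant"
        assert rate == 100.0

    def test_headline_rate_17_of_33(self):
        """33 assayed variants with 16 discordant give 51.5%."""
        assert vr.concordance_rate(17, 33) == pytest.approx(51.5, abs=0.05)

    def test_rate_from_flags_matches_formula(self):
        directions = ["up"] * 33
        afs = pd.DataFrame(
            {"popA": [0.9] * 33, "popB": [0.2] * 33},
            index=[f"v{i}" for i in range(33)],
        )
        high = pd.Series({f"g{i}": ("popA" if i < 17 else "popB") for i in range(33)})
        flags, rate = vr.assess_concordance(self._assay(directions), high, afs)
        assert rate == pytest.approx(100 * 17 / 33)
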