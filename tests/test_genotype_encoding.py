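"""Coverage normalisation, event segmentation, encoding and observations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagecoev import genotype_encoding as ge
from phagecoev import synthetic_data as sd


def rec(iso, typ, start, end, genome="bacterium", effect="nonsynonymous",
        copy_number="", ref="A", alt="G"):
    return dict(isolate_id=iso, replicate_id="R1", genome=genome, type=typ,
                start=start, end=end, ref=ref, alt=alt, copy_number=copy_number,
                effect_annotation=effect)


class TestCoverage:
    def test_identical_tracks_normalise_to_one(self):
        cov = np.random.default_rng(0).poisson(50, size=500).astype(float) + 1
        c, cands = ge.normalize_coverage(cov, cov)
        assert np.allclose(c, 1.0)
        assert cands == []

    def test_duplication_detected(self):
        anc = np.full(1000, 40.0)
        iso = anc.copy()
        iso[300:600] = 80.0
        c, cands = ge.normalize_coverage(iso, anc, min_span=100)
        assert np.allclose(c[300:600], 2.0)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end, cands[0].kind) == (301, 600, "amplification")

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(1)
        anc = rng.poisson(60, 400).astype(float) + 1
        iso = rng.poisson(60, 400).astype(float) + 1
        c1, _ = ge.normalize_coverage(iso, anc)
        c3, _ = ge.normalize_coverage(3.0 * iso, anc)
        assert np.allclose(c1, c3)

    def test_zero_ancestral_positions_masked(self):
        anc = np.full(300, 50.0)
        anc[10] = 0.0
        with pytest.warns(UserWarning):
            c, _ = ge.normalize_coverage(np.full(300, 50.0), anc)
        assert np.isnan(c[10])


class TestSegmentation:
    def test_partial_overlap_three_events(self):
        records = pd.DataFrame([rec("A", "deletion", 1000, 3000, effect="disruption"),
                                rec("B", "deletion", 2000, 4000, effect="disruption")])
        segs = ge.segment_overlapping_events(records)
        key = segs.groupby(["start", "end"])["isolate_id"].apply(set)
        assert len(key) == 3
        assert key.loc[(1000, 1999)] == {"A"}
        assert key.loc[(2000, 3000)] == {"A", "B"}
        assert key.loc[(3001, 4000)] == {"B"}

    def test_disjoint_events_unchanged(self):
        records = pd.DataFrame([rec("A", "deletion", 100, 200, effect="disruption"),
                                rec("B", "deletion", 500, 700, effect="disruption")])
        segs = ge.segment_overlapping_events(records)
        assert sorted(zip(segs["start"], segs["end"])) == [(100, 200), (500, 700)]

    def test_nested_intervals(self):
        records = pd.DataFrame([rec("A", "deletion", 100, 500, effect="disruption"),
                                rec("B", "deletion", 200, 300, effect="disruption")])
        segs = ge.segment_overlapping_events(records)
        key = segs.groupby(["start", "end"])["isolate_id"].apply(set)
        assert key.loc[(100, 199)] == {"A"}
        assert key.loc[(200, 300)] == {"A", "B"}
        assert key.loc[(301, 500)] == {"A"}

    def test_types_not_mixed(self):
        records = pd.DataFrame([
            rec("A", "deletion", 100, 300, effect="disruption"),
            rec("B", "amplification", 200, 400, copy_number=3, effect="disruption"),
        ])
        segs = ge.segment_overlapping_events(records)
        # a deletion and an amplification overlapping do not cut each other
        assert sorted(zip(segs["type"], segs["start"], segs["end"])) == [
            ("amplification", 200, 400), ("deletion", 100, 300)]

    @given(st.lists(
        st.tuples(st.sampled_from("ABCD"), st.integers(1, 300), st.integers(1, 200)),
        min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_covered_bases_conserved(self, raw):
        records = pd.DataFrame(
            [rec(iso, "deletion", s, s + ln - 1, effect="disruption")
             for iso, s, ln in raw]
        )
        segs = ge.segment_overlapping_events(records)
        for iso in records["isolate_id"].unique():
            def covered(df):
                base = np.zeros(1000, dtype=int)
                for _, r in df[df["isolate_id"] == iso].iterrows():
                    base[r["start"] - 1 : r["end"]] += 1
                return base
            assert np.array_equal(covered(records), covered(segs))


class TestEncoding:
    def test_single_snp_binary_column(self):
        records = pd.DataFrame([rec("A", "SNP", 50, 50)])
        gm = ge.encode_predictors(records, isolates=["A", "B"])
        assert gm.values.shape == (2, 1)
        assert list(gm.values.iloc[:, 0]) == [1, 0]

    def test_amplification_integer_with_ancestral_one(self):
        records = pd.DataFrame([rec("A", "amplification", 10, 90, copy_number=3,
                                    effect="disruption")])
        gm = ge.encode_predictors(records, isolates=["A", "B", "C"])
        assert list(gm.values.iloc[:, 0]) == [3, 1, 1]

    def test_synonymous_snps_omitted(self):
        records = pd.DataFrame([rec("A", "SNP", 50, 50, effect="synonymous")])
        gm = ge.encode_predictors(records, isolates=["A"])
        assert gm.values.shape[1] == 0

    def test_conflicting_amplification_records_rejected(self):
        records = pd.DataFrame([
            rec("A", "amplification", 10, 90, copy_number=3, effect="disruption"),
            rec("A", "amplification", 10, 90, copy_number=5, effect="disruption"),
        ])
        with pytest.raises(ValueError):
            ge.encode_predictors(records, isolates=["A"])


class TestJoining:
    def _matrix(self, records, isolates):
        return ge.encode_predictors(pd.DataFrame(records), isolates=isolates)

    def test_identical_patterns_merged(self):
        gm = self._matrix(
            [rec("A", "SNP", 10, 10), rec("A", "SNP", 99, 99)], ["A", "B"]
        )
        joined = ge.join_cooccurring(gm)
        assert joined.values.shape[1] == 1
        assert "+" in joined.values.columns[0]

    def test_amplifications_never_merged(self):
        gm = self._matrix(
            [rec("A", "amplification", 10, 90, copy_number=2, effect="disruption"),
             rec("A", "amplification", 200, 300, copy_number=2, effect="disruption")],
            ["A", "B"],
        )
        joined = ge.join_cooccurring(gm)
        assert joined.values.shape[1] == 2

    def test_distinct_patterns_untouched_and_idempotent(self):
        gm = self._matrix(
            [rec("A", "SNP", 10, 10), rec("B", "SNP", 99, 99)], ["A", "B"]
        )
        j1 = ge.join_cooccurring(gm)
        assert j1.values.shape[1] == 2
        j2 = ge.join_cooccurring(j1)
        pd.testing.assert_frame_equal(j1.values, j2.values)


class TestObservations:
    def test_identical_genotypes_pooled(self):
        bact = pd.DataFrame({"m1": [1]}, index=["B1"])
        phage = pd.DataFrame({"p1": [0, 0]}, index=["P1", "P2"])
        M = pd.DataFrame([[0.2], [0.4]], index=["P1", "P2"], columns=["B1"])
        obs = ge.build_observations(bact, phage, M)
        assert len(obs) == 1
        assert obs["response"].iloc[0] == pytest.approx(0.3)
        assert obs["weight"].iloc[0] == 2

    def test_unique_genotypes_one_observation_per_pair(self):
        rng = np.random.default_rng(2)
        bact = pd.DataFrame(np.eye(4, dtype=int), index=[f"B{i}" for i in range(4)])
        bact.columns = [f"m{i}" for i in range(4)]
        phage = pd.DataFrame(np.eye(3, dtype=int), index=[f"P{i}" for i in range(3)])
        phage.columns = [f"p{i}" for i in range(3)]
        M = pd.DataFrame(rng.uniform(size=(3, 4)),
                         index=phage.index, columns=bact.index)
        obs = ge.build_observations(bact, phage, M)
        assert len(obs) == 12
        assert obs["weight"].sum() == 12

    def test_weights_sum_to_scored_pairs(self):
        out = sd.gen_genotype_phenotype(sd.SimGenotypeSpec(seed=8))
        obs = ge.build_observations(out["bacteria_genotypes"],
                                    out["phage_genotypes"],
                                    out["infection_matrix"])
        scored = int(out["infection_matrix"].notna().sum().sum())
        assert obs["weight"].sum() == scored
        assert obs["response"].between(0, 1).all()

    def test_isolate_mismatch_rejected(self):
        bact = pd.DataFrame({"m1": [1]}, index=["B1"])
        phage = pd.DataFrame({"p1": [1]}, index=["P1"])
        M = pd.DataFrame([[0.5]], index=["P1"], columns=["B_unknown"])
        with pytest.raises(ValueError):
            ge.build_observations(bact, phage, M)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        out = sd.gen_genotype_phenotype(
            sd.SimGenotypeSpec(n_bacteria=6, n_phage=4, n_mutations=8,
                               n_pairs=None, seed=3)
        )
        path = tmp_path / "muts.tsv"
        ge.write_mutation_table(out["bacteria_mutations"], path)
        back = ge.read_mutation_table(path)
        assert len(back) == len(out["bacteria_mutations"])
        assert set(back["isolate_id"]) == set(out["bacteria_mutations"]["isolate_id"])
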