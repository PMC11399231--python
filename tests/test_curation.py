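"""Degeneracy-aware dataset construction and fitness arithmetic."""

import numpy as np
import pytest

from codonlens.curation import (
    MutationDescriptor,
    MutationScanDataset,
    ReferenceInconsistencyError,
    apply_codon_mutation,
    build_complete_set,
    build_unique_set,
    dedupe_degenerate_test,
    degeneracy_key,
    enumerate_codon_substitutions,
    filter_translation_mismatch,
    fitness_weighted_average,
    group_degenerate,
    normalize_fitness,
)
from codonlens.seqcore import STANDARD_CODE, CdsRecord, ProteinRecord, translate

from conftest import random_cds_string


def rec(seq, i=None):
    return CdsRecord(id=i or seq, sequence=seq)


class TestMutationDescriptor:
    def test_derived_fields_and_display(self):
        m = MutationDescriptor(position=26, ref_codon="TCT", alt_codon="TGT")
        assert (m.ref_aa, m.alt_aa) == ("S", "C")
        assert str(m) == "S26C"
        assert not m.is_synonymous

    def test_synonymous_flag(self):
        assert MutationDescriptor(1, "GCT", "GCC").is_synonymous

    def test_identical_codons_rejected(self):
        with pytest.raises(ValueError):
            MutationDescriptor(1, "GCT", "GCT")


class TestFilterTranslationMismatch:
    def test_keep_and_reject(self):
        pairs = [
            (rec("ATGGCT", "a"), ProteinRecord(id="a", sequence="MA")),
            (rec("ATGGCT", "b"), ProteinRecord(id="b", sequence="MV")),
        ]
        kept, log = filter_translation_mismatch(pairs)
        assert [c.id for c, _ in kept] == ["a"]
        assert log[0]["id"] == "b" and "mismatch" in log[0]["reason"]

    def test_empty(self):
        assert filter_translation_mismatch([]) == ([], [])

    def test_frame_errors_become_rejections(self):
        kept, log = filter_translation_mismatch(
            [(rec("ATGGC", "x"), ProteinRecord(id="x", sequence="MA"))]
        )
        assert kept == [] and "FrameError" in log[0]["reason"]

    def test_planted_mismatches_counted(self, rng):
        """Exactly the planted corruptions are rejected."""
        pairs = []
        bad = {2, 5, 7}
        for i in range(10):
            cds = rec(random_cds_string(rng, 12), f"s{i}")
            prot = translate(cds)
            if i in bad:
                prot = prot[:-1] + ("W" if prot[-1] != "W" else "C")
            pairs.append((cds, ProteinRecord(id=f"s{i}", sequence=prot)))
        kept, log = filter_translation_mismatch(pairs)
        assert {e["id"] for e in log} == {f"s{i}" for i in bad}
        assert len(kept) == 7


class TestGroupDegenerate:
    def test_basic_grouping(self):
        groups = group_degenerate([rec("GCT"), rec("GCC"), rec("ATG")])
        assert set(groups) == {"A", "M"}
        assert {r.sequence for r in groups["A"]} == {"GCT", "GCC"}

    def test_all_distinct_singletons(self):
        groups = group_degenerate([rec("ATG"), rec("TGG")])
        assert all(len(v) == 1 for v in groups.values())

    def test_synonymous_scan_group_sizes_match_code(self):
        """A full substitution scan at one codon groups by synonym sets."""
        reference = rec("ATGGCTCTT", "wt")
        variants = enumerate_codon_substitutions(reference, position=2)
        groups = group_degenerate([reference, *variants])
        for key, members in groups.items():
            aa2 = key[1] if len(key) > 1 else "*"
            expected = len(STANDARD_CODE.synonym_sets[aa2])
            assert len(members) == expected

    def test_terminal_stop_ignored(self):
        assert len(group_degenerate([rec("ATGTAA"), rec("ATG")])) == 1


class TestCompleteSet:
    def test_degenerate_with_test_removed(self):
        out = build_complete_set([rec("GCT"), rec("ATG")], [rec("GCC")])
        assert [r.sequence for r in out] == ["ATG"]

    def test_disjoint_proteomes_untouched(self):
        train = [rec("ATG"), rec("TGG")]
        assert build_complete_set(train, [rec("GCC")]) == train

    def test_resulting_protein_sets_disjoint(self, rng):
        pool = [rec(random_cds_string(rng, 6), f"r{i}") for i in range(60)]
        train, test = pool[:40], pool[40:]
        out = build_complete_set(train, test)
        assert not (
            {degeneracy_key(r) for r in out} & {degeneracy_key(r) for r in test}
        )


class TestUniqueSet:
    def test_one_per_group(self):
        out = build_unique_set([rec("GCT"), rec("GCC"), rec("ATG")], seed=0)
        assert len(out) == 2
        assert "ATG" in {r.sequence for r in out}

    def test_singletons_identity(self):
        recs = [rec("ATG"), rec("TGG")]
        assert build_unique_set(recs, seed=3) == recs

    def test_seed_reproducible(self):
        recs = [rec(s, str(i)) for i, s in enumerate(
            ["GCT", "GCC", "GCA", "CTT", "CTC", "ATG"])]
        a = build_unique_set(recs, seed=42)
        b = build_unique_set(recs, seed=42)
        assert [r.id for r in a] == [r.id for r in b]

    def test_nondegenerate_and_maximal(self, rng):
        recs = [rec(random_cds_string(rng, 4), f"r{i}") for i in range(80)]
        out = build_unique_set(recs, seed=1)
        keys = [degeneracy_key(r) for r in out]
        assert len(keys) == len(set(keys))  # nondegenerate
        assert len(out) == len({degeneracy_key(r) for r in recs})
        kept_ids = {r.id for r in out}
        for r in recs:  # maximal: any removed CDS collides with a kept one
            if r.id not in kept_ids:
                assert degeneracy_key(r) in set(keys)

    def test_raw_labels_retained(self):
        recs = [CdsRecord(id="a", sequence="GCT", label=0.4),
                CdsRecord(id="b", sequence="GCC", label=0.8)]
        (kept,) = build_unique_set(recs, seed=5)
        assert kept.label in (0.4, 0.8)  # raw, never averaged


class TestDedupeDegenerateTest:
    def test_one_degenerate_pair_keeps_one(self):
        test = [rec("ATG", "m"), rec("GCT", "a1"), rec("GCC", "a2"),
                rec("TGG", "w")]
        kept, removed = dedupe_degenerate_test(test, seed=9)
        assert len(kept) == 3 and len(removed) == 1
        assert removed[0].id in {"a1", "a2"}
        again, _ = dedupe_degenerate_test(test, seed=9)
        assert [r.id for r in again] == [r.id for r in kept]


class TestApplyCodonMutation:
    def test_substitution(self):
        out = apply_codon_mutation(
            rec("ATGGCT", "wt"), MutationDescriptor(2, "GCT", "GCC")
        )
        assert out.sequence == "ATGGCC"
        assert str(out.mutation) == "A2A"

    def test_reference_inconsistency(self):
        with pytest.raises(ReferenceInconsistencyError):
            apply_codon_mutation(
                rec("ATGGCT"), MutationDescriptor(2, "GCA", "GCC")
            )

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            apply_codon_mutation(
                rec("ATGGCT"), MutationDescriptor(3, "GCT", "GCC")
            )

    def test_full_scan_yields_63(self):
        variants = enumerate_codon_substitutions(rec("ATGGCT"), position=2)
        assert len(variants) == 63
        assert len({v.sequence for v in variants}) == 63

    def test_exclude_stops(self):
        variants = enumerate_codon_substitutions(
            rec("ATGGCT"), position=2, include_stops=False
        )
        assert len(variants) == 60

    def test_translation_single_residue_change(self, rng):
        reference = rec(random_cds_string(rng, 10), "wt")
        for v in enumerate_codon_substitutions(reference, position=4):
            a = translate(reference, allow_internal_stop=True)
            b = translate(v, allow_internal_stop=True)
            assert len(a) == len(b)
            assert sum(x != y for x, y in zip(a, b)) <= 1


class TestScanDatasetValidation:
    def test_inconsistent_variant_rejected(self):
        reference = rec("ATGGCT", "wt")
        bad = CdsRecord(id="v", sequence="TTGGCC",
                        mutation=MutationDescriptor(2, "GCT", "GCC"))
        with pytest.raises(ValueError):
            MutationScanDataset(reference=reference, variants=[bad])


class TestFitness:
    @pytest.mark.parametrize(
        "counts,conc,expected",
        [
            ([10], [10], 1.0),
            ([5, 5], [1, 100], 1.0),  # (5*0 + 5*2) / 10
            ([0, 10], [1, 100], 2.0),
        ],
    )
    def test_weighted_average(self, counts, conc, expected):
        assert fitness_weighted_average(counts, conc) == pytest.approx(expected)

    def test_zero_total_count(self):
        with pytest.raises(ValueError):
            fitness_weighted_average([0, 0], [1, 10])

    def test_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            fitness_weighted_average([1], [0])

    def test_injectable_log(self):
        assert fitness_weighted_average(
            [1], [np.e], log_fn=np.log
        ) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "f,fwt,w", [(2.0, 2.0, 1.0), (3.0, 2.0, 1.5), (0.0, 2.0, 0.0)]
    )
    def test_normalize(self, f, fwt, w):
        assert normalize_fitness(f, fwt) == pytest.approx(w)

    def test_more_fit_than_wt_flag(self):
        from codonlens.curation import FitnessRecord

        assert FitnessRecord(f=3.0, f_wt=2.0).more_fit_than_wt
        assert not FitnessRecord(f=1.0, f_wt=2.0).more_fit_than_wt

    def test_zero_wildtype(self):
        with pytest.raises(ZeroDivisionError):
            normalize_fitness(1.0, 0.0)
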