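"""Structure-dataset filter cascade and threshold classifiers."""

import itertools
import random

import pytest

from kinvar.errors import InputError
from kinvar.io import AA_ORDER
from kinvar.structure import (
    FAUCHERE_PLISKA,
    StructureRecord,
    binding_delta,
    classify_conservation,
    classify_exposure,
    classify_stability,
    format_ranges,
    hbond_delta,
    hydrophobicity_delta,
    hydrophobicity_direction,
    parse_ranges,
    ss_group,
    structure_filter,
)

from conftest import make_variant


def record(gene="GRK4", coverage=0.9, positions=range(1, 501), has_drug=True):
    return StructureRecord(
        gene=gene,
        pdb_id="4YHJ",
        coverage=coverage,
        crystallized_positions=frozenset(positions),
        has_drug=has_drug,
    )


class TestFilterCascade:
    def test_low_af_fails_filter_5(self):
        kept, excluded = structure_filter([make_variant(af=0.09)], [record()])
        assert kept == [] and excluded[0].filter_number == 5

    def test_coverage_exception_retains_crystallized_position(self):
        kept, excluded = structure_filter(
            [make_variant(af=0.12)], [record(coverage=0.65)]
        )
        assert len(kept) == 1 and excluded == []

    def test_coverage_exception_can_be_disabled(self):
        kept, excluded = structure_filter(
            [make_variant(af=0.12)], [record(coverage=0.65)], coverage_exception=False
        )
        assert kept == [] and excluded[0].filter_number == 4

    def test_uncrystallized_position_fails_filter_3(self):
        kept, excluded = structure_filter(
            [make_variant(pos=600, af=0.12)], [record(positions=range(1, 501))]
        )
        assert kept == [] and excluded[0].filter_number == 3

    def test_no_structure_fails_filter_1(self):
        kept, excluded = structure_filter([make_variant(gene="NOPDB", af=0.5)], [record()])
        assert kept == [] and excluded[0].filter_number == 1

    def test_drug_filter_only_when_required(self):
        v = [make_variant(af=0.5)]
        recs = [record(has_drug=False)]
        kept, _ = structure_filter(v, recs)
        assert len(kept) == 1
        kept, excluded = structure_filter(v, recs, require_drug=True)
        assert kept == [] and excluded[0].filter_number == 2

    @staticmethod
    def _random_instance(rng):
        genes = [f"G{i}" for i in range(6)]
        records = [
            StructureRecord(
                gene=g,
                pdb_id=f"1AB{i}",
                coverage=rng.uniform(0.4, 1.0),
                crystallized_positions=frozenset(
                    rng.sample(range(1, 101), rng.randint(0, 80))
                ),
                has_drug=rng.random() < 0.5,
            )
            for i, g in enumerate(genes[:4])  # two genes have no structure
        ]
        variants = [
            make_variant(
                "R", "W", gene=rng.choice(genes), pos=rng.randint(1, 110),
                af=round(rng.random(), 3),
            )
            for _ in range(40)
        ]
        return variants, records

    def test_idempotence_and_output_subset(self):
        rng = random.Random(0)
        for _ in range(25):
            variants, records = self._random_instance(rng)
            kept, excluded = structure_filter(variants, records, require_drug=True)
            assert set(kept) <= set(variants)
            assert len(kept) + len(excluded) == len(variants)
            kept2, excluded2 = structure_filter(kept, records, require_drug=True)
            assert kept2 == kept and excluded2 == []

    def test_relaxing_any_filter_never_shrinks_output(self):
        rng = random.Random(1)
        for _ in range(25):
            variants, records = self._random_instance(rng)
            strict_kwargs = dict(
                af_min=0.10, coverage_min=0.70, require_drug=True, coverage_exception=False
            )
            base = set(structure_filter(variants, records, **strict_kwargs)[0])
            for relaxed in (
                dict(strict_kwargs, af_min=0.0),
                dict(strict_kwargs, coverage_min=0.0),
                dict(strict_kwargs, require_drug=False),
                dict(strict_kwargs, coverage_exception=True),
            ):
                assert base <= set(structure_filter(variants, records, **relaxed)[0])

    def test_ranges_round_trip(self):
        assert parse_ranges("30-32,40,50-51") == frozenset({30, 31, 32, 40, 50, 51})
        assert format_ranges({30, 31, 32, 40, 50, 51}) == "30-32,40,50-51"


class TestThresholdClassifiers:
    @pytest.mark.parametrize(
        "value,label", [(4.9, "buried"), (81.0, "exposed"), (5.0, "exposed"), (0.0, "buried")]
    )
    def test_exposure_cutoff(self, value, label):
        assert classify_exposure(value) == label

    def test_negative_accessibility_rejected(self):
        with pytest.raises(InputError):
            classify_exposure(-0.1)

    @pytest.mark.parametrize(
        "ddG,ddS,expected",
        [
            (-2.767, 1.178, ("destabilizing", "increased")),
            (0.5, -0.1, ("stabilizing", "decreased")),
            (0.0, 0.0, ("stabilizing", "decreased")),
        ],
    )
    def test_stability_flexibility(self, ddG, ddS, expected):
        assert classify_stability(ddG, ddS) == expected

    @pytest.mark.parametrize(
        "score,label",
        [(-1.5, "highly_conserved"), (0.0, "intermediate"), (1.2, "highly_variable"),
         (-1.0, "intermediate"), (1.0, "intermediate")],
    )
    def test_conservation(self, score, label):
        assert classify_conservation(score) == label

    def test_hydrophobicity_identity_and_phe_to_ala(self):
        assert hydrophobicity_delta("A", "A") == (0.0, "no_significant_change")
        delta, _ = hydrophobicity_delta("F", "A")
        assert delta > 0  # Phe outranks Ala: mutant is less hydrophobic
        assert hydrophobicity_direction("F", "A") == "decreased"

    def test_hydrophobicity_antisymmetry_all_400_pairs(self):
        for a, b in itertools.product(AA_ORDER, repeat=2):
            da, _ = hydrophobicity_delta(a, b)
            db, _ = hydrophobicity_delta(b, a)
            assert da == pytest.approx(-db)

    def test_hydrophobicity_thresholds(self):
        # R -> C spans more than 2 units toward hydrophobic: significant increase
        delta, cls = hydrophobicity_delta("R", "C")
        assert delta == pytest.approx(-2.55) and cls == "increase"
        delta, cls = hydrophobicity_delta("W", "R")
        assert delta == pytest.approx(3.26) and cls == "decrease"

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(InputError):
            hydrophobicity_delta("X", "A")

    def test_scale_is_the_published_table(self):
        # spot anchors of the octanol/water pi scale
        assert FAUCHERE_PLISKA["G"] == 0.0
        assert FAUCHERE_PLISKA["W"] == max(FAUCHERE_PLISKA.values())
        assert FAUCHERE_PLISKA["R"] == min(FAUCHERE_PLISKA.values())

    @pytest.mark.parametrize("before,after,expected", [(5, 3, -2), (4, 4, 0), (2, 3, 1)])
    def test_hbond_delta(self, before, after, expected):
        assert hbond_delta(before, after) == expected

    @pytest.mark.parametrize(
        "native,mutant,delta,label",
        [
            (-13.0, -3.9, -9.1, "decrease"),
            (-8.0, -8.0, 0.0, "no_change"),
            (-6.0, -7.0, 1.0, "increase"),
        ],
    )
    def test_binding_delta(self, native, mutant, delta, label):
        d, lab = binding_delta(native, mutant)
        assert d == pytest.approx(delta) and lab == label

    def test_ss_grouping(self):
        assert [ss_group(c) for c in "HGIEB TS-"] == [
            "helix", "helix", "helix", "strand", "strand",
            "loop", "loop", "loop", "loop",
        ]
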