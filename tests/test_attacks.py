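import numpy as np
import pytest

from aposignal import (
    DamageMark,
    SpecimenRecord,
    background_predation_pressure,
    classify_mark,
    compare_indices,
    read_marks_table,
    score_specimen,
    site_attack_rate,
    write_marks_table,
)
from aposignal.attacks import dedupe_records
from aposignal.errors import NoDataError, ValidationError


def specimen(
    id="B1",
    category="palatable_nonmimic",
    ring="none",
    wingspan=70.0,
    marks=(),
    site="S01",
    transect="S01-T1",
    age=3,
):
    return SpecimenRecord(
        id=id,
        species="sp",
        category=category,
        ring=ring,
        wingspan_mm=wingspan,
        age_class=age,
        site=site,
        transect=transect,
        marks=tuple(marks),
    )


def bird_mark(depth=8.0, symmetric=False):
    return DamageMark(
        depth_mm=depth, symmetric=symmetric, wing="both" if symmetric else "left"
    )


class TestClassifyMark:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (1.5, "excluded"),  # very small (<2 mm) damage is wear, not beak
            (2.0, "ambiguous"),
            (3.0, "ambiguous"),  # 2-5 mm: bird or other natural causes
            (5.0, "ambiguous"),
            (5.1, "bird_attack"),  # >5 mm is diagnostic of a bird strike
            (7.0, "bird_attack"),
        ],
    )
    def test_depth_rules(self, depth, expected):
        assert classify_mark(DamageMark(depth_mm=depth)) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValidationError):
            DamageMark(depth_mm=-1.0)

    def test_symmetric_mark_must_span_both_wings(self):
        with pytest.raises(ValidationError):
            DamageMark(depth_mm=8.0, symmetric=True, wing="left")


class TestScoreSpecimen:
    def test_symmetric_damage_is_one_attack(self):
        s = specimen(marks=[bird_mark(8.0, symmetric=True)])
        assert score_specimen(s) == (1, 1)

    def test_all_tiny_marks_score_zero(self):
        s = specimen(marks=[DamageMark(1.0), DamageMark(1.5), DamageMark(0.5)])
        assert score_specimen(s) == (0, 0)

    def test_count_vs_binary(self):
        s = specimen(marks=[bird_mark(8.0), bird_mark(6.0)])
        assert score_specimen(s) == (2, 1)

    def test_ambiguous_flag(self):
        s = specimen(marks=[DamageMark(3.0)])
        assert score_specimen(s, include_ambiguous=True) == (1, 1)
        assert score_specimen(s, include_ambiguous=False) == (0, 0)

    def test_attacked_never_exceeds_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            marks = [DamageMark(float(d)) for d in rng.uniform(0, 10, rng.integers(0, 5))]
            count, attacked = score_specimen(specimen(marks=marks))
            assert attacked <= count
            assert attacked in (0, 1)


def _cohort(n, attacked_n, **kw):
    out = []
    for i in range(n):
        marks = [bird_mark()] if i < attacked_n else []
        out.append(specimen(id=f"X{i}-{kw.get('category','p')}", marks=marks, **kw))
    return out


class TestSiteAttackRate:
    def test_ring_specimen_proportion(self):
        # 286 attacked among 644 mimicry-ring specimens
        records = _cohort(644, 286, category="model", ring="Danaus")
        summary = site_attack_rate(records)
        assert summary.rate == pytest.approx(286 / 644, abs=1e-12)

    def test_palatable_proportion(self):
        # 537 attacked among 1021 palatable specimens
        records = _cohort(1021, 537)
        assert site_attack_rate(records).rate == pytest.approx(537 / 1021, abs=1e-12)

    def test_wilson_interval_at_zero_rate(self):
        records = _cohort(10, 0)
        summary = site_attack_rate(records)
        assert summary.rate == 0.0
        lo, hi = summary.ci95
        # Wilson oracle: upper bound z^2 / (n + z^2) at x = 0
        z = 1.959963984540054
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi == pytest.approx(z**2 / (10 + z**2), abs=1e-9)

    def test_order_and_duplication_invariance(self):
        records = _cohort(20, 7)
        r1 = site_attack_rate(records).rate
        r2 = site_attack_rate(records[::-1]).rate
        r3 = site_attack_rate(dedupe_records(records + records)).rate
        assert r1 == r2 == r3

    def test_empty_filter_raises(self):
        with pytest.raises(NoDataError):
            site_attack_rate(_cohort(5, 1), predicate=lambda r: r.ring == "Delias")


class TestBackgroundPredationPressure:
    def test_restricted_to_large_palatable(self):
        qualifying = _cohort(80, 40, wingspan=70.0)
        small = _cohort(50, 50, wingspan=45.0)  # under the 50 mm cutoff
        toxic = _cohort(30, 30, category="model", ring="Euploea")
        summary = background_predation_pressure(qualifying + small + toxic)
        assert summary.n_inspected == 80
        assert summary.rate == pytest.approx(0.5)
        assert 0.3 <= summary.rate <= 0.8  # observed field range

    def test_no_qualifying_specimens(self):
        with pytest.raises(NoDataError):
            background_predation_pressure(_cohort(5, 2, wingspan=40.0))


class TestCompareIndices:
    def _site_records(self, rates):
        records = []
        for i, rate in enumerate(rates):
            records += [
                specimen(id=f"s{i}-{j}", site=f"S{i}", marks=[bird_mark()] if j < rate * 20 else [])
                for j in range(20)
            ]
        return records

    def test_identical_indices_r2_one(self):
        rep = compare_indices(self._site_records([0.1, 0.3, 0.5, 0.7]))
        assert rep["r2"] == pytest.approx(1.0)
        assert rep["p"] < 0.01

    def test_constant_binary_index_r2_zero(self):
        records = []
        for i in range(4):
            for j in range(10):
                # everyone attacked; count varies by site
                marks = [bird_mark()] * (1 + (i + j) % 3)
                records.append(specimen(id=f"c{i}-{j}", site=f"S{i}", marks=marks))
        assert compare_indices(records)["r2"] == 0.0

    def test_too_few_sites_raises(self):
        with pytest.raises(NoDataError):
            compare_indices(self._site_records([0.5, 0.5]))

    def test_simulated_survey_indices_agree(self):
        from aposignal import SimConfig, gen_survey

        records, *_ = gen_survey(SimConfig(seed=9))
        assert compare_indices(records)["r2"] > 0.8


class TestAgeIndependence:
    def test_age_strata_share_attack_rate(self):
        from aposignal import SimConfig, gen_survey

        records, *_ = gen_survey(
            SimConfig(seed=5, palatable_specimens_per_site=400, n_sites=6)
        )
        pal = [r for r in records if r.category == "palatable_nonmimic"]
        young = [r for r in pal if r.age_class <= 2]
        old = [r for r in pal if r.age_class >= 4]
        ry = site_attack_rate(young).rate
        ro = site_attack_rate(old).rate
        se = np.sqrt(ry * (1 - ry) / len(young) + ro * (1 - ro) / len(old))
        assert abs(ry - ro) < 4 * se


class TestMarksTableRoundTrip:
    def test_round_trip_and_dedup(self, tmp_path):
        records = [
            specimen(id="A", marks=[bird_mark(8.0, symmetric=True), DamageMark(1.0)]),
            specimen(id="B"),
            specimen(id="C", category="mimic", ring="Tirumala", marks=[DamageMark(3.5)]),
        ]
        p = tmp_path / "marks.csv"
        write_marks_table(records, p)
        back = read_marks_table(p)
        assert [r.id for r in back] == ["A", "B", "C"]
        assert back[0].marks[0].symmetric
        assert len(back[1].marks) == 0
        assert score_specimen(back[2]) == (1, 1)
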