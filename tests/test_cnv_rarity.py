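"""Rarity-filter tests, including an independent brute-force re-evaluation
of all four criteria (the oracle never calls the module under test)."""

import dataclasses

import pytest

from rarecnv.cnv_rarity import (
    CommonCnvRecord,
    RareFilterParams,
    apply_rare_filter,
    evaluate_call,
    is_common_vs_database,
    reciprocal_overlap_ge,
    seen_in_controls,
)
from rarecnv.genome_model import CnvCall, GenomicInterval
from rarecnv.synthetic_data import SimConfig, gen_cnv_callset, gen_genome


# --- independent oracle ----------------------------------------------------

def oracle_reasons(call, db, cohorts, params):
    """Brute-force re-evaluation of the four criteria with per-base sets."""
    reasons = set()
    if (call.interval.end - call.interval.start) / 1000.0 <= params.min_size_kb:
        reasons.add("fails_size")
    if call.n_markers < params.min_markers:
        reasons.add("fails_markers")
    covered = set()
    span = set(range(call.interval.start, call.interval.end))
    for rec in db:
        if rec.dosage != call.dosage or rec.frequency < params.max_common_frequency:
            continue
        if rec.interval.chrom != call.interval.chrom:
            continue
        covered |= span & set(range(rec.interval.start, rec.interval.end))
    if span and len(covered) / len(span) >= params.max_common_coverage:
        reasons.add("common_in_database")
    for cohort in cohorts:
        for ctrl in cohort:
            if ctrl.dosage != call.dosage:
                continue
            if ctrl.interval.chrom != call.interval.chrom:
                continue
            ov = len(span & set(range(ctrl.interval.start, ctrl.interval.end)))
            if ov >= params.reciprocal_overlap * len(span) and ov >= (
                params.reciprocal_overlap
                * (ctrl.interval.end - ctrl.interval.start)
            ):
                reasons.add("seen_in_controls")
    return reasons


def small_call(chrom="1", start=1000, end=3000, cn=1, nm=100, sample="P1"):
    return CnvCall(
        interval=GenomicInterval(chrom, start, end),
        copy_number=cn,
        sample_id=sample,
        n_markers=nm,
    )


PARAMS_SMALL = RareFilterParams(min_size_kb=1.0, min_markers=25)


class TestDatabaseCriterion:
    def test_no_matching_dosage_records(self, call_factory):
        call = call_factory(cn=1)
        db = [
            CommonCnvRecord(
                interval=call.interval, dosage="gain", frequency=0.05
            )
        ]
        assert not is_common_vs_database(call, db)

    def test_heavily_covered_by_common_gain(self, call_factory):
        call = call_factory(cn=3, start=100_000, end=200_000)
        rec = CommonCnvRecord(
            interval=GenomicInterval("1", 100_000, 180_000),
            dosage="gain",
            frequency=0.05,
        )
        assert is_common_vs_database(call, [rec])  # 0.80 >= 0.50

    def test_low_frequency_records_cannot_make_common(self, call_factory):
        call = call_factory(cn=3, start=100_000, end=200_000)
        rec = CommonCnvRecord(
            interval=GenomicInterval("1", 100_000, 180_000),
            dosage="gain",
            frequency=0.0001,
        )
        assert not is_common_vs_database(call, [rec])

    def test_boundary_exactly_half_is_common(self, call_factory):
        call = call_factory(cn=1, start=100_000, end=200_000)
        rec = CommonCnvRecord(
            interval=GenomicInterval("1", 100_000, 150_000),
            dosage="loss",
            frequency=0.01,
        )
        assert is_common_vs_database(call, [rec])

    def test_frequency_exactly_one_permille_counts(self, call_factory):
        call = call_factory(cn=1)
        rec = CommonCnvRecord(
            interval=call.interval, dosage="loss", frequency=0.001
        )
        assert is_common_vs_database(call, [rec])


class TestControlCriterion:
    def test_empty_cohorts(self, call_factory):
        assert not seen_in_controls(call_factory(), [])

    def test_identical_call_in_controls(self, call_factory):
        call = call_factory(cn=1)
        ctrl = call_factory(cn=1, sample="CTRL")
        assert seen_in_controls(call, [[ctrl]])

    def test_nested_in_much_larger_control(self, call_factory):
        call = call_factory(cn=1, start=100_000, end=200_000)
        big = call_factory(cn=1, start=0, end=1_000_000, sample="CTRL")
        assert not seen_in_controls(call, [[big]])  # fails control->query side

    def test_dosage_mismatch_ignored(self, call_factory):
        call = call_factory(cn=1)
        ctrl = call_factory(cn=3, sample="CTRL")
        assert not seen_in_controls(call, [[ctrl]])

    def test_reciprocal_overlap_threshold(self):
        a = GenomicInterval("1", 0, 100)
        b = GenomicInterval("1", 50, 150)
        assert reciprocal_overlap_ge(a, b, 0.5)
        assert not reciprocal_overlap_ge(a, b, 0.51)


class TestApplyFilter:
    def test_small_call_fails_size(self, call_factory):
        call = call_factory(start=100_000, end=145_000)  # 45 kb
        (decision,) = apply_rare_filter([call])
        assert not decision.rare
        assert decision.reasons == {"fails_size"}

    def test_boundary_exactly_50kb_fails(self, call_factory):
        (decision,) = apply_rare_filter([call_factory(start=0, end=50_000)])
        assert decision.reasons == {"fails_size"}

    def test_markers_at_exactly_25_passes(self, call_factory):
        (decision,) = apply_rare_filter([call_factory(nm=25)])
        assert decision.rare
        (decision,) = apply_rare_filter([call_factory(nm=24)])
        assert decision.reasons == {"fails_markers"}

    def test_fixture_calls_all_rare_with_empty_references(self, result_table,
                                                          toy_grid):
        calls = [
            dataclasses.replace(r.call, n_markers=100) for r in result_table
        ]
        decisions = apply_rare_filter(calls, db=[], cohorts=[])
        assert all(d.rare for d in decisions)
        assert len(decisions) == 19

    def test_missing_marker_count_without_grid_errors(self, call_factory):
        call = call_factory(nm=None)
        with pytest.raises(ValueError, match="marker"):
            apply_rare_filter([call])

    def test_grid_fallback_when_call_lacks_markers(self, call_factory, toy_grid):
        call = call_factory(nm=None, start=100_000, end=200_000)  # 100 probes
        (decision,) = apply_rare_filter([call], grid=toy_grid)
        assert decision.rare

    def test_stable_input_order(self, call_factory):
        calls = [call_factory(start=s, end=s + 60_000, sample=f"P{s}")
                 for s in (500_000, 100_000, 300_000)]
        decisions = apply_rare_filter(calls)
        assert [d.call for d in decisions] == calls


class TestOracleEquivalence:
    def test_synthetic_labels_recovered(self):
        cfg = SimConfig(
            seed=11,
            spike_in_rare_cnvs=[
                (GenomicInterval("1", 2_000_000, 2_300_000), 1, "S01"),
                (GenomicInterval("2", 5_000_000, 5_200_000), 3, "S02"),
            ],
            n_decoys_per_kind=2,
        )
        grid, _ = gen_genome(cfg)
        bundle = gen_cnv_callset(cfg, grid)
        decisions = apply_rare_filter(
            bundle.calls, bundle.common_db, bundle.control_cohorts, grid
        )
        by_call = {id(d.call): d for d in decisions}
        for truth in bundle.truth:
            d = by_call[id(truth.call)]
            if truth.label == "rare":
                assert d.rare, f"spike-in rejected: {d.reasons}"
            else:
                assert d.reasons == {truth.label}

    def test_equals_brute_force_on_random_cases(self):
        import numpy as np

        rng = np.random.default_rng(5)
        params = RareFilterParams(min_size_kb=1.0)
        for _ in range(60):
            call = small_call(
                chrom=str(rng.integers(1, 3)),
                start=int(rng.integers(0, 5_000)),
                end=int(rng.integers(5_000, 9_000)),
                cn=int(rng.choice([0, 1, 3, 4])),
                nm=int(rng.integers(0, 60)),
            )
            db = [
                CommonCnvRecord(
                    interval=GenomicInterval(
                        str(rng.integers(1, 3)),
                        int(rng.integers(0, 6_000)),
                        int(rng.integers(6_000, 9_500)),
                    ),
                    dosage=str(rng.choice(["gain", "loss"])),
                    frequency=float(rng.choice([0.0001, 0.001, 0.05])),
                )
                for _ in range(rng.integers(0, 4))
            ]
            cohorts = [
                [
                    small_call(
                        chrom=str(rng.integers(1, 3)),
                        start=int(rng.integers(0, 6_000)),
                        end=int(rng.integers(6_000, 9_500)),
                        cn=int(rng.choice([1, 3])),
                        sample="C",
                    )
                    for _ in range(rng.integers(0, 3))
                ]
            ]
            got = evaluate_call(call, db, cohorts, None, params).reasons
            assert got == oracle_reasons(call, db, cohorts, params)


class TestMonotonicity:
    def _decisions(self, params, db=(), cohorts=()):
        calls = [
            small_call(start=0, end=e, nm=nm, cn=1, sample=f"P{i}")
            for i, (e, nm) in enumerate(
                [(60_000, 30), (45_000, 40), (200_000, 20), (90_000, 26)]
            )
        ]
        return calls, apply_rare_filter(calls, list(db), list(cohorts),
                                        None, params)

    def test_raising_size_threshold_shrinks_rare_set(self):
        _, loose = self._decisions(RareFilterParams(min_size_kb=40))
        _, tight = self._decisions(RareFilterParams(min_size_kb=80))
        assert sum(d.rare for d in tight) <= sum(d.rare for d in loose)
        for dl, dt in zip(loose, tight):
            assert not (dt.rare and not dl.rare)

    def test_raising_marker_threshold_shrinks_rare_set(self):
        _, loose = self._decisions(RareFilterParams(min_markers=10))
        _, tight = self._decisions(RareFilterParams(min_markers=35))
        for dl, dt in zip(loose, tight):
            assert not (dt.rare and not dl.rare)

    def test_enlarging_database_shrinks_rare_set(self):
        rec = CommonCnvRecord(
            interval=GenomicInterval("1", 0, 300_000),
            dosage="loss",
            frequency=0.05,
        )
        _, before = self._decisions(RareFilterParams())
        _, after = self._decisions(RareFilterParams(), db=[rec])
        for db_, da in zip(before, after):
            assert not (da.rare and not db_.rare)

    def test_enlarging_cohorts_shrinks_rare_set(self):
        ctrl = small_call(start=0, end=60_000, cn=1, sample="CTRL")
        _, before = self._decisions(RareFilterParams())
        _, after = self._decisions(RareFilterParams(), cohorts=[[ctrl]])
        for db_, da in zip(before, after):
            assert not (da.rare and not db_.rare)


def test_reason_codes_subset_and_exhaustive(call_factory):
    calls = [call_factory(start=0, end=e, nm=nm, cn=1, sample=str(i))
             for i, (e, nm) in enumerate([(10_000, 5), (60_000, 50)])]
    decisions = apply_rare_filter(calls)
    assert len(decisions) == len(calls)
    for d in decisions:
        assert d.reasons <= {
            "fails_size", "fails_markers", "common_in_database",
            "seen_in_controls",
        }
        assert d.rare == (not d.reasons)
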