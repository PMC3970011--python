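import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promvar.group_stats import (
    angular_transform,
    compare_proportions,
    content_histogram,
    match_group,
    read_sweep_table,
    run_case_matrix,
    threshold_sweep,
    write_sweep_table,
)
from promvar.io_formats import read_gene_sets, read_snp_table, read_transcript_table
from promvar.snp_content import build_content_table, filter_snps
from promvar.synthetic_data import FIXTURE_MANIFEST, SimulationSpec, simulate_dataset
from promvar.transcript_catalog import CaseSpec, DEFAULT_CASES, filter_transcripts

from conftest import make_tx, snp_table_at


def table_with_contents(contents, case=CaseSpec("TSS", 500, "any"), prefix="NM"):
    recs = [
        make_tx(f"{prefix}_{i:04d}", f"{prefix}G{i}", tx_start=100_000 + 10_000 * i,
                tx_end=102_000 + 10_000 * i)
        for i in range(len(contents))
    ]
    positions = []
    for rec, c in zip(recs, contents):
        positions.extend(range(rec.tx_start - 500, rec.tx_start - 500 + c))
    table = build_content_table(recs, snp_table_at({"1": positions}), case)
    assert list(table.contents) == list(contents)
    return table


class TestContentHistogram:
    def test_counting(self):
        hist, at_least = content_histogram(table_with_contents([0, 0, 1, 3]))
        assert hist == {0: 2, 1: 1, 3: 1}
        assert at_least == {1: 2, 2: 1, 3: 1}

    def test_empty(self):
        hist, at_least = content_histogram(table_with_contents([]))
        assert hist == {} and at_least == {}

    def test_fixture_histogram(self, fixture_dir):
        records, _ = read_transcript_table(fixture_dir / "tiny_refgene.tsv")
        kept, _ = filter_transcripts(records)
        snps, _ = read_snp_table(fixture_dir / "tiny_snps.tsv")
        table = build_content_table(kept, filter_snps(snps), CaseSpec("TSS", 500, "any"))
        hist, at_least = content_histogram(table)
        # manifest contents: {3, 2, 3, 2, 7, 1, 1, 0, 1}
        assert hist == {0: 1, 1: 3, 2: 2, 3: 2, 7: 1}
        assert at_least[1] == 8 and at_least[6] == 1 and at_least[7] == 1

    def test_conservation(self):
        contents = [0, 1, 1, 2, 5, 9]
        hist, _ = content_histogram(table_with_contents(contents))
        assert sum(hist.values()) == len(contents)


class TestAngularTransform:
    def test_boundaries_and_closed_form(self):
        assert angular_transform(0.0) == 0.0
        assert angular_transform(1.0) == pytest.approx(math.pi, abs=1e-12)
        assert angular_transform(0.25) == pytest.approx(math.pi / 3, abs=1e-12)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            angular_transform(-0.01)
        with pytest.raises(ValueError):
            angular_transform(1.01)

    def test_vectorized(self):
        out = angular_transform(np.array([0.0, 0.25, 1.0]))
        np.testing.assert_allclose(out, [0.0, math.pi / 3, math.pi], atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(p=st.floats(0.0, 1.0))
    def test_range_and_monotonicity(self, p):
        y = angular_transform(p)
        assert 0.0 <= y <= math.pi + 1e-12


class TestCompareProportions:
    def test_equal_proportions_give_null(self):
        res = compare_proportions(30, 100, 3000, 10000)
        assert res.z_stat == 0.0
        assert res.p_value == pytest.approx(0.5)

    def test_frozen_oracle_values(self):
        # closed-form evaluation, frozen:
        # y1 = 2*asin(sqrt(0.1)) = 0.6435011087932844
        # y2 = 2*asin(sqrt(0.05)) = 0.4510268117962624
        # z  = (y1 - y2)/sqrt(1/100 + 1/10000) = 1.9151908367155968
        # one-sided normal tail = 0.027734085327971718
        res = compare_proportions(10, 100, 500, 10000)
        assert res.y1 == pytest.approx(0.6435011087932844, abs=1e-12)
        assert res.y2 == pytest.approx(0.4510268117962624, abs=1e-12)
        assert res.z_stat == pytest.approx(1.9151908367155968, abs=1e-12)
        assert res.p_value == pytest.approx(0.027734085327971718, abs=1e-12)

    def test_zero_counts(self):
        res = compare_proportions(0, 50, 0, 5000)
        assert res.z_stat == 0.0 and res.p_value == pytest.approx(0.5)

    def test_two_sided(self):
        one = compare_proportions(10, 100, 500, 10000)
        two = compare_proportions(10, 100, 500, 10000, "two-sided")
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_pooled_df_mode_more_conservative(self):
        normal = compare_proportions(10, 40, 50, 400)
        pooled = compare_proportions(10, 40, 50, 400, df_mode="pooled")
        assert pooled.p_value > normal.p_value
        assert pooled.z_stat == normal.z_stat

    @pytest.mark.parametrize(
        "args", [(1, 0, 1, 10), (1, 10, 1, 0), (11, 10, 1, 10), (-1, 10, 1, 10)]
    )
    def test_invalid_counts_fatal(self, args):
        with pytest.raises(ValueError):
            compare_proportions(*args)

    @settings(max_examples=100, deadline=None)
    @given(
        x1=st.integers(0, 50),
        n1=st.integers(1, 50),
        x2=st.integers(0, 500),
        n2=st.integers(1, 500),
    )
    def test_swap_negates_z(self, x1, n1, x2, n2):
        x1, x2 = min(x1, n1), min(x2, n2)
        a = compare_proportions(x1, n1, x2, n2)
        b = compare_proportions(x2, n2, x1, n1)
        assert a.z_stat == pytest.approx(-b.z_stat, abs=1e-12)


class TestThresholdSweep:
    def test_group_equals_background(self):
        table = table_with_contents([0, 1, 2, 5, 9])
        sweep = threshold_sweep(table, table, range(1, 21))
        assert all(r.z_stat == 0.0 for r in sweep)
        assert len(sweep) == 20

    def test_boundary_closed_form(self):
        group = table_with_contents([10, 11, 12])
        background = table_with_contents([0, 0, 0, 0])
        res = threshold_sweep(group, background, [1]).at(1)
        assert res.p1 == 1.0 and res.p2 == 0.0
        expected_z = math.pi / math.sqrt(1 / 3 + 1 / 4)
        assert res.z_stat == pytest.approx(expected_z, abs=1e-12)

    def test_monotonic_tail_proportions(self):
        spec = SimulationSpec(n_transcripts=2000, chromosome_length=2_000_000,
                              group_sizes=(("g", 100),), seed=7)
        transcripts, snps, truth = simulate_dataset(spec)
        kept, _ = filter_transcripts(transcripts)
        background = build_content_table(kept, filter_snps(snps), CaseSpec("TSS", 500, "any"))
        group, _ = match_group(truth.group_symbols["g"], background)
        sweep = threshold_sweep(group, background)
        p1 = [r.p1 for r in sweep]
        p2 = [r.p2 for r in sweep]
        assert all(a >= b for a, b in zip(p1, p1[1:]))
        assert all(a >= b for a, b in zip(p2, p2[1:]))
        assert [r.N for r in sweep] == list(range(1, 21))

    def test_case_mismatch_fatal(self):
        a = table_with_contents([1], CaseSpec("TSS", 500, "any"))
        b = table_with_contents([1], CaseSpec("TSS", 1000, "any"))
        with pytest.raises(ValueError, match="CaseSpec mismatch"):
            threshold_sweep(a, b)

    def test_threshold_below_one_fatal(self):
        table = table_with_contents([1])
        with pytest.raises(ValueError):
            threshold_sweep(table, table, [0, 1])

    def test_deterministic(self):
        spec = SimulationSpec(n_transcripts=1000, chromosome_length=1_100_000,
                              group_sizes=(("g", 50),), seed=11)
        frames = []
        for _ in range(2):
            transcripts, snps, truth = simulate_dataset(spec)
            kept, _ = filter_transcripts(transcripts)
            bg = build_content_table(kept, filter_snps(snps), CaseSpec("TSS", 500, "any"))
            group, _ = match_group(truth.group_symbols["g"], bg)
            frames.append(threshold_sweep(group, bg).to_frame())
        assert frames[0].equals(frames[1])


class TestRunCaseMatrix:
    @pytest.fixture()
    def fixture_inputs(self, fixture_dir):
        records, _ = read_transcript_table(fixture_dir / "tiny_refgene.tsv")
        kept, _ = filter_transcripts(records)
        snps, _ = read_snp_table(fixture_dir / "tiny_snps.tsv")
        return kept, filter_snps(snps)

    def test_default_cases_cardinality(self, fixture_inputs):
        kept, snps = fixture_inputs
        # GENG has a zero-length 5'UTR, so the positive-UTR cases warn
        with pytest.warns(UserWarning):
            sweeps = run_case_matrix(kept, snps, {"olf": ["GENA", "GENG", "GENL"]})
        assert len(sweeps) == 6
        labels = {label for _, label in sweeps}
        assert labels == {c.label for c in DEFAULT_CASES}

    def test_unmatched_symbols_warn(self, fixture_inputs):
        kept, snps = fixture_inputs
        with pytest.warns(UserWarning, match="2 symbol"):
            run_case_matrix(
                kept, snps, {"g": ["GENA", "NOPE1", "NOPE2"]},
                cases=[CaseSpec("TSS", 500, "any")],
            )

    def test_hand_audited_entries(self, fixture_inputs):
        """Three entries of the (olf, utr5_ge0_TSS_500) sweep, audited by
        hand from the fixture manifest contents:
        group = {GENA: 3, GENG: 7, GENL: 1}, background has contents
        {3, 2, 3, 2, 7, 1, 1, 0, 1}."""
        kept, snps = fixture_inputs
        sweeps = run_case_matrix(
            kept, snps, {"olf": ["GENA", "GENG", "GENL"]},
            cases=[CaseSpec("TSS", 500, "any")],
        )
        sweep = sweeps[("olf", "utr5_ge0_TSS_500")]
        for N, x1, x2 in [(1, 3, 8), (2, 2, 5), (3, 2, 3)]:
            res = sweep.at(N)
            assert (res.x1, res.n1, res.x2, res.n2) == (x1, 3, x2, 9)
            y1 = 2 * math.asin(math.sqrt(x1 / 3))
            y2 = 2 * math.asin(math.sqrt(x2 / 9))
            z = (y1 - y2) / math.sqrt(1 / 3 + 1 / 9)
            assert res.z_stat == pytest.approx(z, abs=1e-12)
            assert res.p_value == pytest.approx(
                0.5 * math.erfc(z / math.sqrt(2)), abs=1e-12
            )


class TestSerialization:
    def test_round_trip(self, tmp_path):
        group = table_with_contents([2, 7, 1])
        background = table_with_contents([0, 1, 2, 3, 7])
        sweep = threshold_sweep(group, background, range(1, 21), group_name="toy")
        path = tmp_path / "sweep.tsv"
        write_sweep_table(sweep, path)
        again = read_sweep_table(path)
        assert again.case == sweep.case and again.group_name == "toy"
        assert len(again) == 20
        for a, b in zip(again, sweep):
            assert a.N == b.N and a.x1 == b.x1 and a.x2 == b.x2
            assert a.z_stat == pytest.approx(b.z_stat, rel=1e-15)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-15)

    def test_twenty_data_lines(self, tmp_path):
        group = table_with_contents([2, 7, 1])
        sweep = threshold_sweep(group, group, range(1, 21))
        path = tmp_path / "sweep.tsv"
        write_sweep_table(sweep, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 21  # header + 20
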