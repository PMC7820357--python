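"""Detection filters, tract clustering and round trips against truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutacc import callset_io as cio
from mutacc.detect import (
    ConversionTract,
    DetectionError,
    FilterConfig,
    call_mito_mutations,
    call_nuclear_mutations,
    cluster_positions,
    compare_ma_vs_controls,
    detect_all,
    detect_conversion_tracts,
)
from tests.conftest import make_calls


def _records(line_ids, genotype="G1", n_nuc=60, n_mito=30):
    return [
        cio.MALineRecord(
            line_id=lid,
            genotype_id=genotype,
            population_id="P1",
            g=10,
            generation_time_days=10.0,
            n_callable_nuclear=n_nuc,
            n_callable_mito=n_mito,
        )
        for lid in line_ids
    ]


def _alt(ref):
    return "A" if ref != "A" else "C"


class TestNuclearCalling:
    def _setup(self, toy_reference, n_lines=5):
        anc = cio.AncestralState(
            genotype_id="G1",
            het_sites=pd.DataFrame(columns=["contig", "pos", "ref", "alt"]),
        )
        lines = {f"L{i}": cio.empty_calls() for i in range(1, n_lines + 1)}
        records = _records(list(lines))
        return anc, lines, records

    def test_unique_planted_het_called(self, toy_reference):
        anc, lines, records = self._setup(toy_reference)
        ref5 = toy_reference.base("chr1", 5)
        lines["L2"] = make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET)])
        calls = call_nuclear_mutations({"G1": anc}, lines, records, toy_reference)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row.line_id, row.pos, row.alt) == ("L2", 5, _alt(ref5))

    def test_shared_variant_rejected_when_unique_required(self, toy_reference):
        anc, lines, records = self._setup(toy_reference)
        ref9 = toy_reference.base("chr1", 9)
        shared = [("chr1", 9, ref9, _alt(ref9), cio.GT_HET)]
        lines["L1"] = make_calls(shared)
        lines["L3"] = make_calls(shared)
        calls = call_nuclear_mutations({"G1": anc}, lines, records, toy_reference)
        assert len(calls) == 0
        relaxed = FilterConfig(require_unique_to_line=False)
        calls = call_nuclear_mutations(
            {"G1": anc}, lines, records, toy_reference, relaxed
        )
        assert len(calls) == 2

    def test_ancestral_het_site_not_called(self, toy_reference):
        ref5 = toy_reference.base("chr1", 5)
        anc = cio.AncestralState(
            genotype_id="G1",
            het_sites=pd.DataFrame(
                [("chr1", 5, ref5, _alt(ref5))],
                columns=["contig", "pos", "ref", "alt"],
            ),
        )
        lines = {"L1": make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET)])}
        calls = call_nuclear_mutations(
            {"G1": anc}, lines, _records(["L1"]), toy_reference
        )
        assert len(calls) == 0

    def test_depth_and_quality_filters(self, toy_reference):
        anc, lines, records = self._setup(toy_reference, n_lines=1)
        ref5 = toy_reference.base("chr1", 5)
        low_dp = make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET, np.nan, 5, 99.0)])
        lines = {"L1": low_dp}
        assert (
            len(call_nuclear_mutations({"G1": anc}, lines, _records(["L1"]), toy_reference))
            == 0
        )
        low_q = make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET, np.nan, 30, 10.0)])
        lines = {"L1": low_q}
        assert (
            len(call_nuclear_mutations({"G1": anc}, lines, _records(["L1"]), toy_reference))
            == 0
        )

    def test_uncallable_site_excluded(self, toy_reference):
        toy_reference.callable_mask["chr1"][5 - 1] = False
        anc, lines, records = self._setup(toy_reference, n_lines=1)
        ref5 = toy_reference.base("chr1", 5)
        lines = {"L1": make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET)])}
        assert (
            len(call_nuclear_mutations({"G1": anc}, lines, _records(["L1"]), toy_reference))
            == 0
        )

    def test_missing_metadata_raises(self, toy_reference):
        anc, lines, _ = self._setup(toy_reference)
        with pytest.raises(DetectionError, match="absent from metadata"):
            call_nuclear_mutations({"G1": anc}, lines, _records(["L1"]), toy_reference)

    def test_tightening_filters_never_adds_calls(self, small_experiment):
        exp = small_experiment
        base = FilterConfig()
        n_base = len(
            call_nuclear_mutations(
                exp.ancestors, exp.calls, exp.records, exp.reference, base,
                exp.genotype_of_line,
            )
        )
        for tighter in (
            FilterConfig(min_depth=25),
            FilterConfig(min_quality=100.0),
            FilterConfig(max_depth_factor=1.0),
        ):
            n = len(
                call_nuclear_mutations(
                    exp.ancestors, exp.calls, exp.records, exp.reference, tighter,
                    exp.genotype_of_line,
                )
            )
            assert n <= n_base


class TestMitoCalling:
    def test_frequency_floor(self, toy_reference):
        ref = toy_reference.base("mtDNA", 7)
        lines = {
            "L1": make_calls([("mtDNA", 7, ref, _alt(ref), cio.GT_HET, 0.04, 100, 99.0)])
        }
        calls = call_mito_mutations(None, lines, _records(["L1"]), toy_reference)
        assert len(calls) == 0

    def test_fixed_variant_accepted_with_f_one(self, toy_reference):
        ref = toy_reference.base("mtDNA", 7)
        lines = {
            "L1": make_calls([("mtDNA", 7, ref, _alt(ref), cio.GT_HOM_ALT, 1.0, 100, 99.0)])
        }
        calls = call_mito_mutations(None, lines, _records(["L1"]), toy_reference)
        assert len(calls) == 1
        assert calls.iloc[0].f_i == 1.0

    def test_planted_frequencies_recovered(self, toy_reference):
        ref7, ref9 = toy_reference.base("mtDNA", 7), toy_reference.base("mtDNA", 9)
        lines = {
            "L1": make_calls(
                [
                    ("mtDNA", 7, ref7, _alt(ref7), cio.GT_HET, 0.12, 100, 99.0),
                    ("mtDNA", 9, ref9, _alt(ref9), cio.GT_HET, 0.55, 100, 99.0),
                ]
            )
        }
        calls = call_mito_mutations(None, lines, _records(["L1"]), toy_reference)
        assert len(calls) == 2
        assert calls["f_i"].sum() == pytest.approx(0.67)

    def test_ancestral_heteroplasmy_excluded(self, toy_reference):
        ref = toy_reference.base("mtDNA", 7)
        row = [("mtDNA", 7, ref, _alt(ref), cio.GT_HET, 0.5, 100, 99.0)]
        anc = {"G1": make_calls(row)}
        lines = {"L1": make_calls(row)}
        calls = call_mito_mutations(anc, lines, _records(["L1"]), toy_reference)
        assert len(calls) == 0

    def test_frequency_outside_unit_interval_rejected(self, toy_reference):
        ref = toy_reference.base("mtDNA", 7)
        lines = {
            "L1": make_calls([("mtDNA", 7, ref, _alt(ref), cio.GT_HET, 1.5, 100, 99.0)])
        }
        with pytest.raises(DetectionError, match="frequency"):
            call_mito_mutations(None, lines, _records(["L1"]), toy_reference)


def brute_force_single_linkage(positions, max_gap):
    """All-pairs union-find oracle for single-linkage gap clustering."""
    pos = sorted(positions)
    parent = {p: p for p in pos}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in pos:
        for b in pos:
            if a != b and abs(a - b) <= max_gap:
                parent[find(a)] = find(b)
    clusters = {}
    for p in pos:
        clusters.setdefault(find(p), []).append(p)
    return sorted(sorted(c) for c in clusters.values())


class TestTractClustering:
    def test_two_tracts_hand_example(self):
        clusters = cluster_positions([100, 150, 2000], max_gap=1000)
        assert clusters == [[100, 150], [2000]]
        assert sum(len(c) for c in clusters) == 3  # x_g counts sites

    def test_no_loh_sites_empty(self, toy_reference):
        anc = cio.AncestralState(
            genotype_id="G1",
            het_sites=pd.DataFrame(
                [("chr1", 5, toy_reference.base("chr1", 5), _alt(toy_reference.base("chr1", 5)))],
                columns=["contig", "pos", "ref", "alt"],
            ),
        )
        ref5 = toy_reference.base("chr1", 5)
        lines = {"L1": make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HET)])}
        tracts = detect_conversion_tracts(
            {"G1": anc}, lines, _records(["L1"]), toy_reference
        )
        assert tracts == []

    def test_deletion_guard_excludes_half_depth_sites(self, toy_reference):
        ref5 = toy_reference.base("chr1", 5)
        ref9 = toy_reference.base("chr1", 9)
        anc = cio.AncestralState(
            genotype_id="G1",
            het_sites=pd.DataFrame(
                [("chr1", 5, ref5, _alt(ref5)), ("chr1", 9, ref9, _alt(ref9))],
                columns=["contig", "pos", "ref", "alt"],
            ),
        )
        # line mean depth is 40; site 9 at depth 12 < 0.5*40 fails the guard
        lines = {
            "L1": make_calls(
                [
                    ("chr1", 5, ref5, _alt(ref5), cio.GT_HOM_REF, np.nan, 68, 99.0),
                    ("chr1", 9, ref9, _alt(ref9), cio.GT_HOM_REF, np.nan, 12, 99.0),
                ]
            )
        }
        tracts = detect_conversion_tracts(
            {"G1": anc}, lines, _records(["L1"]), toy_reference
        )
        assert [t.positions for t in tracts] == [(5,)]
        assert tracts[0].directions == ("to_ref",)

    def test_direction_to_alt(self, toy_reference):
        ref5 = toy_reference.base("chr1", 5)
        anc = cio.AncestralState(
            genotype_id="G1",
            het_sites=pd.DataFrame(
                [("chr1", 5, ref5, _alt(ref5))], columns=["contig", "pos", "ref", "alt"]
            ),
        )
        lines = {"L1": make_calls([("chr1", 5, ref5, _alt(ref5), cio.GT_HOM_ALT)])}
        tracts = detect_conversion_tracts(
            {"G1": anc}, lines, _records(["L1"]), toy_reference
        )
        assert tracts[0].directions == ("to_alt",)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(1, 1_000_000), unique=True, min_size=1, max_size=100),
        st.integers(1, 100_000),
    )
    def test_clustering_matches_brute_force_oracle(self, positions, max_gap):
        assert cluster_positions(positions, max_gap) == brute_force_single_linkage(
            positions, max_gap
        )

    def test_tract_invariants(self):
        t = ConversionTract("L1", "chr1", (10, 20, 35), ("to_ref",) * 3)
        assert t.n_sites == 3 and t.span == 26
        with pytest.raises(DetectionError):
            ConversionTract("L1", "chr1", (20, 10), ("to_ref", "to_ref"))


class TestZeroNoiseRoundTrip:
    def test_detection_recovers_truth_exactly(self, small_experiment):
        exp = small_experiment
        filters = FilterConfig(
            min_depth=0, min_quality=0, mito_min_frequency=0, mito_min_alt_reads=0,
            lod_depth_ratio_min=0,
        )
        nuc, mito, tracts = detect_all(
            exp.bundle(), filters=filters, genotype_of_line=exp.genotype_of_line
        )
        truth_nuc = exp.truth.nuclear_mutations.sort_values(
            ["line_id", "contig", "pos"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            nuc[["line_id", "contig", "pos", "ref", "alt"]], truth_nuc
        )
        # conversion tracts coincide with the planted ledger
        got = sorted((t.line_id, t.positions) for t in tracts)
        planted = sorted(
            (t["line_id"], tuple(t["positions"])) for t in exp.truth.conversion_tracts
        )
        assert got == planted
        # every planted heteroplasmy is recovered with its exact frequency
        truth_mito = exp.truth.mito_events.sort_values(
            ["line_id", "pos"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            mito[["line_id", "contig", "pos", "ref", "alt", "f_i"]].rename(
                columns={"f_i": "frequency"}
            ),
            truth_mito,
        )

    def test_detection_is_deterministic(self, small_experiment):
        exp = small_experiment
        a = detect_all(exp.bundle(), genotype_of_line=exp.genotype_of_line)
        b = detect_all(exp.bundle(), genotype_of_line=exp.genotype_of_line)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert [(t.line_id, t.positions) for t in a[2]] == [
            (t.line_id, t.positions) for t in b[2]
        ]


class TestControls:
    def test_ratio_arithmetic(self):
        table = pd.DataFrame(
            {
                "role": ["MA", "extant_control"],
                "events": [6.0, 0.6],
                "exposure": [1e7, 1e7],
            }
        )
        assert compare_ma_vs_controls(table) == pytest.approx(10.0)

    def test_equal_rates_give_one(self):
        table = pd.DataFrame(
            {"role": ["MA", "starting_control"], "events": [2.0, 2.0], "exposure": [1e7, 1e7]}
        )
        assert compare_ma_vs_controls(table) == pytest.approx(1.0)

    def test_zero_control_rate_flagged_infinite(self):
        table = pd.DataFrame(
            {"role": ["MA", "extant_control"], "events": [2.0, 0.0], "exposure": [1e7, 1e7]}
        )
        with pytest.warns(UserWarning, match="control rate is zero"):
            assert np.isinf(compare_ma_vs_controls(table))

    def test_missing_role_rejected(self):
        table = pd.DataFrame({"role": ["MA"], "events": [1.0], "exposure": [1e7]})
        with pytest.raises(DetectionError, match="control"):
            compare_ma_vs_controls(table)

    def test_simulated_controls_tenfold_lower_conversion(self):
        # two simulations differing only in conversion rate by 10x
        from mutacc.simulate import SimulationConfig, simulate_ma_experiment
        from mutacc.detect import tract_site_counts

        def run(mu_gc, seed):
            cfg = SimulationConfig(
                n_genotypes=1,
                lines_per_genotype=30,
                nuclear_length=100_000,
                ancestral_het_density=0.01,
                true_mu_bs=0.0,
                true_mu_gc=mu_gc,
                mito_mu=0.0,
                tract_length_mean=100,
                seed=seed,
            )
            exp = simulate_ma_experiment(cfg)
            tracts = detect_all(exp.bundle(), genotype_of_line=exp.genotype_of_line)[2]
            events = tract_site_counts(tracts).sum()
            expo = sum(
                r.g * exp.ancestors[r.genotype_id].n_het for r in exp.records
            )
            return events, expo

        ma_e, ma_x = run(2e-4, seed=11)
        ctrl_e, ctrl_x = run(2e-5, seed=12)
        table = pd.DataFrame(
            {
                "role": ["MA", "extant_control"],
                "events": [float(ma_e), float(ctrl_e)],
                "exposure": [float(ma_x), float(ctrl_x)],
            }
        )
        ratio = compare_ma_vs_controls(table)
        # sampling error: ~900 and ~90 expected events
        assert 6 < ratio < 16
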