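"""Read assignment, UMB deduplication (with brute-force oracle), coverage
reporting, QC comparison and the desk-scale pileup caller."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smmipkit as sk
from smmipkit.panel import PanelError
from smmipkit.reads import (SampleMetrics, assign_read_list, coverage_report,
                            deduplicate, qc_compare, sample_metrics)
from smmipkit.simulate import revcomp

from conftest import make_assignment


@pytest.fixture(scope="module")
def sim_run(small_panel, small_reference):
    # error-free so the manifest round-trip is exact
    cfg = sk.SimConfig(seed=7, n_genes=2, exons_per_gene=3, exon_len=150,
                       n_samples=1, depth=50, seq_error_rate=0.0)
    return sk.simulate_cohort(small_panel, small_reference, cfg)


class TestAssignment:
    def test_simulator_round_trip_recovers_probe_and_umb(self, sim_run, small_panel):
        pairs = sim_run["reads"]["S00"]
        assignments, qc = assign_read_list(pairs, small_panel)
        assert qc["on_target_fraction"] == 1.0  # no off-target simulated
        assert qc["assigned"] + qc["unassigned"] == qc["total_pairs"]
        by_read = {a.read_id: a for a in assignments}
        mols = {(m["probe_id"], m["mol_id"]): m["umb"]
                for m in sim_run["manifest"]["samples"]["S00"]["molecules"]}
        for a in assignments:
            _, _, probe_id, mol_id, _ = a.read_id.split(":")
            assert a.probe_id == probe_id
            assert a.umb == mols[(probe_id, int(mol_id))]

    def test_two_arm_mismatches_rejected_at_tolerance_one(self, small_panel):
        probe = small_panel.probes[0]
        insert = "A" * 110
        ext = list(probe.ext_arm)
        ext[0] = "A" if ext[0] != "A" else "C"
        ext[5] = "A" if ext[5] != "A" else "C"
        r1 = "".join(ext) + insert
        r2 = "ACGTA" + probe.lig_arm + revcomp(insert)
        got, _ = assign_read_list([("r1", r1, r2)], small_panel, max_arm_mismatch=1)
        assert got == []
        got, _ = assign_read_list([("r1", r1, r2)], small_panel, max_arm_mismatch=2)
        assert [a.probe_id for a in got] == [probe.probe_id]

    def test_read_shorter_than_arm_plus_tag_unassigned(self, small_panel):
        got, qc = assign_read_list([("r1", "ACG", "AC")], small_panel)
        assert got == [] and qc["unassigned"] == 1

    def test_fastq_files_round_trip(self, small_panel, small_reference, small_cfg,
                                    tmp_path):
        sim = sk.simulate_cohort(small_panel, small_reference, small_cfg,
                                 out_dir=tmp_path)
        r1, r2 = sim["paths"]["S00"]
        assignments, qc = sk.assign_reads(r1, r2, small_panel)
        assert qc["assigned"] == len(sim["reads"]["S00"])

    def test_truncated_pair_raises(self, tmp_path):
        (tmp_path / "a_R1.fastq").write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIIII\n")
        (tmp_path / "a_R2.fastq").write_text("@r1\nACGT\n+\nIIII\n")
        panel = sk.Panel([sk.Probe(probe_id="p", gene="G",
                                   target=sk.GenomicInterval("c", 0, 110),
                                   ext_arm="ACGT", lig_arm="ACGT")])
        with pytest.raises(PanelError, match="truncated"):
            sk.assign_reads(tmp_path / "a_R1.fastq", tmp_path / "a_R2.fastq", panel)


class TestSamIntake:
    def test_tag_recovered_from_read_name_and_probe_by_overlap(self, small_panel,
                                                               tmp_path):
        probe = small_panel.probes[0]
        t = probe.target
        sam = tmp_path / "toy.sam"
        sam.write_text(
            f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{t.chrom}\tLN:10000\n"
            f"readA#ACGTA\t0\t{t.chrom}\t{t.start + 1}\t60\t110M\t*\t0\t0\t"
            f"{'A' * 110}\t{'I' * 110}\n"
            f"readB\t4\t*\t0\t0\t*\t*\t0\t0\tAC\tII\n")
        from smmipkit.reads import assignments_from_sam
        assignments, qc = assignments_from_sam(sam, small_panel)
        assert qc == {"assigned": 1, "unassigned": 1}
        a = assignments[0]
        assert (a.read_id, a.probe_id, a.umb) == ("readA", probe.probe_id, "ACGTA")


class TestDeduplicate:
    def test_same_probe_and_umb_collapse_to_one(self):
        assignments = [make_assignment("p1", "AAAAA", read_id=f"r{i}") for i in range(3)]
        kept, report = deduplicate(assignments, seed=0)
        assert len(kept) == 1
        assert report.per_probe["p1"] == {"raw_reads": 3, "dedup_reads": 1,
                                          "duplicate_fraction": pytest.approx(2 / 3)}

    def test_tag_space_ceiling_never_exceeded(self):
        # 2000 reads spanning all 1024 five-base tags saturate at exactly 1024
        umbs = ["".join(t) for t in itertools.product("ACGT", repeat=5)]
        assignments = [make_assignment("p1", umbs[i % 1024], read_id=f"r{i}")
                       for i in range(2000)]
        kept, report = deduplicate(assignments, seed=1, umb_len=5)
        assert report.per_probe["p1"]["dedup_reads"] == 1024 == len(kept)

    def test_ambiguous_umbs_excluded(self):
        assignments = [make_assignment("p1", "AANAA", read_id="r0"),
                       make_assignment("p1", "AAAAA", read_id="r1")]
        kept, report = deduplicate(assignments, seed=0)
        assert len(kept) == 1 and report.ambiguous_umb_reads == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        assignments = [make_assignment(f"p{rng.integers(3)}",
                                       "".join(rng.choice(list("ACGT"), 5)),
                                       read_id=f"r{i}") for i in range(200)]
        kept1, rep1 = deduplicate(assignments, seed=9)
        kept2, rep2 = deduplicate(list(assignments), seed=9)
        assert [a.read_id for a in kept1] == [a.read_id for a in kept2]
        assert rep1.per_probe == rep2.per_probe

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["p1", "p2"]),
                              st.text(alphabet="ACGT", min_size=2, max_size=2)),
                    max_size=100),
           st.integers(min_value=0, max_value=10))
    def test_matches_brute_force_group_by(self, reads, seed):
        """On <=100 reads, dedup equals group-by-(probe,UMB)-pick-one."""
        assignments = [make_assignment(p, u, read_id=f"r{i}")
                       for i, (p, u) in enumerate(reads)]
        kept, report = deduplicate(assignments, seed=seed)
        brute = {}
        for a in assignments:
            brute.setdefault((a.probe_id, a.umb), []).append(a.read_id)
        assert len(kept) == len(brute) == report.total_dedup
        for a in kept:
            assert a.read_id in brute[(a.probe_id, a.umb)]

    def test_distinct_molecule_recovery_tracks_birthday_bound(self):
        """500 simulated molecules at mean PCR duplication 4x recover the
        closed-form expected distinct-tag count 4^5 (1-(1-1/4^5)^500)."""
        u = 4 ** 5
        expected_distinct = u * (1 - (1 - 1 / u) ** 500)
        rng = np.random.default_rng(11)
        observed = []
        for seed in range(5):
            umbs = rng.integers(0, u, size=500)
            assignments = []
            i = 0
            for mol, code in enumerate(umbs):
                umb = "".join("ACGT"[(code >> (2 * k)) & 3] for k in range(5))
                for _ in range(rng.geometric(1 / 4.0)):
                    assignments.append(make_assignment("p1", umb, read_id=f"r{i}"))
                    i += 1
            _, report = deduplicate(assignments, seed=seed)
            observed.append(report.per_probe["p1"]["dedup_reads"])
        assert abs(np.mean(observed) - expected_distinct) <= 3 * np.sqrt(500)


class TestCoverageReport:
    def test_strictly_below_threshold_counted(self, small_panel):
        report = sk.DedupReport()
        counts = {small_panel.probe_ids[0]: 10, small_panel.probe_ids[1]: 30,
                  small_panel.probe_ids[2]: 50}
        for pid, d in counts.items():
            report.per_probe[pid] = {"raw_reads": d, "dedup_reads": d,
                                     "duplicate_fraction": 0.0}
        df, summary = coverage_report(report, small_panel)
        assert summary["n_probes_below"] == 1 + (len(small_panel) - 3)  # zero-filled
        assert len(df) == len(small_panel)  # one row per panel probe

    def test_all_zero_panel(self, small_panel):
        df, summary = coverage_report(sk.DedupReport(), small_panel)
        assert summary["mean_dedup"] == summary["median_dedup"] == 0.0
        assert summary["n_probes_below"] == len(small_panel)

    def test_uniform_simulation_recovers_depth(self, small_panel, small_reference):
        cfg = sk.SimConfig(seed=21, n_genes=2, exons_per_gene=3, exon_len=150,
                           n_samples=1, depth=200, capture_sigma=0.0)
        sim = sk.simulate_coverage_counts(small_panel, small_reference, cfg)
        mean = sim["coverage"]["S00"]["dedup"].mean()
        assert abs(mean - 200) / 200 < 0.10


class TestQcCompare:
    def _metrics(self, cov=258.0, dup=38.0, ids=("p1",)):
        return SampleMetrics(on_target_pct=96.9, duplicate_pct=dup,
                             mean_coverage=cov, probe_ids=frozenset(ids))

    def test_identical_reports_zero_drop(self):
        df = qc_compare(self._metrics(), self._metrics())
        assert (df["pct_drop"] == 0).all()

    def test_blood_vs_dbs_style_coverage_drop(self):
        # 258x whole blood vs 160x dried blood spot: 38% coverage drop
        df = qc_compare(self._metrics(cov=258.0), self._metrics(cov=160.0))
        drop = df.set_index("metric").loc["mean_coverage", "pct_drop"]
        assert drop == pytest.approx(38.0, abs=0.1)

    def test_lower_input_raises_duplicate_fraction(self, small_panel, small_reference):
        """With a fixed read budget, fewer input molecules -> higher duplicate
        fraction (the DBS-versus-blood pattern)."""
        results = {}
        for name, depth in (("blood", 200), ("dbs", 40)):
            cfg = sk.SimConfig(seed=31, n_genes=2, exons_per_gene=3, exon_len=150,
                               n_samples=1, depth=depth, pcr_dup_mean=1.0 + 320 / depth)
            sim = sk.simulate_coverage_counts(small_panel, small_reference, cfg)
            cov = sim["coverage"]["S00"]
            results[name] = 1 - cov["dedup"].sum() / cov["raw"].sum()
        assert results["dbs"] > results["blood"]

    def test_mismatched_panels_rejected(self):
        with pytest.raises(PanelError):
            qc_compare(self._metrics(ids=("p1",)), self._metrics(ids=("p2",)))


class TestPileupCaller:
    def _run(self, variants, seed=41, error=0.0, depth=200):
        cfg = sk.SimConfig(seed=seed, n_genes=1, exons_per_gene=2, exon_len=150,
                           n_samples=1, depth=depth, seq_error_rate=error,
                           capture_sigma=0.0, variants=variants)
        ref = sk.make_reference(cfg)
        panel = sk.design_panel(ref)
        sim = sk.simulate_cohort(panel, ref, cfg)
        assignments, _ = assign_read_list(sim["reads"]["S00"], panel)
        kept, _ = deduplicate(assignments, seed=seed)
        return sk.call_pileup_snvs(kept, panel, ref), ref

    def test_hom_snv_called_hom_with_full_alt_fraction(self):
        calls, ref = self._run([sk.VariantSpec(sample="S00", kind="snv",
                                               gene="GENE1", zygosity="hom",
                                               exon_index=0, offset=60)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.genotype, c.alt_fraction) == ("hom", 1.0)
        assert c.pos == ref.models[0].exons[0].start + 60

    def test_het_snv_alt_fraction_near_half(self):
        calls, _ = self._run([sk.VariantSpec(sample="S00", kind="snv",
                                             gene="GENE1", zygosity="het",
                                             exon_index=1, offset=75)])
        assert len(calls) == 1
        assert calls[0].genotype == "het"
        assert abs(calls[0].alt_fraction - 0.5) < 0.12  # binomial at ~400x

    def test_no_variants_no_errors_gives_zero_calls(self):
        calls, _ = self._run([])
        assert calls == []

    def test_vcf_emission_is_one_based(self, tmp_path):
        calls, _ = self._run([sk.VariantSpec(sample="S00", kind="snv",
                                             gene="GENE1", zygosity="hom",
                                             exon_index=0, offset=10)])
        out = tmp_path / "calls.vcf"
        from smmipkit.reads import write_vcf
        write_vcf(calls, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        assert int(lines[0].split("\t")[1]) == calls[0].pos + 1
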