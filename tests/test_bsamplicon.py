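import re

import numpy as np
import pytest

from methbench.align import PairwiseAlignment
from methbench.bsamplicon import (
    ReadAlignment,
    SiteTable,
    align_read,
    analyze_sample,
    build_site_table,
    classify_reads,
    demultiplex,
    filter_alignment,
    mask_reference,
    project_to_reference,
    read_based_estimate,
    site_based_estimate,
)
from methbench.simulate import (
    SimulationConfig,
    default_mid_table,
    simulate_bisulfite_reads,
)


class TestMaskReference:
    def test_cpg_and_non_cpg_cytosines(self):
        ref = mask_reference("ACGTTCG")
        assert set(ref.c_positions) == {1, 5}
        assert set(ref.informative_sites) == {1, 5}

    def test_no_cytosines(self):
        ref = mask_reference("AGTT")
        assert ref.c_positions == () and ref.informative_sites == ()

    def test_non_cpg_c_is_modifiable_but_not_informative(self):
        ref = mask_reference("ACTTCG")
        assert set(ref.c_positions) == {1, 4}
        assert set(ref.informative_sites) == {4}

    def test_default_reference_has_19_informative_sites(self, reference):
        # independent scan: count CG dinucleotides in the raw sequence
        assert len(reference.informative_sites) == 19
        assert len(re.findall(r"(?=CG)", reference.sequence)) == 19
        assert set(reference.informative_sites) <= set(reference.c_positions)
        for i in reference.informative_sites:
            assert reference.sequence[i : i + 2] == "CG"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            mask_reference("ACGX")
        with pytest.raises(ValueError):
            mask_reference("")


class TestFilter:
    def _aln(self, identity, coverage):
        empty = PairwiseAlignment(1.0, np.empty((0, 2), dtype=np.int64), 0, 0, False)
        return ReadAlignment("r", empty, identity, coverage, False)

    @pytest.mark.parametrize(
        "identity, coverage, ok",
        [(0.95, 0.95, True), (0.90, 0.99, False), (0.99, 0.50, False),
         (0.99, 0.90, False), (0.91, 0.91, True)],
    )
    def test_strict_thresholds(self, identity, coverage, ok):
        assert filter_alignment(self._aln(identity, coverage)) is ok


class TestProjection:
    def test_ungapped_read_projects_its_bases(self, reference):
        aln = align_read(reference.sequence, reference, read_id="r0")
        calls = project_to_reference([aln], {"r0": reference.sequence}, reference)
        assert calls.shape == (1, len(reference))
        assert (calls[0] == reference.encoded).all()

    def test_insertion_dropped_from_projection(self, reference):
        seq = reference.sequence
        read = seq[:100] + "AA" + seq[100:]
        aln = align_read(read, reference, read_id="r0")
        calls = project_to_reference([aln], {"r0": read}, reference)
        # reference-anchored: the insertion leaves no column, every
        # reference position keeps its original base
        assert calls.shape[1] == len(reference)
        assert (calls[0] == reference.encoded).all()

    def test_deletion_yields_gap_calls(self, reference):
        seq = reference.sequence
        read = seq[:100] + seq[105:]
        aln = align_read(read, reference, read_id="r0")
        calls = project_to_reference([aln], {"r0": read}, reference)
        assert (calls[0] == -1).sum() == 5

    def test_depth_matches_interval_arithmetic(self, reference):
        seq = reference.sequence
        reads = {
            "a": seq,                  # covers [0, 205)
            "b": seq[50:],             # covers [50, 205)
            "c": seq[:150],            # covers [0, 150)
        }
        alns = [align_read(s, reference, read_id=k) for k, s in reads.items()]
        calls = project_to_reference(alns, reads, reference)
        depth = (calls >= 0).sum(axis=0)
        intervals = [(0, 205), (50, 205), (0, 150)]
        for pos in (0, 49, 50, 149, 150, 204):
            expected = sum(lo <= pos < hi for lo, hi in intervals)
            assert depth[pos] == expected


class TestEstimates:
    def test_sbe_mean_of_site_fractions(self):
        table = SiteTable(
            (3, 7), np.array([4, 6]), np.array([6, 4]), np.array([10, 10])
        )
        assert site_based_estimate(table) == pytest.approx(50.0)

    def test_sbe_skips_uncovered_sites(self):
        table = SiteTable(
            (3, 7), np.array([10, 0]), np.array([0, 0]), np.array([10, 0])
        )
        assert site_based_estimate(table) == pytest.approx(100.0)

    def test_sbe_all_uncovered_raises(self):
        table = SiteTable((3,), np.array([0]), np.array([0]), np.array([0]))
        with pytest.raises(ValueError):
            site_based_estimate(table)

    def test_rbe_formula_ignores_indeterminate(self):
        from methbench.bsamplicon import ReadClassification

        classes = (
            [ReadClassification(f"m{i}", 19, 0.0, "methylated") for i in range(3)]
            + [ReadClassification("u0", 19, 1.0, "unmethylated")]
            + [ReadClassification("i0", 19, 0.5, "indeterminate")]
        )
        rbe, fractions = read_based_estimate(classes)
        assert rbe == pytest.approx(75.0)
        assert fractions["indeterminate"] == pytest.approx(0.2)
        with pytest.raises(ValueError):
            read_based_estimate([classes[-1]])

    def test_classification_thresholds(self, reference):
        sites = list(reference.informative_sites)
        calls = np.full((3, len(reference)), -2, dtype=np.int8)
        calls[:, :] = reference.encoded
        # read 0: 10/19 converted (52.6%) -> indeterminate
        calls[0, sites[:10]] = 3
        # read 1: 3/19 converted (15.8%) -> methylated (<= 20%)
        calls[1, sites[:3]] = 3
        # read 2: 16/19 converted (84.2%) -> unmethylated (>= 80%)
        calls[2, sites[:16]] = 3
        labels = [c.label for c in classify_reads(calls, reference, list("abc"))]
        assert labels == ["indeterminate", "methylated", "unmethylated"]

    def test_low_site_coverage_excluded(self, reference):
        calls = np.full((1, len(reference)), -2, dtype=np.int8)
        sites = list(reference.informative_sites)
        calls[0, sites[:5]] = 1  # only 5/19 sites covered
        (cls,) = classify_reads(calls, reference, ["r"])
        assert cls.label == "uncovered"
        with pytest.raises(ValueError):
            read_based_estimate([cls])


class TestDemultiplex:
    def test_exact_prefix_assignment(self):
        table = {"s1": "AAAA", "s2": "CCCC"}
        reads = [("r1", "AAAAGGG"), ("r2", "CCCCGGG"), ("r3", "GGGGAAA")]
        by_sample, unassigned = demultiplex(reads, table)
        assert [r for r, _ in by_sample["s1"]] == ["r1"]
        assert [r for r, _ in by_sample["s2"]] == ["r2"]
        assert [r for r, _ in unassigned] == ["r3"]

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"s1": "AAAA", "s2": "AAAA"})

    def test_simulated_pool_counts_match_truth(self, reference, clean_config):
        mids = default_mid_table(3)
        pool = []
        truth_counts = {}
        for i, (name, tag) in enumerate(mids.items()):
            reads, _ = simulate_bisulfite_reads(
                0.5, reference, clean_config, n_reads=20 + i,
                mid_name=name, mid_tag=tag, seed=i,
            )
            pool.extend(reads)
            truth_counts[name] = len(reads)
        by_sample, unassigned = demultiplex(pool, mids)
        assert {k: len(v) for k, v in by_sample.items()} == truth_counts
        assert unassigned == []


class TestPipelineProperties:
    def test_sbe_rbe_agree_without_chimeras(self, reference):
        config = SimulationConfig(seq_error=0.01, chimera_rate=0.0)
        reads, _ = simulate_bisulfite_reads(
            0.5, reference, config, n_reads=400, seed=5
        )
        s = analyze_sample(reads, reference)
        assert abs(s["sbe"] - s["rbe"]) < 2.0
        assert s["class_fractions"]["indeterminate"] < 0.01

    def test_chimeras_inflate_indeterminate_reads_and_split_estimates(self, reference):
        config = SimulationConfig(seq_error=0.01, chimera_rate=0.3)
        reads, _ = simulate_bisulfite_reads(
            0.25, reference, config, n_reads=800, seed=5
        )
        s = analyze_sample(reads, reference)
        # crossovers between methylated and unmethylated molecules make
        # mixed reads: the indeterminate class swells and the read-based
        # estimate detaches downward from the site-based one (mixed reads
        # leave the M/U tally but the per-site counts are conserved)
        assert s["class_fractions"]["indeterminate"] > 0.05
        assert s["sbe"] - s["rbe"] > 1.0

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_conversion_completeness_at_panel_extremes(self, reference, fraction):
        # 99.5% conversion, 1% sequencing error: under 1% of reads of
        # the fully (un)methylated samples deviate from the expected class
        config = SimulationConfig()
        reads, _ = simulate_bisulfite_reads(
            fraction, reference, config, n_reads=500, seed=11
        )
        s = analyze_sample(reads, reference)
        expected = "methylated" if fraction == 1.0 else "unmethylated"
        mismatched = 1.0 - s["class_fractions"][expected]
        assert mismatched < 0.01

    @pytest.mark.parametrize("fraction", [0.1, 0.5, 0.9])
    def test_estimators_recover_realized_fraction(self, reference, clean_config, fraction):
        reads, truth = simulate_bisulfite_reads(
            fraction, reference, clean_config, n_reads=300, seed=int(fraction * 100)
        )
        s = analyze_sample(reads, reference)
        realized = 100.0 * truth["n_methylated"] / truth["n_reads"]
        # perfect chemistry: both estimators equal the realized mixture
        assert s["rbe"] == pytest.approx(realized, abs=0.5)
        assert s["sbe"] == pytest.approx(realized, abs=0.5)
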