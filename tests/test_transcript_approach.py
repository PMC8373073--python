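"""Coverage-profile construction from alignments and p2pPCC statistics."""

import numpy as np
import pytest

from denoiseq import (
    ExonAnnotation,
    ExonRecord,
    ValidationError,
    bin_by_abundance,
    build_profiles,
    generate_coverage_experiment,
    p2p_correlation,
    transcript_similarity_table,
)
from denoiseq.synthetic import sam_to_indexed_bam
from denoiseq.transcript_approach import TranscriptProfileSet


def write_bam(tmp_path, name, sam_body, references=(("chr1", 1000),)):
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    for rname, length in references:
        header.append(f"@SQ\tSN:{rname}\tLN:{length}")
    sam = tmp_path / f"{name}.sam"
    sam.write_text("\n".join(header + sam_body) + "\n")
    return sam_to_indexed_bam(sam, tmp_path / f"{name}.bam")


def sam_line(qname, rname, pos1, length, flag=0):
    return (
        f"{qname}\t{flag}\t{rname}\t{pos1}\t60\t{length}M\t*\t0\t0\t"
        f"{'A' * length}\t{'I' * length}"
    )


@pytest.fixture
def single_exon_annotation():
    return ExonAnnotation([ExonRecord("chr1", 100, 200, "+", "G1", "T1", 1)])


class TestBuildProfiles:
    def test_single_read_inside_single_exon(self, tmp_path, single_exon_annotation):
        bam = write_bam(tmp_path, "s1", [sam_line("r1", "chr1", 111, 10)])
        profiles = build_profiles({"s1": bam}, single_exon_annotation)
        coverage = profiles.profiles["T1"]["s1"]
        assert coverage.sum() == 10
        assert np.array_equal(np.nonzero(coverage)[0], np.arange(10, 20))
        assert profiles.abundance.loc["T1", "s1"] == 1

    def test_two_identical_reads_are_additive(self, tmp_path, single_exon_annotation):
        bam = write_bam(
            tmp_path, "s1",
            [sam_line("r1", "chr1", 111, 10), sam_line("r2", "chr1", 111, 10)],
        )
        profiles = build_profiles({"s1": bam}, single_exon_annotation)
        assert profiles.profiles["T1"]["s1"].max() == 2
        assert profiles.abundance.loc["T1", "s1"] == 2

    def test_read_spanning_two_exons_covers_both(self, tmp_path):
        annotation = ExonAnnotation(
            [
                ExonRecord("chr1", 100, 110, "+", "G1", "T1", 1),
                ExonRecord("chr1", 150, 160, "+", "G1", "T1", 2),
            ]
        )
        # spliced read: 10M40N10M starting at exon1 start
        body = [
            "r1\t0\tchr1\t101\t60\t10M40N10M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20
        ]
        bam = write_bam(tmp_path, "s1", body)
        profiles = build_profiles({"s1": bam}, annotation)
        coverage = profiles.profiles["T1"]["s1"]
        assert len(coverage) == 20
        assert np.array_equal(coverage, np.ones(20))
        assert profiles.abundance.loc["T1", "s1"] == 1  # one increment per read

    def test_minus_strand_profile_reversed(self, tmp_path):
        annotation = ExonAnnotation(
            [ExonRecord("chr1", 100, 200, "-", "G1", "T1", 1)]
        )
        bam = write_bam(tmp_path, "s1", [sam_line("r1", "chr1", 101, 10)])
        coverage = build_profiles({"s1": bam}, annotation).profiles["T1"]["s1"]
        # read at genomic 5' end -> transcript 3' end after reversal
        assert np.array_equal(np.nonzero(coverage)[0], np.arange(90, 100))

    def test_collapsed_read_names_carry_multiplicity(self, tmp_path,
                                                     single_exon_annotation):
        bam = write_bam(tmp_path, "s1", [sam_line("read1_x7", "chr1", 111, 10)])
        profiles = build_profiles(
            {"s1": bam}, single_exon_annotation, collapsed_names=True
        )
        assert profiles.profiles["T1"]["s1"].max() == 7
        assert profiles.abundance.loc["T1", "s1"] == 7

    def test_secondary_alignments_skipped_by_default(self, tmp_path,
                                                     single_exon_annotation):
        body = [
            sam_line("r1", "chr1", 111, 10),
            sam_line("r1", "chr1", 131, 10, flag=256),
        ]
        bam = write_bam(tmp_path, "s1", body)
        default = build_profiles({"s1": bam}, single_exon_annotation)
        assert default.abundance.loc["T1", "s1"] == 1
        with_secondary = build_profiles(
            {"s1": bam}, single_exon_annotation, include_secondary=True
        )
        assert with_secondary.abundance.loc["T1", "s1"] == 2

    def test_missing_chromosome_is_logged_skip(self, tmp_path, caplog):
        annotation = ExonAnnotation(
            [
                ExonRecord("chr1", 100, 200, "+", "G1", "T1", 1),
                ExonRecord("chrMISSING", 0, 50, "+", "G2", "T2", 1),
            ]
        )
        bam = write_bam(tmp_path, "s1", [sam_line("r1", "chr1", 111, 10)])
        profiles = build_profiles({"s1": bam}, annotation)
        assert profiles.abundance.loc["T2", "s1"] == 0

    def test_missing_index_is_io_error(self, tmp_path, single_exon_annotation):
        bam = write_bam(tmp_path, "s1", [sam_line("r1", "chr1", 111, 10)])
        for idx in tmp_path.glob("*.bai"):
            idx.unlink()
        with pytest.raises(OSError):
            build_profiles({"s1": bam}, single_exon_annotation)

    def test_synthetic_sam_reproduces_ground_truth_pileup(self, tmp_path):
        exp = generate_coverage_experiment(
            n_transcripts=6, transcript_length=200, depths=(5, 50, 500),
            n_samples=2, seed=9,
        )
        bams = exp.to_indexed_bams(tmp_path)
        profiles = build_profiles(bams, exp.annotation())
        for tid in exp.transcript_ids:
            for sample in exp.sample_ids:
                assert np.array_equal(
                    profiles.profiles[tid][sample], exp.truth.profiles[tid][sample]
                )
        assert profiles.abundance.equals(exp.truth.abundance)

    def test_multi_file_sample_sums_coverage(self, tmp_path, single_exon_annotation):
        bam_a = write_bam(tmp_path, "a", [sam_line("r1", "chr1", 111, 10)])
        bam_b = write_bam(tmp_path, "b", [sam_line("r2", "chr1", 111, 10)])
        pooled = build_profiles({"s": [bam_a, bam_b]}, single_exon_annotation)
        assert pooled.profiles["T1"]["s"].max() == 2
        assert pooled.abundance.loc["T1", "s"] == 2

    def test_coverage_mass_equals_abundance_times_read_length(self, tmp_path):
        exp = generate_coverage_experiment(
            n_transcripts=4, transcript_length=150, depths=(20,), n_samples=2,
            seed=1, read_length=30,
        )
        bams = exp.to_indexed_bams(tmp_path)
        profiles = build_profiles(bams, exp.annotation())
        for tid in exp.transcript_ids:
            for sample in exp.sample_ids:
                assert profiles.profiles[tid][sample].sum() == (
                    profiles.abundance.loc[tid, sample] * 30
                )


class TestP2PCorrelation:
    def test_identical_nonconstant_profiles(self):
        p = np.array([0.0, 1, 3, 2, 0])
        assert p2p_correlation(p, p) == pytest.approx(1.0)

    def test_zero_profile_rule(self):
        assert p2p_correlation(np.array([1.0, 2, 3]), np.zeros(3)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            p2p_correlation(np.zeros(3), np.zeros(4))

    def test_depth_improves_correlation(self, rng):
        shape = np.exp(np.sin(np.linspace(0, 3 * np.pi, 200)))
        shape /= shape.sum()

        def mean_corr(depth):
            sims = []
            for _ in range(10):
                a = rng.multinomial(depth, shape).astype(float)
                b = rng.multinomial(depth, shape).astype(float)
                sims.append(p2p_correlation(a, b))
            return np.mean(sims)

        assert mean_corr(5000) > mean_corr(5)


class TestSimilarityTable:
    def make_profiles(self, data):
        samples = sorted({s for per in data.values() for s in per})
        import pandas as pd

        abundance = pd.DataFrame(
            {s: {t: float(data[t][s].sum()) for t in data} for s in samples}
        )
        return TranscriptProfileSet(
            sample_ids=samples,
            profiles={t: {s: v.astype(float) for s, v in per.items()}
                      for t, per in data.items()},
            abundance=abundance.loc[list(data)],
        )

    def test_two_samples_single_pairwise_value(self):
        a = np.array([0.0, 2, 4, 1])
        b = np.array([1.0, 2, 5, 0])
        profiles = self.make_profiles({"T1": {"s1": a, "s2": b}})
        table = transcript_similarity_table(profiles)
        expected = p2p_correlation(a, b)
        assert np.allclose(table["similarity"], expected)

    def test_three_samples_mean_over_pairs(self):
        vecs = {
            "s1": np.array([0.0, 2, 4, 1]),
            "s2": np.array([1.0, 2, 5, 0]),
            "s3": np.array([0.0, 1, 4, 2]),
        }
        profiles = self.make_profiles({"T1": vecs})
        table = transcript_similarity_table(profiles).set_index("sample_id")
        for j in vecs:
            expected = np.mean(
                [p2p_correlation(vecs[j], vecs[k]) for k in vecs if k != j]
            )
            assert table.loc[j, "similarity"] == pytest.approx(expected)

    def test_absent_transcript_gets_zero_similarity(self):
        profiles = self.make_profiles(
            {"T1": {"s1": np.zeros(5), "s2": np.zeros(5)}}
        )
        table = transcript_similarity_table(profiles)
        assert (table["similarity"] == 0).all()

    def test_sample_order_invariance(self, rng):
        data = {
            f"T{i}": {s: rng.poisson(5, size=30).astype(float)
                      for s in ("s1", "s2", "s3")}
            for i in range(4)
        }
        fwd = transcript_similarity_table(self.make_profiles(data))
        reordered = {
            t: {s: per[s] for s in ("s3", "s1", "s2")} for t, per in data.items()
        }
        rev = transcript_similarity_table(self.make_profiles(reordered))
        merged = fwd.merge(
            rev, on=["transcript_id", "sample_id"], suffixes=("_f", "_r")
        )
        assert np.allclose(merged["similarity_f"], merged["similarity_r"])

    def test_single_sample_rejected(self):
        profiles = self.make_profiles({"T1": {"s1": np.ones(4)}})
        with pytest.raises(ValidationError):
            transcript_similarity_table(profiles)


class TestBinByAbundance:
    def test_depth_ladder_monotone_binned_similarity(self, tmp_path):
        exp = generate_coverage_experiment(
            n_transcripts=16, transcript_length=400,
            depths=(5, 50, 500, 5000), n_samples=3, seed=17,
        )
        table = transcript_similarity_table(exp.truth)
        by_depth = table.groupby(
            table["transcript_id"].map(exp.depths)
        )["similarity"].mean()
        values = by_depth.loc[[5, 50, 500, 5000]].to_numpy()
        assert np.all(np.diff(values) > 0)

    def test_per_sample_binning(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "transcript_id": ["T1", "T2", "T1", "T2"],
                "sample_id": ["s1", "s1", "s2", "s2"],
                "abundance": [1.0, 5.0, 2.0, 9.0],
                "similarity": [0.1, 0.8, 0.2, 0.9],
            }
        )
        binned = bin_by_abundance(records)
        assert set(binned) == {"s1", "s2"}
        assert binned["s1"].count.sum() == 2
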