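import numpy as np
import pytest

from poccnv.classify import (
    CnvCall,
    ReportingCriteria,
    classify_specimen,
    detect_loh,
    detect_triploidy,
    detect_whole_chromosome_events,
    estimate_mcc,
)
from poccnv.cnvseq import Segment
from poccnv.errors import InvalidConfigError
from poccnv.genome import GenomeConfig, build_genome
from poccnv.simulate import (
    BafProfile,
    Event,
    KaryotypeSpec,
    simulate_specimen,
    simulate_str_pair,
    whole_chromosome_event,
)


def seg(chrom, start_bin, end_bin, mean, genome=None, bin_size=20_000):
    return Segment(
        chrom=chrom, start_bin=start_bin, end_bin=end_bin, mean_log2=mean,
        n_bins=end_bin - start_bin, start=start_bin * bin_size, end=end_bin * bin_size,
    )


# ---------------------------------------------------------------------------
# MCC estimation
# ---------------------------------------------------------------------------

def test_mcc_indeterminate_when_profiles_identical():
    spec, mat = simulate_str_pair(0.0, rng=1)
    # force fetal genotype == maternal genotype at every marker
    from poccnv.simulate import StrMarker, StrMarkerSet

    identical = StrMarkerSet(
        [StrMarker(m.marker, mat_m.genotype, {a: 1 / len(mat_m.genotype) for a in mat_m.genotype})
         for m, mat_m in zip(spec.markers, mat.markers)]
    )
    assert estimate_mcc(identical, mat) is None


def test_mcc_estimate_accuracy_at_half():
    ests = [estimate_mcc(*simulate_str_pair(0.5, rng=r)) for r in range(50)]
    ests = [e for e in ests if e is not None]
    assert len(ests) >= 45
    assert np.mean(ests) == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize("f,expect_excluded", [(0.35, True), (0.20, False)])
def test_mcc_exclusion_gate(mini_genome, mini_criteria, f, expect_excluded):
    """Contamination above the 30% threshold excludes the specimen from analysis."""
    str_pair = simulate_str_pair(f, rng=7)
    segments = [seg("chr1", 0, 100, 0.0)]
    res = classify_specimen(
        segments, mini_genome, mini_criteria, str_pair=str_pair, specimen_id="s"
    )
    assert res.qc_flags.get("mcc_excluded", False) == expect_excluded
    assert (res.category is None) == expect_excluded


# ---------------------------------------------------------------------------
# whole-chromosome events
# ---------------------------------------------------------------------------

def test_uniform_gain_called_trisomy(mini_genome):
    n16 = mini_genome.chrom_slice("chr16").stop - mini_genome.chrom_slice("chr16").start
    events = detect_whole_chromosome_events([seg("chr16", 0, n16, 0.585)], mini_genome)
    assert len(events) == 1
    e = events[0]
    assert (e.chrom, e.direction, e.constitutional) == ("chr16", "gain", True)
    assert e.mosaic_fraction == pytest.approx(1.0, abs=0.01)


def test_x_loss_in_xx_specimen_is_monosomy_x(mini_genome, mini_criteria):
    nx = mini_genome.chrom_slice("chrX").stop - mini_genome.chrom_slice("chrX").start
    res = classify_specimen([seg("chrX", 0, nx, -1.0)], mini_genome, mini_criteria)
    assert res.category == "monosomy_x"


def test_mosaic_gain_fraction_recovered(mini_genome):
    n21 = mini_genome.chrom_slice("chr21").stop - mini_genome.chrom_slice("chr21").start
    events = detect_whole_chromosome_events([seg("chr21", 0, n21, 0.263)], mini_genome)
    assert len(events) == 1
    assert not events[0].constitutional
    assert events[0].mosaic_fraction == pytest.approx(0.40, abs=0.005)


def test_partial_coverage_not_whole_chromosome(mini_genome):
    """A gain over half a chromosome is not a whole-chromosome event."""
    n1 = mini_genome.chrom_slice("chr1").stop - mini_genome.chrom_slice("chr1").start
    half = n1 // 2
    segs = [seg("chr1", 0, half, 0.585), seg("chr1", half, n1, 0.0)]
    assert detect_whole_chromosome_events(segs, mini_genome) == []


def test_tetrasomy_flagged_and_routed_to_other(mini_genome, mini_criteria):
    n8 = mini_genome.chrom_slice("chr8").stop - mini_genome.chrom_slice("chr8").start
    res = classify_specimen([seg("chr8", 0, n8, 1.0)], mini_genome, mini_criteria)
    assert res.whole_events[0].tetrasomy
    assert res.category == "other"


# ---------------------------------------------------------------------------
# BAF detectors
# ---------------------------------------------------------------------------

def test_triploidy_detected_from_baf(mini_genome):
    _, baf_t = simulate_specimen(mini_genome, KaryotypeSpec(ploidy="triploid"), 100_000, seed=3)
    _, baf_d = simulate_specimen(mini_genome, KaryotypeSpec(), 100_000, seed=4)
    assert detect_triploidy(baf_t)[0] == "triploid"
    assert detect_triploidy(baf_d)[0] == "diploid"


def test_local_mosaic_gain_does_not_trigger_triploidy(mini_genome):
    truth = KaryotypeSpec(events=[whole_chromosome_event(mini_genome, "whole_chrom_gain", "chr2", 0.4)])
    _, baf = simulate_specimen(mini_genome, truth, 100_000, seed=5)
    assert detect_triploidy(baf)[0] == "diploid"


def test_triploidy_indeterminate_with_few_markers():
    baf = BafProfile(
        chrom=np.array(["chr1"] * 50, dtype=object),
        pos=np.arange(50, dtype=np.int64) * 1000,
        baf=np.full(50, 0.5),
        markers_per_mb=1.0,
    )
    assert detect_triploidy(baf) == ("indeterminate", None)


def _baf_with_hom_run(run_start, run_end, chrom_len=20_000_000, spacing=25_000, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.arange(0, chrom_len, spacing, dtype=np.int64)
    baf = np.where(rng.random(pos.size) < 0.4, 0.5, np.where(rng.random(pos.size) < 0.5, 0.02, 0.98))
    in_run = (pos >= run_start) & (pos < run_end)
    baf[in_run] = np.where(rng.random(int(in_run.sum())) < 0.5, 0.02, 0.98)
    return BafProfile(
        chrom=np.array(["chr1"] * pos.size, dtype=object), pos=pos, baf=baf, markers_per_mb=40.0
    )


def test_loh_six_mb_run_reported_four_mb_suppressed():
    criteria = ReportingCriteria()  # full-scale 5 Mb threshold
    hit = detect_loh(_baf_with_hom_run(8_000_000, 14_000_000), criteria)
    assert len(hit) == 1
    chrom, start, end = hit[0]
    assert chrom == "chr1" and end - start >= 5_000_000
    assert start == pytest.approx(8_000_000, abs=200_000)
    miss = detect_loh(_baf_with_hom_run(8_000_000, 12_000_000), criteria)
    assert miss == []


def test_fully_heterozygous_chromosome_has_no_loh():
    pos = np.arange(0, 20_000_000, 25_000, dtype=np.int64)
    baf = BafProfile(
        chrom=np.array(["chr1"] * pos.size, dtype=object), pos=pos,
        baf=np.full(pos.size, 0.5), markers_per_mb=40.0,
    )
    assert detect_loh(baf, ReportingCriteria()) == []


# ---------------------------------------------------------------------------
# classification priority and calls
# ---------------------------------------------------------------------------

def test_trisomy_with_sex_polyploidy_is_autosomal_trisomy(mini_genome, mini_criteria):
    """An autosomal trisomy coexisting with a sex-chromosome gain is reported
    as autosomal trisomy."""
    n16 = mini_genome.chrom_slice("chr16").stop - mini_genome.chrom_slice("chr16").start
    nY = mini_genome.chrom_slice("chrY").stop - mini_genome.chrom_slice("chrY").start
    from poccnv.cnvseq import CopyRatioProfile

    prof = CopyRatioProfile("s", np.zeros(mini_genome.n_bins), np.ones(mini_genome.n_bins, bool), "XY")
    segs = [seg("chr16", 0, n16, 0.585), seg("chrY", 0, nY, 1.0)]
    res = classify_specimen(segs, mini_genome, mini_criteria, profile=prof)
    assert res.category == "autosomal_trisomy"


def test_sex_chromosome_only_gain_is_other(mini_genome, mini_criteria):
    from poccnv.cnvseq import CopyRatioProfile

    nY = mini_genome.chrom_slice("chrY").stop - mini_genome.chrom_slice("chrY").start
    prof = CopyRatioProfile("s", np.zeros(mini_genome.n_bins), np.ones(mini_genome.n_bins, bool), "XY")
    res = classify_specimen([seg("chrY", 0, nY, 1.0)], mini_genome, mini_criteria, profile=prof)
    assert res.category == "other"


def test_single_surviving_dup_is_partial_imbalance(mini_genome, mini_criteria):
    """One 2.5-Mb-equivalent duplication and nothing else."""
    segs = [seg("chr16", 0, 7, 0.585), seg("chr16", 7, 226, 0.0)]
    res = classify_specimen(segs, mini_genome, mini_criteria)
    assert res.category == "partial_imbalance"
    assert len(res.calls) == 1
    call = res.calls[0]
    assert call.type == "dup" and call.cytoband.startswith("16")
    assert call.size >= mini_criteria.min_dup_size


def test_subthreshold_dup_not_reported(mini_genome, mini_criteria):
    """A duplication below the size minimum survives neither as a call nor a category."""
    segs = [seg("chr16", 0, 2, 0.585), seg("chr16", 2, 226, 0.0)]
    res = classify_specimen(segs, mini_genome, mini_criteria)
    assert res.category == "normal" and res.calls == []


def test_no_events_is_normal(mini_genome, mini_criteria):
    res = classify_specimen([seg("chr1", 0, 100, 0.0)], mini_genome, mini_criteria)
    assert res.category == "normal" and res.calls == []


def test_all_calls_respect_criteria_sizes(mini_genome, mini_criteria):
    segs = [
        seg("chr1", 0, 3, 0.585),     # too small for a dup
        seg("chr2", 0, 30, 0.585),    # surviving dup
        seg("chr3", 0, 4, -1.0),      # surviving del (1 Mb / 20 = 50 kb min)
        seg("chr4", 0, 10, 0.263),    # mosaic below mosaic-CNV size minimum
        seg("chr5", 0, 30, 0.263),    # surviving mosaic dup
    ]
    # complete each chromosome's partition with a neutral remainder
    segs += [seg(c, hi, 400, 0.0) for c, hi in
             [("chr1", 3), ("chr2", 30), ("chr3", 4), ("chr4", 10), ("chr5", 30)]]
    res = classify_specimen(segs, mini_genome, mini_criteria)
    assert {c.chrom for c in res.calls} == {"chr2", "chr3", "chr5"}
    for c in res.calls:
        if c.mosaic_fraction >= 0.9:
            floor = mini_criteria.min_dup_size if c.type == "dup" else mini_criteria.min_del_size
        else:
            floor = mini_criteria.min_mosaic_cnv_size
        assert c.size >= floor
        assert c.mosaic_fraction >= mini_criteria.min_mosaic_fraction


def test_cnv_seq_platform_skips_baf_detectors(mini_genome, mini_criteria):
    _, baf = simulate_specimen(mini_genome, KaryotypeSpec(ploidy="triploid"), 100_000, seed=6)
    res = classify_specimen(
        [seg("chr1", 0, 100, 0.0)], mini_genome, mini_criteria, baf=baf, platform="cnv_seq"
    )
    # no allelic channel on CNV-seq: the triploid BAF must be ignored
    assert res.category == "normal" and res.triploidy_margin is None


def test_classification_deterministic(mini_genome, mini_criteria):
    truth = KaryotypeSpec(events=[whole_chromosome_event(mini_genome, "whole_chrom_gain", "chr16")])
    _, baf = simulate_specimen(mini_genome, truth, 100_000, seed=8)
    segs = [seg("chr16", 0, 10, 0.6), seg("chr16", 10, 226, 0.58)]
    a = classify_specimen(segs, mini_genome, mini_criteria, baf=baf)
    b = classify_specimen(segs, mini_genome, mini_criteria, baf=baf)
    assert a.category == b.category and a.calls == b.calls


def test_criteria_validation():
    with pytest.raises(InvalidConfigError):
        ReportingCriteria(min_del_size=0)
    with pytest.raises(InvalidConfigError):
        ReportingCriteria(mcc_exclusion=1.5)
    with pytest.raises(InvalidConfigError):
        CnvCall("chr1", 0, 10, "dup", 99, 1.0, "1p11")


def test_scaled_criteria_preserve_fractions():
    c = ReportingCriteria().scaled(20)
    assert c.min_del_size == 50_000 and c.min_dup_size == 100_000
    assert c.min_mosaic_fraction == 0.30 and c.mcc_exclusion == 0.30
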