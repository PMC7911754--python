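import numpy as np
import pytest

from poccnv.classify import ReportingCriteria
from poccnv.cnvseq import CopyRatioProfile
from poccnv.genome import GenomeConfig, build_genome


@pytest.fixture(scope="session")
def mini_genome():
    """Default miniature genome: 24 chromosomes at 1/20 hg19 scale, 20-kb bins."""
    return build_genome()


@pytest.fixture(scope="session")
def mini_criteria():
    """Reporting criteria with size thresholds matched to the 1/20 genome."""
    return ReportingCriteria().scaled(20)


@pytest.fixture
def flat_single_chrom():
    """Factory for a one-chromosome genome with constant GC (CBS unit tests)."""

    def make(n_bins: int, bin_size: int = 1000, gc: float = 0.4):
        return build_genome(
            GenomeConfig(
                chromosomes=[("chr1", n_bins * bin_size)],
                bin_size=bin_size,
                gc_track={"chr1": np.full(n_bins, gc)},
            )
        )

    return make


def profile_from_values(values: np.ndarray, specimen_id: str = "t") -> CopyRatioProfile:
    values = np.asarray(values, dtype=float)
    return CopyRatioProfile(
        specimen_id=specimen_id,
        log2_ratio=values,
        mask=np.isfinite(values),
        inferred_sex="XX",
    )
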