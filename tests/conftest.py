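import numpy as np
import pytest

from epinorm.peak_io import GeneAnnotation, GeneModel, Peak, PeakSet
from epinorm.synthetic_data import SimulationParams, generate_annotation, generate_peak_experiment


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    """The default synthetic study conditions."""
    return SimulationParams()


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down experiment for fast end-to-end tests."""
    return SimulationParams(
        n_genes=60,
        chrom_length=3_000_000,
        n_common=80,
        n_diff_ko=15,
        n_diff_wt=15,
        signature_size=20,
        n_reps=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_experiment(default_params):
    """Annotation + peak catalogs + counts + truth at the default conditions."""
    rngs = default_params.rngs()
    annotation = generate_annotation(default_params, rngs["annotation"])
    ko, wt, counts_ko, counts_wt, truth = generate_peak_experiment(
        default_params, annotation, rngs["peaks"]
    )
    return annotation, ko, wt, counts_ko, counts_wt, truth


@pytest.fixture()
def two_gene_annotation() -> GeneAnnotation:
    """One + strand and one − strand gene with simple exon structure."""
    plus = GeneModel("GPLUS", "chr1", "+", 100_000, 110_000,
                     (100_000, 105_000), (102_000, 110_000))
    minus = GeneModel("GMINUS", "chr1", "-", 300_000, 310_000,
                      (300_000, 306_000), (303_000, 310_000))
    return GeneAnnotation([plus, minus])


def random_peakset(rng: np.random.Generator, n: int, label: str,
                   span: int = 100_000, max_len: int = 2_000) -> PeakSet:
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    peaks = [Peak("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
    return PeakSet(label, peaks)
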