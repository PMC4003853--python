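import numpy as np
import pytest

from osd_haplomap.genomic_io import build_windows, callable_mask, read_variants
from osd_haplomap.synthetic_data import MosaicParams, simulate_mosaic, write_fixture

STUDY_CHROM = {"chr1": 10_000_000}


@pytest.fixture(scope="session")
def small_mosaic():
    """A 10-Mb two-strain mosaic at the default study conditions."""
    params = MosaicParams(chrom_lengths=STUDY_CHROM, seed=3)
    return simulate_mosaic(params)


@pytest.fixture(scope="session")
def mosaic_fixture_dir(small_mosaic, tmp_path_factory):
    """The same mosaic written to disk (VCF, gap BEDs, sizes, truth)."""
    outdir = tmp_path_factory.mktemp("mosaic")
    paths = write_fixture(small_mosaic, outdir)
    return paths


@pytest.fixture(scope="session")
def scanned_windows(small_mosaic, mosaic_fixture_dir):
    """Window table inputs for the small mosaic, read back from disk."""
    pair = small_mosaic.strains[:2]
    pv = read_variants(mosaic_fixture_dir["vcf"], pair)
    windows = build_windows(small_mosaic.params.chrom_lengths)
    cb = callable_mask(small_mosaic.gaps[pair[0]], small_mosaic.gaps[pair[1]],
                       windows)
    return pv, windows, cb
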