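import pytest

from brbkit.demux import parse_read_structure
from brbkit.simulate import (
    SimLibraryConfig,
    make_toy_annotation,
    random_barcodes,
    simulate_brbseq_library,
)


@pytest.fixture(scope="session")
def toy_annotation():
    return make_toy_annotation(n_genes=20, n_chroms=2, include_mt=True, seed=1)


@pytest.fixture(scope="session")
def gene_model(toy_annotation):
    return toy_annotation.gene_model()


@pytest.fixture(scope="session")
def barcodes():
    return random_barcodes(4, length=6, min_dist=3, seed=2)


@pytest.fixture(scope="session")
def read_structure():
    return parse_read_structure("B6N10V5")


@pytest.fixture(scope="session")
def clean_library(tmp_path_factory, gene_model, barcodes, read_structure):
    """Error-free library: no sequencing errors, no special reads."""
    cfg = SimLibraryConfig(
        barcodes=barcodes,
        read_structure=read_structure,
        molecules_per_sample=500,
        dup_p=0.5,
        seed=3,
    )
    outdir = tmp_path_factory.mktemp("clean_lib")
    return simulate_brbseq_library(cfg, gene_model, outdir)


@pytest.fixture(scope="session")
def messy_library(tmp_path_factory, gene_model, barcodes, read_structure):
    """Library with unmapped / multimapped / intergenic reads injected."""
    cfg = SimLibraryConfig(
        barcodes=barcodes,
        read_structure=read_structure,
        molecules_per_sample=400,
        dup_p=0.5,
        frac_unmapped=0.05,
        frac_multimapped=0.05,
        frac_intergenic=0.05,
        seed=4,
    )
    outdir = tmp_path_factory.mktemp("messy_lib")
    return simulate_brbseq_library(cfg, gene_model, outdir)
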