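import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from togcn import expression as expr
from togcn import family as fam
from togcn import network as net
from togcn import pipeline
from togcn import promoter as prom
from togcn import synthetic


@pytest.fixture(scope="session")
def expr_fixture():
    """Default planted expression matrix (500 genes, 30 TFs, 5 modules, seed 42)."""
    return synthetic.generate_expression(seed=42)


@pytest.fixture(scope="session")
def expr_fixture_low_noise():
    return synthetic.generate_expression(noise_sd=0.05, seed=42)


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome")
    fasta, gff, truth = synthetic.generate_genome(outdir, seed=42)
    annotation = fam.GenomeAnnotation.from_gff3(gff)
    motifs = prom.load_motif_table()
    return {
        "fasta": fasta,
        "gff": gff,
        "truth": truth,
        "annotation": annotation,
        "motifs": motifs,
    }


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo")
    manifest = pipeline.demo(outdir, seed=42)
    return {"outdir": outdir, "manifest": manifest}


@pytest.fixture(scope="session")
def filtered_fixture(expr_fixture):
    matrix, truth = expr_fixture
    filtered = expr.filter_low_expression(matrix)
    means = expr.treatment_means(filtered)
    return {"filtered": filtered, "means": means, "truth": truth}


@pytest.fixture(scope="session")
def network_fixture(filtered_fixture):
    graph = net.build_edges(
        filtered_fixture["filtered"], filtered_fixture["truth"].tf_ids, pcc_min=0.9
    )
    return {"graph": graph, **filtered_fixture}
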