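import numpy as np
import pytest

from ompfam.pipeline import PipelineConfig, run_pipeline
from ompfam.profiles import build_profile, calibrate
from ompfam.synth import GeneratorConfig, generate, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic superfamily for module-level integration tests."""
    cfg = GeneratorConfig(seed=7)
    cfg.template_counts = {k: 6 for k in cfg.template_counts}
    cfg.contaminants_per_family = 4
    return generate(cfg)


@pytest.fixture(scope="session")
def potra_profile(small_dataset):
    profile = build_profile(small_dataset.seed_alignments["potra"],
                            name="potra", pseudocount_weight=8.0)
    calibrate(profile, seed=23)
    return profile


@pytest.fixture(scope="session")
def omp85_profile(small_dataset):
    profile = build_profile(small_dataset.seed_alignments["barrel_omp85"],
                            name="omp85", pseudocount_weight=8.0)
    calibrate(profile, seed=22)
    return profile


def _write_and_run(tmpdir, gen_config, seed=7):
    dataset = generate_dataset(gen_config, tmpdir)
    config = PipelineConfig(
        sequences=str(tmpdir / "sequences.fasta"),
        seed_omp85=str(tmpdir / "seeds" / "barrel_omp85.afa"),
        seed_tpsb=str(tmpdir / "seeds" / "barrel_tpsb.afa"),
        seed_potra=str(tmpdir / "seeds" / "potra.afa"),
        annotations=str(tmpdir / "annotations.tsv"),
        taxa=str(tmpdir / "taxa.tsv"),
        subfamilies=str(tmpdir / "truth.tsv"),
        ftsq=str(tmpdir / "ftsq.fasta"),
        outdir=str(tmpdir / "out"),
        seed=seed,
    )
    return dataset, run_pipeline(config)


@pytest.fixture(scope="session")
def full_pipeline(tmp_path_factory):
    """The reference end-to-end run: ten architectures x 30 sequences plus
    50 contaminants at divergence 0.25, seed 7."""
    tmpdir = tmp_path_factory.mktemp("full_run")
    return _write_and_run(tmpdir, GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A fast end-to-end run on the reduced dataset."""
    tmpdir = tmp_path_factory.mktemp("small_run")
    cfg = GeneratorConfig(seed=7)
    cfg.template_counts = {k: 6 for k in cfg.template_counts}
    cfg.contaminants_per_family = 4
    return _write_and_run(tmpdir, cfg)
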