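import pytest

from bbbcurate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def clean_dataset():
    """Small corruption-free corpus: pipeline output must equal truth."""
    cfg = SyntheticConfig(
        n_molecules=40, seed=11, noise_sd=0.0, outlier_rate=0.0,
        conflict_rate=0.0, whitespace_rate=0.0, salt_rate=0.0,
        charge_rate=0.0, name_only_rate=0.0, cid_only_rate=0.0,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def messy_dataset():
    """Corpus with default noise/corruption rates and known truth."""
    return generate(SyntheticConfig(n_molecules=60, seed=5))


def run_offline(dataset, tmpdir, **overrides):
    """Drive the full pipeline over a generated dataset's CSV tables."""
    from bbbcurate.pipeline import RunConfig, SourceSpec, run_pipeline

    src = tmpdir / "src"
    dataset.write(src)
    sources = [
        SourceSpec(path=str(src / f"{sid}.csv"), source_id=sid,
                   schema_map=dataset.schema_map)
        for sid in sorted(dataset.sources)
    ]
    config = RunConfig(sources=sources, output_dir=str(tmpdir / "out"), **overrides)
    return run_pipeline(config, resolver=dataset.resolver)
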