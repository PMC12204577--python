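import numpy as np
import pytest

from ncaabind import encoder, featurizer, fixtures, ingest, model, tokenizer


@pytest.fixture(scope="session")
def std_fixture(tmp_path_factory):
    """One standard synthetic study: 150 peptides, 3 latent factors,
    noise 0.2, written to disk and re-read through the public pipeline."""
    out = tmp_path_factory.mktemp("std_fixture")
    spec = fixtures.FixtureSpec(seed=1)
    registry = fixtures.generate_registry(spec.n_ncaa_types, spec.seed)
    table, truth = fixtures.generate_dataset(spec, registry, out_dir=out)
    records = ingest.read_iedb_export(out / "export.csv")
    kept, report = ingest.filter_dataset(
        records, hla=fixtures.FIXTURE_HLA, response=fixtures.FIXTURE_RESPONSE
    )
    peptides = [tokenizer.tokenize_name(r.name_field) for r in kept]
    tokens = sorted({t for p in peptides for t in p.tokens})
    fmap = featurizer.build_token_map(registry, tokens)
    X, ids = encoder.encode_dataset(peptides, fmap)
    y = model.transform_target(np.array([r.quantitative_nM for r in kept]))
    return {
        "spec": spec,
        "registry": registry,
        "table": table,
        "truth": truth,
        "records": kept,
        "report": report,
        "peptides": peptides,
        "fmap": fmap,
        "X": X,
        "ids": ids,
        "y": y,
        "dir": out,
    }


@pytest.fixture(scope="session")
def manifest():
    return featurizer.load_default_manifest()
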