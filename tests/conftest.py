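"""Shared fixtures: synthetic corpora built once per session."""

import numpy as np
import pytest

from coexpr import catalog as cat
from coexpr.normalize import vst
from coexpr.store import build_store
from coexpr.synthetic import default_dictionaries, preset, simulate_counts


def dictionaries_from(dicts: dict):
    return (
        cat.RegexDictionary(dicts["tissues"]),
        cat.RegexDictionary(dicts["disease"]),
        cat.RegexDictionary(dicts["scrna"]),
    )


def records_from_metadata(
    metadata,
    dicts: dict,
    min_reads: int = cat.DEFAULT_MIN_READS,
    min_group_size: int = cat.DEFAULT_MIN_GROUP_SIZE,
):
    td, dd, sd = dictionaries_from(dicts)
    records = [
        cat.SampleRecord(r.sample_id, r.tissue_description, int(r.total_reads))
        for r in metadata.itertuples()
    ]
    return cat.apply_filters(
        cat.annotate_records(records, td, dd, sd), min_reads, min_group_size
    )


def build_preset_store(name: str, seed: int):
    spec = preset(name, seed=seed)
    counts, metadata, truth = simulate_counts(spec)
    dicts = default_dictionaries([g.tissue for g in spec.groups])
    records = records_from_metadata(metadata, dicts)
    store = build_store(vst(counts), records)
    return store, truth, counts, metadata


@pytest.fixture(scope="session")
def strong_bundle():
    return build_preset_store("strong", seed=11)


@pytest.fixture(scope="session")
def strong_store(strong_bundle):
    return strong_bundle[0]


@pytest.fixture(scope="session")
def strong_truth(strong_bundle):
    return strong_bundle[1]


@pytest.fixture(scope="session")
def null_bundle():
    return build_preset_store("null", seed=7)


@pytest.fixture(scope="session")
def null_store(null_bundle):
    return null_bundle[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
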