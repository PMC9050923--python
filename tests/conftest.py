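import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

from triazqsar import activity, fields, library, prep
from triazqsar.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def library_records():
    return library.build_library()


@pytest.fixture(scope="session")
def records_by_id(library_records):
    return {r.id: r for r in library_records}


@pytest.fixture(scope="session")
def dataset():
    return activity.default_dataset()


@pytest.fixture(scope="session")
def small_aligned(records_by_id):
    """Four real compounds embedded (few starts) and scaffold-aligned."""
    ids = (101, 56, 1, 116)
    confs = [
        prep.assign_charges(
            prep.embed_minimize(records_by_id[c].mol, compound_id=c, seed=11, n_starts=5)
        )
        for c in ids
    ]
    return prep.align_to_reference(confs, reference_id=101)


@pytest.fixture(scope="session")
def small_descriptors(small_aligned):
    grid = fields.make_grid(small_aligned.conformers, spacing=2.0, margin=4.0)
    cfg = fields.FieldConfig()
    blocks = [fields.compute_field_block(c, grid, cfg) for c in small_aligned.conformers]
    return fields.assemble_descriptor_matrix(blocks, grid, cfg)


@pytest.fixture(scope="session")
def full_run():
    """One full default-configuration pipeline run, shared by the model tests."""
    return run_pipeline(RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
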