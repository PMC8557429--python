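"""Shared fixtures: one deterministic synthetic proteome reused across modules."""

import pytest

from neuropep.precursor_annotation import annotate_precursor
from neuropep.synthetic_data import generate_proteome

SEED = 11


@pytest.fixture(scope="session")
def proteome():
    """Default study conditions: 7 planted families (5 discoverable) + 1000 decoys."""
    records, annotations, truth = generate_proteome(n_decoys=1000, seed=SEED)
    return records, annotations, truth


@pytest.fixture(scope="session")
def planted_annotated(proteome):
    """Annotated planted precursors (with their true signal annotations)."""
    records, annotations, truth = proteome
    sig = {a.protein_id: a for a in annotations}
    planted = set(truth.planted_ids())
    return [annotate_precursor(r, sig[r.id]) for r in records if r.id in planted]
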