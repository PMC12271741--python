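import numpy as np
import pytest
from hypothesis import settings

from compevol.data import CompartmentClass, GeneRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(gene_id, omega, abundance, compartment, essential=True, ds=0.3, **kw):
    label = {
        CompartmentClass.MEMBRANE: "cell membrane",
        CompartmentClass.CYTOPLASM: "cytoplasm",
        CompartmentClass.OTHERS: "nucleolus",
    }[compartment]
    return GeneRecord(
        gene_id=gene_id,
        omega=omega,
        ds=ds,
        abundance=abundance,
        location_label=label,
        essential=essential,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_two_class_records(rng):
    """60 genes in two classes with a common abundance->rate law (a null)."""
    recs = []
    for i in range(60):
        comp = CompartmentClass.MEMBRANE if i < 30 else CompartmentClass.CYTOPLASM
        x = rng.normal(2.0, 1.0)
        y = -0.3 * x + rng.normal(0, 0.3)
        recs.append(make_record(f"t{i:03d}", 10.0**y, 10.0**x, comp))
    return recs
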