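import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from expertpe.config import RunConfig
from expertpe.pipeline import design_edits
from expertpe.sequence_core import EditAtom, EditSpec
from expertpe.synthetic_fixtures import make_locus, recipe_for_nicks

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_locus():
    """400-nt locus whose only guide sites give nicks at 180 and 217 (DCN 37)."""
    return make_locus(recipe_for_nicks(seed=7, length=400, nicks=(180, 217)))


@pytest.fixture(scope="session")
def replace37_edit():
    return EditSpec(
        atoms=(EditAtom(180, 217, "T" * 18 + "A" * 19),),
        label="-37to-1 replace 37 bp",
    )


@pytest.fixture(scope="session")
def top_design(planted_locus, replace37_edit):
    designs, frame = design_edits(planted_locus, replace37_edit, RunConfig(strand="+"))
    assert designs
    return designs[0], frame


def make_sites(nicks, strand="+"):
    """Manually construct same-strand guide sites at given nick indices."""
    from expertpe.guide_search import GuideSite

    spacer = "ATCTTATCATTCTATAATCT"  # GG/CC-free dummy protospacer
    return [
        GuideSite(spacer=spacer, pam="AGG", strand=strand,
                  protospacer_start=n - 17, nick=n)
        for n in nicks
    ]
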