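import numpy as np
import pytest

from immunopep.io import ContaminantLists, PeptideRecord, filter_repertoire
from immunopep.simulate import (
    EXAMPLE_CONTAMINANTS,
    RepertoireSpec,
    b57_like_specs,
    simulate_repertoire,
)


def records_from_frame(df):
    from immunopep.io import parse_modifications

    return [
        PeptideRecord(
            sequence=r.sequence,
            confidence=float(r.confidence),
            modifications=parse_modifications(str(r.modifications)),
            allotype=str(r.allotype),
            replicate=str(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def contaminant_lists():
    return ContaminantLists(generic_contaminants=frozenset(EXAMPLE_CONTAMINANTS))


@pytest.fixture(scope="session")
def b57_cohort(contaminant_lists):
    """Filtered repertoires for the three bundled allotype-like specs."""
    reps = {}
    for name, spec in b57_like_specs(n=1200, seed=11).items():
        df = simulate_repertoire(spec)
        reps[name] = filter_repertoire(
            records_from_frame(df), 95.0, contaminant_lists, allotype=name
        )
    return reps


@pytest.fixture(scope="session")
def nonamers_fixed_profile():
    """Seeded 9-mer set drawn position-independently from a stated profile."""
    from immunopep.simulate import profile_with_anchors

    prof = profile_with_anchors(9, {2: {"S": 0.4, "T": 0.25}, 9: {"W": 0.6, "F": 0.3}})
    spec = RepertoireSpec(
        n=3000,
        seed=5,
        length_weights={9: 1.0},
        profiles={9: prof},
        contaminant_fraction=0.0,
        low_confidence_fraction=0.0,
    )
    return simulate_repertoire(spec).sequence.tolist(), prof
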