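import pytest

from ith_ihc import Cohort, DEFAULT_MARKERS, TumorGrid


def make_tumor(tumor_id, stage, foci, lost, markers=DEFAULT_MARKERS, missing=()):
    """Build a TumorGrid from a {marker: iterable-of-lost-foci} mapping.

    Cells default to score 2; `missing` lists (focus, marker) cells to
    blank to non-evaluable.
    """
    grid = {}
    for f in foci:
        for m in markers:
            if (f, m) in missing:
                grid[(f, m)] = None
            elif f in lost.get(m, ()):
                grid[(f, m)] = 0
            else:
                grid[(f, m)] = 2
    return TumorGrid(tumor_id=tumor_id, stage=stage, foci=list(foci), grid=grid)


@pytest.fixture
def worked_example_tumor():
    """The canonical worked example: ARID1A and BRM lost in the first
    three of four foci, PBRM1 and BRG1 lost only in the third."""
    return make_tumor(
        "T5", 1, ["R1", "R2", "R3", "R4"],
        {"ARID1A": {"R1", "R2", "R3"}, "BRM": {"R1", "R2", "R3"},
         "PBRM1": {"R3"}, "BRG1": {"R3"}},
    )


@pytest.fixture
def worked_example_cohort(worked_example_tumor):
    return Cohort(tumors=[worked_example_tumor])


@pytest.fixture
def all_retained_cohort():
    tumors = [
        make_tumor(f"N{i}", 1 + i % 4, ["F1", "F2", "F3", "F4"], {})
        for i in range(8)
    ]
    return Cohort(tumors=tumors)


@pytest.fixture
def three_tumor_cohort():
    """Three tumors, each losing PBRM1 in exactly one of its four foci."""
    tumors = [
        make_tumor(f"T{i}", 1, ["F1", "F2", "F3", "F4"], {"PBRM1": {"F1"}})
        for i in range(3)
    ]
    return Cohort(tumors=tumors)
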