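"""Shared fixtures: a session-wide synthetic study and interval helpers."""

import warnings

import pytest

from qtlatlas import QTLInterval, QTLRecord, analyze_study, simulate_study


@pytest.fixture(scope="session")
def study():
    """One synthetic study with planted truth, shared across the session."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def analysis(study):
    """The full in-memory analysis of the shared study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # planted foreign-gene edge warns
        return analyze_study(study)


def make_interval(
    qtl_id,
    chrom,
    start,
    end,
    trait="FT",
    population="pop1",
    country="China",
    source="src1",
):
    """Fabricate a projected QTL interval without running placement."""
    rec = QTLRecord(
        qtl_id=qtl_id, trait=trait, population=population, country=country,
        markers=("m",), source=source,
    )
    return QTLInterval(
        qtl=rec, chrom=chrom, start=start, end=end, basis="two_markers",
        window_bp=0,
    )


@pytest.fixture
def mk_interval():
    return make_interval
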