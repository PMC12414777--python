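import pytest

from fh_triage.phenotype import apply_exclusions, assign_carriers
from fh_triage.synthetic import build_table_fixtures, cascade_relative_ids


@pytest.fixture(scope="session")
def study_fixtures():
    """Deterministic reconstruction of the study's printed-table marginals."""
    return build_table_fixtures()


@pytest.fixture(scope="session")
def carrier_analysis(study_fixtures):
    """Carrier set after assignment and the study exclusion rules."""
    fx = study_fixtures
    cs = assign_carriers(fx["genotypes"], fx["variants"])
    return apply_exclusions(
        cs,
        cascade_relative_ids=cascade_relative_ids(fx["carriers"]),
        q4494del_variant_ids=frozenset({"APOB_Q4494DEL"}),
    )
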