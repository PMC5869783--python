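import pandas as pd
import pytest

from htcover import CriteriaConfig, RecordBundle, StudyConfig, make_table


def build_bundle(**tables) -> RecordBundle:
    """Construct a bundle from per-table row dicts, filling the rest empty."""
    kwargs = {}
    for name in ("persons", "screenings", "services", "diagnoses", "registry",
                 "followups"):
        rows = tables.get(name)
        kwargs[name] = make_table(name, pd.DataFrame(rows) if rows else None)
    return RecordBundle(**kwargs)


@pytest.fixture
def study():
    return StudyConfig()


@pytest.fixture
def criteria():
    return CriteriaConfig()


@pytest.fixture
def eligibility_bundle():
    """Ten persons: two under-age, one prior-HT, one off-province, six eligible.

    The off-province person lives in province 40, which the matching
    ``eligibility_study`` config excludes from the included set.
    """
    persons = [
        # age 13 and 14 at 2013-01-01
        dict(person_id="E01", birth_date="1999-06-01", sex="female",
             province_code=5, in_civil_registry=True),
        dict(person_id="E02", birth_date="1998-06-30", sex="male",
             province_code=5, in_civil_registry=True),
        # exactly 15 on the reference date
        dict(person_id="E03", birth_date="1998-01-01", sex="female",
             province_code=5, in_civil_registry=True),
        dict(person_id="E04", birth_date="1960-03-15", sex="male",
             province_code=5, in_civil_registry=True),  # prior HT (registry)
        dict(person_id="E05", birth_date="1970-07-20", sex="female",
             province_code=40, in_civil_registry=True),  # excluded province
        dict(person_id="E06", birth_date="1980-01-31", sex="male",
             province_code=6, in_civil_registry=True),
        dict(person_id="E07", birth_date="1955-11-05", sex="female",
             province_code=6, in_civil_registry=True),
        dict(person_id="E08", birth_date="1990-02-28", sex="male",
             province_code=7, in_civil_registry=True),
        dict(person_id="E09", birth_date="1948-08-09", sex="female",
             province_code=7, in_civil_registry=True),
        dict(person_id="E10", birth_date="1975-12-31", sex="male",
             province_code=8, in_civil_registry=True),
    ]
    registry = [
        dict(person_id="E04", condition="hypertension",
             registration_date="2012-05-01"),
        # non-HT registry entry must not exclude
        dict(person_id="E06", condition="other", registration_date="2011-02-02"),
    ]
    return build_bundle(persons=persons, registry=registry)


@pytest.fixture
def eligibility_study():
    return StudyConfig(included_provinces=frozenset(set(range(1, 77)) - {40}))
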