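import numpy as np
import pytest

from twinpain.datamodel import (
    Cohort,
    IndividualRecord,
    Role,
    Tristate,
    Zygosity,
)


def make_twin(family_id, role, zygosity, value, trait="lbp_life", age=15.0, **kw):
    """Build a twin record with one tristate trait set."""
    fields = {trait: value}
    fields.update(kw)
    return IndividualRecord(
        family_id=family_id,
        role=role,
        zygosity=zygosity,
        age=age,
        sex="female",
        **fields,
    )


def pair_cohort(pair_values, zygosity=Zygosity.MZ, trait="lbp_life"):
    """Cohort of twin pairs from a list of (value1, value2) tristates."""
    records = []
    for i, (v1, v2) in enumerate(pair_values):
        fid = f"P{i:04d}"
        records.append(make_twin(fid, Role.TWIN1, zygosity, v1, trait))
        records.append(make_twin(fid, Role.TWIN2, zygosity, v2, trait))
    return Cohort(records=records)


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """A 4-row toy cohort file: two twins, one mother, one father."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "family_id,role,zygosity,age,sex,pain_sites,most_important_site,"
        "lbp_life,tlbp_current,serious_injury_or_disease\n"
        "F1,twin1,MZ,14,female,neck;lower_back,lower_back,1,1,0\n"
        "F1,twin2,MZ,14,male,,,0,0,0\n"
        "F1,mother,,45,female,,,1,0,0\n"
        "F1,father,,47,male,,,NA,0,0\n"
    )
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230214)
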