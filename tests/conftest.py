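import numpy as np
import pytest

from glycoprog import Cohort, OGTTRecord, Participant, Visit


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_visit(visit_index, g0=None, g60=None, g120=None, i0=None, i60=None,
               i120=None, hba1c=None, bmi=None, fat_mass=None, med=False,
               msi=None, mbcf=None):
    return Visit(visit_index=visit_index,
                 ogtt=OGTTRecord(g0=g0, g60=g60, g120=g120,
                                 i0=i0, i60=i60, i120=i120, hba1c=hba1c),
                 bmi=bmi, fat_mass=fat_mass, on_antidiabetic_medication=med,
                 msi=msi, mbcf=mbcf)


def make_participant(pid, visits, sex="female", age=50.0):
    return Participant(id=pid, sex=sex, baseline_age=age, visits=tuple(visits))


@pytest.fixture
def small_cohort():
    """Three participants with assorted visits and missing values."""
    p1 = make_participant("A", [
        make_visit(0, g0=85.0, g60=120.0, g120=110.0, i0=6.0, i60=25.0,
                   i120=20.0, hba1c=5.2, bmi=23.0, fat_mass=15.0),
        make_visit(2, g0=88.0, g120=115.0, hba1c=5.3, bmi=23.5),
        make_visit(5, g0=95.0, g60=150.0, g120=130.0, i0=8.0, i60=30.0,
                   i120=26.0, hba1c=5.5, bmi=24.0, fat_mass=16.0),
    ])
    p2 = make_participant("B", [
        make_visit(0, g0=90.0, g120=120.0, hba1c=5.4, bmi=26.0),
        make_visit(5, g0=110.0, g120=160.0, hba1c=5.9, bmi=27.0),
    ], sex="male")
    p3 = make_participant("C", [make_visit(0, g0=99.0, g120=139.0, hba1c=5.6)])
    return Cohort(participants=(p1, p2, p3), provenance="unit-test")
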