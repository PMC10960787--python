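import pytest

from renalrx import PatientProfile, load_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture()
def m001():
    """Worked-example patient: G3b CKD, diabetic, not on dialysis, on an
    oral hypoglycemic plus an interacting ACE-i/ARA pair."""
    return PatientProfile(
        patient_id="M001", age=61.0, gender="F", bmi=29.4, hba1c=7.0,
        gfr=30.0, scr=2.4, has_ckd="Yes", has_t2dm="Yes", has_dialysis="No",
        prescription=frozenset({"Acarbose", "Candesartan", "Ramipril"}))


def profile(gfr=None, hba1c=None, ckd=None, t2dm=None, dialysis=None,
            rx=(), pid="P1"):
    return PatientProfile(
        patient_id=pid, gfr=gfr, hba1c=hba1c, has_ckd=ckd, has_t2dm=t2dm,
        has_dialysis=dialysis, prescription=frozenset(rx))
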