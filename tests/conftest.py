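import datetime

import pytest

from claimstroke import default_catalog, default_ruleset
from claimstroke.model import (
    AdmissionEpisode,
    ClaimLine,
    CodeKind,
    Department,
    DxPosition,
    Setting,
)

INDEX_DATE = datetime.date(2012, 6, 1)


def make_line(
    code,
    *,
    off=0,
    kind=CodeKind.PROCEDURE,
    setting=Setting.IN_HOSPITAL,
    department=Department.OTHER,
    dx_position=None,
    patient_id="P1",
    claim_id="C1",
    index_date=INDEX_DATE,
):
    if dx_position is None:
        dx_position = (
            DxPosition.ADDITIONAL if kind is CodeKind.DIAGNOSIS else DxPosition.NONE
        )
    service = index_date + datetime.timedelta(days=off)
    return ClaimLine(
        patient_id=patient_id,
        claim_id=claim_id,
        setting=setting,
        department=department,
        code=code,
        code_kind=kind,
        dx_position=dx_position,
        service_date=service,
        claim_start_date=index_date if setting is Setting.IN_HOSPITAL else service,
    )


def make_episode(lines, *, principal_dx="I639", index_date=INDEX_DATE, episode_id="E1"):
    episode_lines = [l for l in lines if -7 <= (l.service_date - index_date).days <= 90]
    lookback = [l for l in lines if l.service_date < index_date]
    return AdmissionEpisode(
        episode_id=episode_id,
        patient_id="P1",
        index_date=index_date,
        principal_dx=principal_dx,
        episode_lines=episode_lines,
        lookback_lines=lookback,
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()
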