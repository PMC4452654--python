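import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from treatcycles import build_cohort, group_into_cases, worked_example_fixture


@pytest.fixture(scope="session")
def worked_records():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_cases(worked_records):
    return group_into_cases(worked_records)


@pytest.fixture(scope="session")
def worked_cycles(worked_cases):
    case_cycles, joined = build_cohort(worked_cases)
    return {c.case_ids[0]: c for c in case_cycles}, joined
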