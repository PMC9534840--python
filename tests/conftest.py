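"""Shared fixtures: a hand-built toy observation dataset.

The toy dataset covers the curation rules in a form small enough to check by
hand: ego A has five partners with a tied weight (counts 10, 5, 2, 2, 1),
ego B groomed only four partners (excluded by the partner filter), and ego C
has one 5-minute follow (discarded, taking its only record of partner H with
it) plus five retained follows giving exactly five partners.
"""

import textwrap

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

TOY_FOLLOWS = textwrap.dedent("""\
    follow_id,group_id,focal_id,date,duration_minutes,n_scans
    F001,gA,A,2016-01-01,10,10
    F002,gA,A,2016-01-02,10,10
    F003,gA,A,2016-01-03,10,10
    F004,gA,A,2016-01-04,10,10
    F005,gA,A,2016-01-05,10,10
    F006,gA,A,2016-01-06,10,10
    F007,gA,A,2016-01-07,10,10
    F008,gA,A,2016-01-08,10,10
    F009,gA,A,2016-01-09,10,10
    F010,gA,A,2016-01-10,10,10
    F011,gA,A,2016-01-11,10,10
    F012,gA,A,2016-01-12,10,10
    F013,gA,B,2016-02-01,10,10
    F014,gA,B,2016-02-02,10,10
    F015,gA,B,2016-02-03,10,10
    F016,gA,B,2016-02-04,10,10
    F017,gA,C,2016-03-01,5,5
    F018,gA,C,2016-03-02,10,10
    F019,gA,C,2016-03-03,10,10
    F020,gA,C,2016-03-04,10,10
    F021,gA,C,2016-03-05,10,10
    F022,gA,C,2016-03-06,10,10
    """)

# ego A counts: B=10 follows (3 scans in F001 still count once), C=5, D=2,
# E=2, F=1 -> weights (10, 5, 2, 2, 1); minutes mode: B=12, C=5, D=2, E=2, F=1
TOY_EVENTS = textwrap.dedent("""\
    follow_id,scan_index,behavior,partner_id,minutes
    F001,1,grooming,B,1
    F001,2,grooming,B,1
    F001,3,grooming,B,1
    F001,4,grooming,C,1
    F001,5,grooming,D,1
    F002,1,grooming,B,1
    F002,2,grooming,C,1
    F002,3,grooming,D,1
    F002,4,grooming,E,1
    F003,1,grooming,B,1
    F003,3,grooming,C,1
    F003,5,grooming,E,1
    F004,1,grooming,B,1
    F004,2,grooming,C,1
    F004,3,grooming,F,1
    F005,1,grooming,B,1
    F005,2,grooming,C,1
    F006,1,grooming,B,1
    F007,1,grooming,B,1
    F008,1,grooming,B,1
    F009,1,grooming,B,1
    F010,1,grooming,B,1
    F011,2,proximity,C,
    F013,1,grooming,A,1
    F013,2,grooming,C,1
    F014,1,grooming,D,1
    F015,1,grooming,E,1
    F017,1,grooming,H,1
    F018,1,grooming,A,1
    F018,2,grooming,D,1
    F019,1,grooming,A,1
    F019,2,grooming,E,1
    F020,1,grooming,F,1
    F021,1,grooming,G,1
    """)

#: hand-computed curation results for the toy dataset (binarised mode)
TOY_WEIGHTS = {
    "A": {"B": 10, "C": 5, "D": 2, "E": 2, "F": 1},
    "B": {"A": 1, "C": 1, "D": 1, "E": 1},
    "C": {"A": 2, "D": 1, "E": 1, "F": 1, "G": 1},
}


@pytest.fixture
def toy_paths(tmp_path):
    """Write the toy CSVs to disk and return their paths."""
    follows = tmp_path / "follows.csv"
    events = tmp_path / "events.csv"
    follows.write_text(TOY_FOLLOWS)
    events.write_text(TOY_EVENTS)
    return {"follows": follows, "events": events, "dir": tmp_path}


@pytest.fixture
def toy_obs(toy_paths):
    from egolayers import parse_observations

    return parse_observations(toy_paths["follows"], toy_paths["events"])


@pytest.fixture
def five_alter_network():
    """The worked ego: weights (10, 5, 2, 2, 1), sigma = 4, t_bar = 2/3."""
    from egolayers import EgoNetwork

    return EgoNetwork(ego_id="A", group_id="gA",
                      weights={"B": 10.0, "C": 5.0, "D": 2.0, "E": 2.0, "F": 1.0},
                      n_follows=12)
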