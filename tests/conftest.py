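"""Shared fixtures.

``published_counts`` holds the printed dyad margins used as reproduction
inputs; ``margin_cohort`` is a subject-level cohort constructed so that all
seven dyad tables reproduce those margins simultaneously (the joint
(paternal, maternal) distribution per sex and status is solved from the
three overlapping dyad denominators, with the leftovers assigned to
single-parent-unknown cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dyadscan.cohort_io import COLUMNS, CohortTable

# printed dyad margins: (parent, offspring_sex) -> (a, n_case, c, n_ctrl)
PUBLISHED_COUNTS = {
    ("father", "male"): (52, 325, 36, 761),
    ("father", "female"): (64, 537, 64, 1383),
    ("any", "female"): (184, 533, 189, 1382),
    ("mother", "female"): (140, 551, 134, 1404),
    ("mother", "male"): (92, 332, 59, 768),
    ("any", "male"): (128, 322, 90, 757),
    ("any", "any"): (312, 855, 279, 2139),
}

# published per-dyad effect values (2 dp) and relative ratios; the
# mother->son row is inconsistent with its printed counts and is omitted
PUBLISHED_RR = {
    ("father", "male"): 3.38,
    ("father", "female"): 2.58,
    ("any", "female"): 2.52,
    ("mother", "female"): 2.66,
    ("any", "male"): 3.34,
    ("any", "any"): 2.80,
}


def _group_rows(sex: str, status: str, counts: dict) -> list[dict]:
    """Explode one sex x status group into subject rows.

    ``counts`` maps (paternal, maternal) history pairs to row counts.
    """
    rows = []
    is_case = status == "case"
    for (pat, mat), k in counts.items():
        for _ in range(k):
            rows.append(
                {
                    "status": status,
                    "sex": sex,
                    "age_at_assessment": 72.0 if is_case else 80.0,
                    "age_of_onset": 70.0 if is_case else np.nan,
                    "paternal_history": pat,
                    "maternal_history": mat,
                }
            )
    return rows


def _solve_group_cells(ef, nf, em, nm, ea, na, mother_constrained=True):
    """Joint (paternal, maternal) cell counts hitting the dyad margins.

    Cells are keyed by (paternal, maternal) history.  When the mother
    margin is jointly infeasible with the father/any margins (the printed
    male-case row: 52/325, 92/332, 128/322 admit no subject-level table
    under the exclusion rules), it is dropped and the implied mother counts
    fall out of the remaining cells.
    """
    nn = na - ea  # both negative
    if mother_constrained:
        yn = min(ef, nm - em - nn)
    else:
        yn = ef
    ny = ea - yn
    yu = ef - yn  # father yes, mother unknown
    nu = nf - ef - nn - ny  # father no, mother unknown
    uy = (em - ny) if mother_constrained else 0
    un = (nm - em - nn - yn) if mother_constrained else 0
    cells = {
        ("yes", "no"): yn,
        ("no", "yes"): ny,
        ("no", "no"): nn,
        ("yes", "unknown"): yu,
        ("no", "unknown"): nu,
        ("unknown", "yes"): uy,
        ("unknown", "no"): un,
    }
    assert all(v >= 0 for v in cells.values()), cells
    return cells


def build_margin_cohort() -> CohortTable:
    """Cohort whose dyad tables match the published margins.

    All margins are reproduced except mother->son for cases, which is
    jointly infeasible with the father->son / any->son margins (consistent
    with that printed row also disagreeing with its own printed effect).
    """
    per_group = {}
    for sex in ("male", "female"):
        e_f, n_f_case, c_f, n_f_ctrl = PUBLISHED_COUNTS[("father", sex)]
        e_m, n_m_case, c_m, n_m_ctrl = PUBLISHED_COUNTS[("mother", sex)]
        e_a, n_a_case, c_a, n_a_ctrl = PUBLISHED_COUNTS[("any", sex)]
        per_group[(sex, "case")] = _solve_group_cells(
            e_f, n_f_case, e_m, n_m_case, e_a, n_a_case,
            mother_constrained=(sex == "female"),
        )
        per_group[(sex, "control")] = _solve_group_cells(
            c_f, n_f_ctrl, c_m, n_m_ctrl, c_a, n_a_ctrl
        )

    rows: list[dict] = []
    for (sex, status), cells in per_group.items():
        rows.extend(_group_rows(sex, status, cells))
    frame = pd.DataFrame(rows)
    frame.insert(0, "subject_id", [f"M{i:05d}" for i in range(len(frame))])
    for col in COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan if col not in ("father_birthplace", "mother_birthplace", "apoe") else None
    return CohortTable(frame, provenance={"source": "margin_fixture", "filters": []})


@pytest.fixture(scope="session")
def margin_cohort() -> CohortTable:
    return build_margin_cohort()


@pytest.fixture(scope="session")
def paperlike_cohort() -> CohortTable:
    from dyadscan import generate_cohort, scenario_preset

    return generate_cohort(scenario_preset("paperlike", seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
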