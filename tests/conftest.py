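"""Shared fixtures: small pedigrees with known relationship structure."""

import pandas as pd
import pytest

from aortaflow.cohort import Pedigree


def _ped_from_rows(rows):
    table = pd.DataFrame(rows, columns=Pedigree.COLUMNS)
    return Pedigree(table)


@pytest.fixture(scope="session")
def trio_pedigree():
    """Father, mother, two full-sib children."""
    return _ped_from_rows([
        ("F1", "dad", "", "", "male", True, True, False, 0),
        ("F1", "mum", "", "", "female", True, True, False, 0),
        ("F1", "kid1", "dad", "mum", "male", False, True, True, 1),
        ("F1", "kid2", "dad", "mum", "female", False, True, False, 1),
    ])


@pytest.fixture(scope="session")
def halfsib_pedigree():
    """Two half sibs sharing a father."""
    return _ped_from_rows([
        ("F1", "dad", "", "", "male", True, True, False, 0),
        ("F1", "mum1", "", "", "female", True, True, False, 0),
        ("F1", "mum2", "", "", "female", True, True, False, 0),
        ("F1", "h1", "dad", "mum1", "male", False, True, False, 1),
        ("F1", "h2", "dad", "mum2", "female", False, True, False, 1),
    ])


@pytest.fixture(scope="session")
def cousin_pedigree():
    """First cousins: children of two full-sib parents."""
    return _ped_from_rows([
        ("F1", "gpa", "", "", "male", True, False, False, 0),
        ("F1", "gma", "", "", "female", True, False, False, 0),
        ("F1", "p1", "gpa", "gma", "male", False, True, False, 1),
        ("F1", "p2", "gpa", "gma", "female", False, True, False, 1),
        ("F1", "s1", "", "", "female", True, True, False, 1),
        ("F1", "s2", "", "", "male", True, True, False, 1),
        ("F1", "c1", "p1", "s1", "male", False, True, False, 2),
        ("F1", "c2", "s2", "p2", "female", False, True, False, 2),
    ])


@pytest.fixture(scope="session")
def cohort_pedigree():
    """Default 108-family synthetic cohort (session-cached for speed)."""
    from aortaflow import simulate_pedigrees

    return simulate_pedigrees(108, seed=20_001)


@pytest.fixture(scope="session")
def cohort_kinship(cohort_pedigree):
    from aortaflow import kinship_matrix

    return kinship_matrix(cohort_pedigree)
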