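import pandas as pd
import pytest

from pgxreg import make_fixture


def build_table1_cohort() -> pd.DataFrame:
    """Phased genotype table matching the published cohort's genotype margins.

    rs4244285: A/A 95, G/A 1288, G/G 3636; rs12248560: C/C 3274, C/T 1565,
    T/T 180; 296 phased double heterozygotes (*2/*17).
    """
    blocks = [
        (95, ("A", "C"), ("A", "C")),     # PM  *2/*2
        (992, ("A", "C"), ("G", "C")),    # IM  *2/*1
        (296, ("A", "C"), ("G", "T")),    # IM+ *2/*17
        (2187, ("G", "C"), ("G", "C")),   # EM  *1/*1
        (1269, ("G", "T"), ("G", "C")),   # EM+ *17/*1
        (180, ("G", "T"), ("G", "T")),    # UM  *17/*17
    ]
    rows = []
    i = 0
    for n, h1, h2 in blocks:
        for _ in range(n):
            rows.append({
                "person_id": f"S{i:05d}",
                "h1_rs4244285": h1[0], "h1_rs12248560": h1[1],
                "h2_rs4244285": h2[0], "h2_rs12248560": h2[1],
            })
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table1_genotypes() -> pd.DataFrame:
    return build_table1_cohort()


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny", seed=3)


@pytest.fixture(scope="session")
def null_fixture():
    return make_fixture("null", seed=5)


def make_persons(ids, death_dates=None, sex="female", birth_year=1970, wave=1):
    """Minimal demographics frame for hand-built outcome tests."""
    n = len(ids)
    death = death_dates if death_dates is not None else [None] * n
    return pd.DataFrame({
        "person_id": list(ids),
        "sex": [sex] * n,
        "birth_year": [birth_year] * n,
        "death_date": pd.to_datetime(pd.Series(death)),
        "wave": [wave] * n,
    })
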