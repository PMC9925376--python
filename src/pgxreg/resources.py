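"""Package defaults: ATC sets, DDD table, ICD-10 mania set, CYP2C rank table.

Everything here is data, not logic, and ships as an editable YAML so that code
sets (which drugs form a group, which diagnosis codes count as mania) can be
swapped without touching the algorithms.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources as _res

import yaml


@lru_cache(maxsize=None)
def defaults() -> dict:
    """Load the shipped defaults.yaml (cached)."""
    text = _res.files("pgxreg").joinpath("data/defaults.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def drug_groups() -> dict[str, list[str]]:
    return {k: list(v) for k, v in defaults()["drug_groups"].items()}


def ddd_mg() -> dict[str, float]:
    return dict(defaults()["ddd_mg"])


def mania_icd10_prefixes() -> frozenset[str]:
    return frozenset(defaults()["mania_icd10_prefixes"])


def mood_stabilizer_atc() -> frozenset[str]:
    return frozenset(defaults()["mood_stabilizer_atc"])


def inducer_inhibitor_atc() -> frozenset[str]:
    d = defaults()
    return frozenset(d["inducer_atc"]) | frozenset(d["inhibitor_atc"])


def cyp2c_rank_table() -> dict[frozenset | tuple, int]:
    """Diplotype -> rank mapping keyed on the sorted pair of haplotype labels."""
    table = {}
    for row in defaults()["cyp2c_rank_table"]:
        key = tuple(sorted(row["haplotypes"]))
        table[key] = int(row["rank"])
    return table


def reference_diplotype() -> tuple[str, str]:
    a, b = defaults()["reference_diplotype"]
    return tuple(sorted((a, b)))
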