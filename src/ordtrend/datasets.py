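"""Packaged worked-example data.

Cell counts of self-reported diabetes (including borderline/
pre-diabetes) and high blood pressure by WHO weight class from the
2007-2008 cycle of a U.S. national health survey, exactly as published;
used by the worked example and the test suite.
"""

from __future__ import annotations

from importlib import resources

from .class_effects import ClassScheme, ContingencyTable, read_contingency_csv, who_bmi_scheme


def _load(name: str) -> tuple[ContingencyTable, ClassScheme]:
    with resources.as_file(resources.files("ordtrend.data").joinpath(name)) as path:
        table, medians = read_contingency_csv(path)
    scheme = who_bmi_scheme()
    if medians != scheme.class_medians:
        raise RuntimeError("packaged fixture medians disagree with WHO scheme")
    return table, scheme


def load_diabetes_table() -> tuple[ContingencyTable, ClassScheme]:
    """Diabetes (or pre/borderline) counts by weight class."""
    return _load("nhanes_diabetes_counts.csv")


def load_blood_pressure_table() -> tuple[ContingencyTable, ClassScheme]:
    """High-blood-pressure counts by weight class."""
    return _load("nhanes_blood_pressure_counts.csv")
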