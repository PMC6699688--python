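"""Shipped fixture tables: printed-table transcriptions used for the
deterministic acceptance checks (combining-ability mean squares, genetic
variance components, SSR locus diversity)."""

from importlib import resources

import pandas as pd

from .study_io import read_fixture_table

__all__ = ["load_mean_squares", "load_variance_components", "load_locus_stats"]


def _path(name: str):
    return resources.files("linetester").joinpath("data", name)


def load_mean_squares() -> pd.DataFrame:
    """Published line x tester ANOVA mean squares (sources x 16 traits,
    plus the df column)."""
    with resources.as_file(_path("table2_mean_squares.csv")) as p:
        return read_fixture_table(p, "mean_squares")


def load_variance_components() -> pd.DataFrame:
    """Published genetic variance components and derived parameters
    (component rows x 16 traits)."""
    with resources.as_file(_path("table3_variance_components.csv")) as p:
        return read_fixture_table(p, "variance_components")


def load_locus_stats() -> pd.DataFrame:
    """Published per-locus SSR diversity statistics (87 loci)."""
    with resources.as_file(_path("table6_locus_stats.csv")) as p:
        return read_fixture_table(p, "locus_stats")
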