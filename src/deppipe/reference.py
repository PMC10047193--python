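"""Bundled worked-example input tables.

Two small TSVs ship with the package: the ranked hub lists produced by
the three topological centralities on an audiogenic-seizure-model
inferior-colliculus PPI network (21 / 21 / 10 nodes for Degree / MCC /
MNC), and the matching epilepsy gene-disease evidence table (14 records
across the knowledge and text-mining channels). They exercise the
consensus-intersection and confidence-filter stages on real published
numbers without any external download.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .datamodel import DiseaseAssociation
from .io import read_disease_table

_DATA = files("deppipe") / "data"


def load_hub_ranked_lists() -> dict[str, list[str]]:
    """The three ranked hub lists, keyed by method (degree, mcc, mnc)."""
    df = pd.read_csv(str(_DATA / "hub_ranked_lists.tsv"), sep="\t")
    return {
        method: group["node"].tolist() for method, group in df.groupby("method")
    }


def load_epilepsy_associations() -> list[DiseaseAssociation]:
    """The 14-record epilepsy gene-disease evidence table."""
    return read_disease_table(str(_DATA / "epilepsy_gene_associations.tsv"))
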