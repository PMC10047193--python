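"""Missing-value handling: exclusive proteins, the NA filter, imputation.

The stage order is fixed and matters. Group-exclusive proteins (all
values missing in one group, at least three present in the other) are
detected on the RAW matrix, because any such protein necessarily fails
the downstream NA filter and would otherwise vanish unreported. Only
then is the matrix filtered (at least ``min_present_per_group`` observed
replicates per group AND at most ``max_total_na`` missing cells per
protein) and the survivors' remaining holes filled by per-sample
(column) mean imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AbundanceDataset


@dataclass(frozen=True)
class ExclusiveRecord:
    """A protein quantified exclusively in one group."""

    protein_id: str
    present_group: str
    n_present: int


@dataclass
class FilterReport:
    """Outcome of the NA filter plus Table-1-style per-sample counts."""

    kept_ids: list[str]
    excluded_ids: list[str]
    na_counts_by_group: pd.DataFrame  # proteins x groups, NA counts
    per_sample_counts: pd.DataFrame  # sample_id, group, n_present, n_missing

    def to_dict(self) -> dict:
        return {
            "n_kept": len(self.kept_ids),
            "n_excluded": len(self.excluded_ids),
            "excluded_ids": self.excluded_ids,
            "per_sample": self.per_sample_counts.to_dict(orient="records"),
        }


def detect_exclusive(
    dataset: AbundanceDataset, min_present: int = 3
) -> list[ExclusiveRecord]:
    """Find proteins whose values exist in one group only.

    A protein is exclusive to group G iff every value in the other group
    is missing and it has at least ``min_present`` observed values in G.
    Run this on the raw dataset, before any filtering or imputation.
    """
    g1, g2 = dataset.groups
    cols = {g: dataset.group_columns(g) for g in (g1, g2)}
    present = ~dataset.mask
    out: list[ExclusiveRecord] = []
    for i, pid in enumerate(dataset.protein_ids):
        n1 = int(present[i, cols[g1]].sum())
        n2 = int(present[i, cols[g2]].sum())
        if n2 == 0 and n1 >= min_present:
            out.append(ExclusiveRecord(pid, g1, n1))
        elif n1 == 0 and n2 >= min_present:
            out.append(ExclusiveRecord(pid, g2, n2))
    return sorted(out, key=lambda r: r.protein_id)


def filter_missingness(
    dataset: AbundanceDataset,
    min_present_per_group: int = 4,
    max_total_na: int = 3,
) -> tuple[AbundanceDataset, FilterReport]:
    """Drop proteins with too many missing values.

    A protein is kept iff it has at least ``min_present_per_group``
    observed values in EACH group and at most ``max_total_na`` missing
    cells in total.
    """
    g1, g2 = dataset.groups
    cols = {g: dataset.group_columns(g) for g in (g1, g2)}
    for g in (g1, g2):
        if min_present_per_group > len(cols[g]):
            raise ValueError(
                f"min_present_per_group={min_present_per_group} exceeds "
                f"size of group {g!r} ({len(cols[g])})"
            )
    mask = dataset.mask
    na1 = mask[:, cols[g1]].sum(axis=1)
    na2 = mask[:, cols[g2]].sum(axis=1)
    present1 = len(cols[g1]) - na1
    present2 = len(cols[g2]) - na2
    keep = (
        (present1 >= min_present_per_group)
        & (present2 >= min_present_per_group)
        & (na1 + na2 <= max_total_na)
    )
    kept_ids = [p for p, k in zip(dataset.protein_ids, keep) if k]
    excluded_ids = [p for p, k in zip(dataset.protein_ids, keep) if not k]

    per_sample = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "group": [dataset.group_of[s] for s in dataset.sample_ids],
            "n_present": (~mask).sum(axis=0),
            "n_missing": mask.sum(axis=0),
        }
    )
    na_by_group = pd.DataFrame(
        {g1: na1, g2: na2}, index=dataset.protein_ids
    )
    report = FilterReport(
        kept_ids=kept_ids,
        excluded_ids=excluded_ids,
        na_counts_by_group=na_by_group,
        per_sample_counts=per_sample,
    )
    return dataset.subset_proteins(kept_ids), report


def impute_sample_mean(
    dataset: AbundanceDataset,
) -> tuple[AbundanceDataset, dict[str, int]]:
    """Replace each missing cell by its sample column's observed mean.

    Column means are computed on the pre-imputation values, so imputation
    leaves every column mean unchanged. Returns the imputed dataset and
    the number of cells imputed per protein.
    """
    values = dataset.values.copy()
    mask = dataset.mask
    col_present = (~mask).sum(axis=0)
    if (col_present == 0).any():
        bad = [s for s, n in zip(dataset.sample_ids, col_present) if n == 0]
        raise ValueError(f"all-missing sample columns: {bad}")
    col_means = np.nanmean(dataset.values, axis=0)
    rows, cols = np.nonzero(mask)
    values[rows, cols] = col_means[cols]
    counts = {
        pid: int(mask[i].sum()) for i, pid in enumerate(dataset.protein_ids)
    }
    out = dataset.copy()
    out.values = values
    return out, counts
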