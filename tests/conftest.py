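from __future__ import annotations

import numpy as np
import pytest

from deppipe.datamodel import AbundanceDataset


def make_dataset(
    values: np.ndarray,
    n_control: int | None = None,
    protein_ids: list[str] | None = None,
    groups: tuple[str, str] = ("CONTROL", "GASH"),
) -> AbundanceDataset:
    """Small-dataset builder: first half of the columns is the control
    group unless n_control says otherwise."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    if n_control is None:
        n_control = n_samp // 2
    sample_ids = [f"{groups[0]}_{j + 1}" for j in range(n_control)] + [
        f"{groups[1]}_{j + 1}" for j in range(n_samp - n_control)
    ]
    group_of = {
        s: groups[0] if j < n_control else groups[1]
        for j, s in enumerate(sample_ids)
    }
    return AbundanceDataset(
        protein_ids=protein_ids or [f"P{i + 1}" for i in range(n_prot)],
        sample_ids=sample_ids,
        group_of=group_of,
        values=values,
    )


@pytest.fixture
def two_group_dataset() -> AbundanceDataset:
    """3 proteins x (3 + 3) samples, one missing cell."""
    values = np.array(
        [
            [10.0, 11.0, 12.0, 13.0, 14.0, 15.0],
            [20.0, 21.0, np.nan, 22.0, 23.0, 24.0],
            [5.0, 5.5, 6.0, 5.2, 5.7, 6.2],
        ]
    )
    return make_dataset(values)
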