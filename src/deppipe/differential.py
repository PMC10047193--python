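"""Per-protein differential expression by effect size.

For every protein the two groups are compared with a two-sample t-test
(Welch by default; Student's pooled-variance t optionally) and the
effect quantified as Cohen's d:

    FC       = mean_case - mean_control          (log units)
    pooled_s = sqrt((s_control^2 + s_case^2) / 2)
    d        = FC / pooled_s

A protein is called up-regulated when p < p_cutoff and d > d_cutoff,
down-regulated when p < p_cutoff and d < -d_cutoff (strict inequalities
throughout, so boundary ties are never called). Because the abundances
are on a log scale, FC is a log fold change; both FC and d are reported
for every protein. No multiple-testing correction is applied by default.

Large-|FC| outliers among the called DEPs are flagged by a parametric
cut-off: mean(|FC|) + 2 * SD(|FC|), computed over DEPs only.

The module is organised statsmodels-style: build a
:class:`DifferentialExpression` model from an imputed dataset, call
``fit()``, and read estimates off the returned
:class:`DifferentialResults` (``.records``, ``.summary()``,
``.volcano_table()``, ``.detect_outliers()``). Thin functional wrappers
(:func:`dep_statistics`, :func:`classify_deps`, ...) cover script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceDataset

P_FLOOR = 1e-300  # keeps -log10(p) finite on the volcano scale


@dataclass
class DepRecord:
    """Per-protein differential statistics."""

    protein_id: str
    mean_control: float
    mean_case: float
    sd_control: float
    sd_case: float
    fc: float
    pooled_sd: float
    cohen_d: float
    p_value: float
    n_imputed: int = 0
    direction: str = "ns"
    degenerate: bool = False


@dataclass
class OutlierReport:
    """Parametric |FC| outlier call over the DEP set."""

    cutoff: float
    mean_abs_lfc: float
    sd_abs_lfc: float
    up_outliers: list[str] = field(default_factory=list)
    down_outliers: list[str] = field(default_factory=list)

    @property
    def outlier_ids(self) -> list[str]:
        return self.up_outliers + self.down_outliers


class DifferentialExpression:
    """Two-group differential-expression model over an imputed matrix.

    Parameters
    ----------
    dataset : AbundanceDataset
        Must contain no missing values (run the missingness stage first).
    imputation_counts : dict, optional
        Per-protein number of imputed cells, carried into the records.
    control_group, case_group : str, optional
        Which group label plays control / case; default is file order
        (first-seen group = control). FC is case minus control.
    test : {"welch", "student"}
        Welch's unequal-variance t (default) or Student's pooled t.
    """

    def __init__(
        self,
        dataset: AbundanceDataset,
        imputation_counts: dict[str, int] | None = None,
        control_group: str | None = None,
        case_group: str | None = None,
        test: str = "welch",
    ) -> None:
        if dataset.mask.any():
            raise ValueError("dataset contains missing values; impute first")
        if test not in ("welch", "student"):
            raise ValueError(f"unknown test {test!r}")
        groups = dataset.groups
        self.control_group = control_group or groups[0]
        self.case_group = case_group or next(
            g for g in groups if g != self.control_group
        )
        if {self.control_group, self.case_group} != set(groups):
            raise ValueError("control/case labels do not match dataset groups")
        for g in groups:
            if len(dataset.samples_in_group(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        self.dataset = dataset
        self.imputation_counts = imputation_counts or {}
        self.test = test

    def fit(
        self, p_cutoff: float = 0.05, d_cutoff: float = 2.0
    ) -> "DifferentialResults":
        ds = self.dataset
        ctrl = ds.values[:, ds.group_columns(self.control_group)]
        case = ds.values[:, ds.group_columns(self.case_group)]

        mean_c = ctrl.mean(axis=1)
        mean_g = case.mean(axis=1)
        sd_c = ctrl.std(axis=1, ddof=1)
        sd_g = case.std(axis=1, ddof=1)
        fc = mean_g - mean_c
        pooled = np.sqrt((sd_c**2 + sd_g**2) / 2.0)
        degenerate = pooled == 0.0

        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(degenerate, np.nan, fc / np.where(degenerate, 1.0, pooled))
        # exact equality of all values in both groups: a zero effect, not a
        # degenerate one-sided blow-up
        zero_effect = degenerate & (fc == 0.0)
        d = np.where(zero_effect, 0.0, d)

        equal_var = self.test == "student"
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
        p = np.where(degenerate, np.nan, p)
        p = np.where(zero_effect, 1.0, p)

        records: list[DepRecord] = []
        for i, pid in enumerate(ds.protein_ids):
            records.append(
                DepRecord(
                    protein_id=pid,
                    mean_control=float(mean_c[i]),
                    mean_case=float(mean_g[i]),
                    sd_control=float(sd_c[i]),
                    sd_case=float(sd_g[i]),
                    fc=float(fc[i]),
                    pooled_sd=float(pooled[i]),
                    cohen_d=float(d[i]) if not np.isnan(d[i]) else float("nan"),
                    p_value=float(p[i]) if not np.isnan(p[i]) else float("nan"),
                    n_imputed=int(self.imputation_counts.get(pid, 0)),
                    degenerate=bool(degenerate[i] and not zero_effect[i]),
                )
            )
        _classify_inplace(records, p_cutoff, d_cutoff)
        return DifferentialResults(
            model=self, records=records, p_cutoff=p_cutoff, d_cutoff=d_cutoff
        )


class DifferentialResults:
    """Fitted differential-expression results."""

    def __init__(
        self,
        model: DifferentialExpression,
        records: list[DepRecord],
        p_cutoff: float,
        d_cutoff: float,
    ) -> None:
        self.model = model
        self.records = records
        self.p_cutoff = p_cutoff
        self.d_cutoff = d_cutoff

    @property
    def up(self) -> list[DepRecord]:
        return [r for r in self.records if r.direction == "up"]

    @property
    def down(self) -> list[DepRecord]:
        return [r for r in self.records if r.direction == "down"]

    @property
    def ns(self) -> list[DepRecord]:
        return [r for r in self.records if r.direction == "ns"]

    @property
    def deps(self) -> list[DepRecord]:
        return [r for r in self.records if r.direction != "ns"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def volcano_table(self) -> pd.DataFrame:
        """Rows (protein_id, cohen_d, -log10 p, direction); degenerate
        records are excluded and p is floored so the y-axis stays finite."""
        rows = [
            {
                "protein_id": r.protein_id,
                "cohen_d": r.cohen_d,
                "neg_log10_p": -np.log10(max(r.p_value, P_FLOOR)),
                "direction": r.direction,
            }
            for r in self.records
            if not r.degenerate
        ]
        return pd.DataFrame(rows)

    def detect_outliers(self) -> OutlierReport:
        return detect_outliers(self.deps)

    def summary(self) -> str:
        n = len(self.records)
        n_sig_p = sum(
            1
            for r in self.records
            if not r.degenerate and r.p_value < self.p_cutoff
        )
        n_deg = sum(1 for r in self.records if r.degenerate)
        lines = [
            "Differential expression summary",
            "=" * 47,
            f"test: {self.model.test} two-sample t (two-sided)",
            f"contrast: {self.model.case_group} - {self.model.control_group}",
            f"proteins tested:            {n}",
            f"p < {self.p_cutoff:g}:                  {n_sig_p}",
            f"up   (p<{self.p_cutoff:g} & d>{self.d_cutoff:g}):    {len(self.up)}",
            f"down (p<{self.p_cutoff:g} & d<-{self.d_cutoff:g}):   {len(self.down)}",
            f"degenerate (zero variance): {n_deg}",
        ]
        deps = self.deps
        if len(deps) >= 2:
            rep = self.detect_outliers()
            lines.append(f"|FC| outlier cutoff:        {rep.cutoff:.3f}")
            lines.append(
                f"outliers (up/down):         "
                f"{len(rep.up_outliers)}/{len(rep.down_outliers)}"
            )
        return "\n".join(lines)


def _classify_inplace(
    records: list[DepRecord], p_cutoff: float, d_cutoff: float
) -> None:
    for r in records:
        if r.degenerate or np.isnan(r.p_value):
            r.direction = "ns"
        elif r.p_value < p_cutoff and r.cohen_d > d_cutoff:
            r.direction = "up"
        elif r.p_value < p_cutoff and r.cohen_d < -d_cutoff:
            r.direction = "down"
        else:
            r.direction = "ns"


def dep_statistics(
    dataset: AbundanceDataset,
    imputation_counts: dict[str, int] | None = None,
    control_group: str | None = None,
    case_group: str | None = None,
    test: str = "welch",
    p_cutoff: float = 0.05,
    d_cutoff: float = 2.0,
) -> list[DepRecord]:
    """Per-protein statistics for an imputed, two-group dataset."""
    model = DifferentialExpression(
        dataset,
        imputation_counts=imputation_counts,
        control_group=control_group,
        case_group=case_group,
        test=test,
    )
    return model.fit(p_cutoff=p_cutoff, d_cutoff=d_cutoff).records


def classify_deps(
    records: list[DepRecord], p_cutoff: float = 0.05, d_cutoff: float = 2.0
) -> tuple[list[DepRecord], list[DepRecord], list[DepRecord]]:
    """Partition records into (up, down, ns) under strict cut-offs."""
    _classify_inplace(records, p_cutoff, d_cutoff)
    up = [r for r in records if r.direction == "up"]
    down = [r for r in records if r.direction == "down"]
    ns = [r for r in records if r.direction == "ns"]
    return up, down, ns


def detect_outliers(dep_records: list[DepRecord], k: float = 2.0) -> OutlierReport:
    """Flag DEPs whose |FC| exceeds mean(|FC|) + k * SD(|FC|).

    Computed over the called DEPs only (sample SD, n-1); strict
    inequality, so when all |FC| coincide nothing is flagged.
    """
    if len(dep_records) < 2:
        raise ValueError("need at least 2 DEPs to estimate an outlier cutoff")
    abs_fc = np.array([abs(r.fc) for r in dep_records])
    mean = float(abs_fc.mean())
    sd = float(abs_fc.std(ddof=1))
    cutoff = mean + k * sd
    up = [r.protein_id for r in dep_records if r.direction == "up" and abs(r.fc) > cutoff]
    down = [
        r.protein_id for r in dep_records if r.direction == "down" and abs(r.fc) > cutoff
    ]
    return OutlierReport(
        cutoff=cutoff,
        mean_abs_lfc=mean,
        sd_abs_lfc=sd,
        up_outliers=sorted(up),
        down_outliers=sorted(down),
    )


def volcano_table(records: list[DepRecord]) -> pd.DataFrame:
    """Volcano-plot coordinates (Cohen's d vs -log10 p) for all
    non-degenerate records."""
    rows = [
        {
            "protein_id": r.protein_id,
            "cohen_d": r.cohen_d,
            "neg_log10_p": -np.log10(max(r.p_value, P_FLOOR)),
            "direction": r.direction,
        }
        for r in records
        if not r.degenerate
    ]
    return pd.DataFrame(rows)
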