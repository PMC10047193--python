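"""Direction x category association by Monte-Carlo chi-squared.

Counts of up- vs down-regulated DEPs per ontology category form a
contingency table. The chi-squared statistic on that table is compared
against null tables drawn with the observed margins fixed (Patefield's
algorithm), giving a simulation p-value

    p = (1 + #{simulated chi2 >= observed}) / (n_sim + 1)

that is valid at any table size, with no minimum-expected-count caveat.
Pearson residuals (obs - exp) / sqrt(exp) localise the association:
a cell is significant when |residual| > 2, and for display each cell
gets a confidence band from standard-normal quantiles of the residual
(1.645 / 1.960 / 2.241 / 2.576 -> "." / "*" / "**").

Model/Results style: :class:`CategoryAssociation` is built from the DEP
direction lists and an annotation table; ``fit()`` returns an
:class:`AssociationResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnnotationTable

logger = logging.getLogger(__name__)

# standard-normal quantiles for 90 / 95 / 97.5 / 99% two-sided confidence
_BAND_EDGES = (1.6448536269514722, 1.959963984540054, 2.241402727604947,
               2.5758293035489004)
_BAND_LABELS = ("n.s.", "•", "*", "**")


@dataclass
class AssociationResult:
    """Chi-squared association between DEP direction and categories."""

    ontology: str
    contingency: pd.DataFrame  # categories x {up, down}
    chi2_statistic: float
    mc_p_value: float
    n_sim: int
    seed: int
    residuals: pd.DataFrame
    bands: pd.DataFrame
    significant_cells: list[tuple[str, str]]
    n_unannotated: int = 0

    def summary(self) -> str:
        lines = [
            f"Direction x category association ({self.ontology})",
            "=" * 47,
            f"chi-squared statistic: {self.chi2_statistic:.4f}",
            f"Monte-Carlo p-value:   {self.mc_p_value:.5f} "
            f"(n_sim={self.n_sim}, seed={self.seed})",
            f"significant cells (|Pearson residual| > 2): "
            f"{len(self.significant_cells)}",
        ]
        for cat, direction in self.significant_cells:
            r = self.residuals.loc[cat, direction]
            lines.append(f"  {cat} / {direction}: residual {r:+.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ontology": self.ontology,
            "contingency": self.contingency.to_dict(),
            "chi2_statistic": self.chi2_statistic,
            "mc_p_value": self.mc_p_value,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "residuals": self.residuals.to_dict(),
            "bands": self.bands.to_dict(),
            "significant_cells": [list(c) for c in self.significant_cells],
            "n_unannotated": self.n_unannotated,
        }


def build_contingency(
    deps_up: list[str],
    deps_down: list[str],
    annotations: AnnotationTable,
    ontology: str,
) -> tuple[pd.DataFrame, int]:
    """Count up/down DEPs per category of one ontology.

    A DEP annotated to several categories contributes once to each;
    unannotated DEPs are dropped (their count is returned and logged).
    """
    ann = annotations.for_ontology(ontology)
    cat_of: dict[str, list[str]] = {}
    for r in ann.itertuples(index=False):
        cat_of.setdefault(r.id, []).append(r.category)
    annotated = set(cat_of)
    n_unannotated = sum(1 for d in list(deps_up) + list(deps_down) if d not in annotated)
    if not (set(deps_up) | set(deps_down)) & annotated:
        raise ValueError(
            f"no DEP has a {ontology} annotation: id spaces do not intersect"
        )
    if n_unannotated:
        logger.info(
            "%s: %d DEPs without annotation dropped", ontology, n_unannotated
        )
    categories = sorted({c for cats in cat_of.values() for c in cats})
    table = pd.DataFrame(0, index=categories, columns=["up", "down"])
    for direction, deps in (("up", deps_up), ("down", deps_down)):
        for dep in deps:
            for cat in cat_of.get(dep, ()):
                table.loc[cat, direction] += 1
    return table, n_unannotated


def _chi2_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    nz = expected > 0
    return float((((obs - expected) ** 2)[nz] / expected[nz]).sum())


def _expected(obs: np.ndarray) -> np.ndarray:
    total = obs.sum()
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total


def monte_carlo_chisq(
    contingency: pd.DataFrame | np.ndarray,
    n_sim: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chi-squared statistic with a fixed-margins simulation p-value.

    Null tables share the observed row and column sums (Patefield
    sampling via :func:`scipy.stats.random_table`). Rows or columns with
    zero margin contribute nothing to the statistic under any null table
    and are removed before sampling.
    """
    obs = np.asarray(contingency, dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must hold non-negative integers")
    if obs.sum() == 0:
        raise ValueError("all-zero contingency table")
    expected = _expected(obs)
    chi2 = _chi2_stat(obs, expected)

    rows = obs.sum(axis=1) > 0
    cols = obs.sum(axis=0) > 0
    trimmed = obs[np.ix_(rows, cols)]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        # margins admit only one table: the statistic is identically 0
        return chi2, 1.0
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(
        trimmed.sum(axis=1).astype(int), trimmed.sum(axis=0).astype(int)
    )
    sims = sampler.rvs(size=n_sim, method="patefield", random_state=rng)
    exp_t = _expected(trimmed)
    nz = exp_t > 0
    sim_chi2 = (((sims - exp_t) ** 2)[..., nz] / exp_t[nz]).sum(axis=-1)
    n_ge = int((sim_chi2 >= chi2 - 1e-12).sum())
    mc_p = (1 + n_ge) / (n_sim + 1)
    return chi2, float(mc_p)


def pearson_residual_bands(
    contingency: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Pearson residuals with display bands and the |r| > 2 call.

    Cells with zero expected count get NaN residuals and the band
    "undef". Residuals at or beyond 2.576 are reported as "**" (the
    strongest band) with a log note.
    """
    obs = contingency.to_numpy(dtype=float)
    expected = _expected(obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (obs - expected) / np.sqrt(expected)
    res[expected == 0] = np.nan
    residuals = pd.DataFrame(
        res, index=contingency.index, columns=contingency.columns
    )

    def band(r: float) -> str:
        if np.isnan(r):
            return "undef"
        a = abs(r)
        if a >= _BAND_EDGES[3]:
            logger.info("residual %.3f beyond the 99%% band, shown as '**'", r)
            return "**"
        for edge, label in zip(_BAND_EDGES[:3][::-1], _BAND_LABELS[:0:-1]):
            if a >= edge:
                return label
        return "n.s."

    bands = residuals.map(band)
    significant = [
        (cat, direction)
        for cat in contingency.index
        for direction in contingency.columns
        if abs(residuals.loc[cat, direction]) > 2
    ]
    return residuals, bands, significant


class CategoryAssociation:
    """Association model between DEP direction and one ontology's categories."""

    def __init__(
        self,
        deps_up: list[str],
        deps_down: list[str],
        annotations: AnnotationTable,
        ontology: str,
    ) -> None:
        self.deps_up = list(deps_up)
        self.deps_down = list(deps_down)
        self.annotations = annotations
        self.ontology = ontology

    def fit(self, n_sim: int = 2000, seed: int = 0) -> AssociationResult:
        table, n_unannotated = build_contingency(
            self.deps_up, self.deps_down, self.annotations, self.ontology
        )
        chi2, mc_p = monte_carlo_chisq(table, n_sim=n_sim, seed=seed)
        residuals, bands, significant = pearson_residual_bands(table)
        return AssociationResult(
            ontology=self.ontology,
            contingency=table,
            chi2_statistic=chi2,
            mc_p_value=mc_p,
            n_sim=n_sim,
            seed=seed,
            residuals=residuals,
            bands=bands,
            significant_cells=significant,
            n_unannotated=n_unannotated,
        )
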