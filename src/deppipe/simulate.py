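"""Seeded synthetic data with planted ground truth.

The generator emulates the kind of dataset the pipeline targets: a
label-free DIA proteome quantified over two groups of six replicates,
~5000 proteins on a log-abundance scale, sparse missingness, a small
fraction of proteins with a real group effect, a few of those with an
extreme effect, and a handful of proteins detected exclusively in one
group. Matching synthetic PPI networks, ontology annotations and
gene-disease tables are generated with their own planted structure, and
every generator returns a :class:`SyntheticTruth` so recovery can be
scored exactly.

Planted effects are parameterised directly in Cohen's-d units: the case
group's mean shift for a planted protein is ``d * within_sd``, so the
population effect size equals ``d`` and downstream recovery tests can
address the DEP-calling cut-off (|d| > 2) without conversion.

Every generator is a pure function of its parameters and seed: the same
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceDataset,
    AnnotationTable,
    DiseaseAssociation,
    PpiNetwork,
)

ONTOLOGY_LIST = ("GO-CC", "GO-BP", "GO-MF", "KOG")


@dataclass
class SimulationParams:
    """Knobs of the abundance-matrix simulator.

    Defaults describe a 2 x 6 replicate design of 5000 proteins with
    baseline log abundance ~ Normal(20, 2), within-group SD 0.5 log
    units, 3% planted differential proteins with |d| uniform in [2, 5]
    (random sign), 2% of those with an extreme effect (|d| >= 8), 1.5%
    missing-completely-at-random cells, and 10 exclusive proteins per
    group (all values missing in the other group, at least 3 present).
    """

    n_proteins: int = 5000
    n_reps_per_group: int = 6
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    within_sd: float = 0.5
    frac_dep: float = 0.03
    effect_size_range: tuple[float, float] = (2.0, 5.0)
    frac_outlier_dep: float = 0.02
    outlier_effect_range: tuple[float, float] = (8.0, 12.0)
    missing_rate: float = 0.015
    missing_mechanism: str = "mcar"  # or "mnar" (intensity-dependent)
    n_exclusive_per_group: int = 10
    group_labels: tuple[str, str] = ("CONTROL", "GASH")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dep", "frac_outlier_dep", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_proteins", "n_reps_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_exclusive_per_group < 0:
            raise ValueError("n_exclusive_per_group must be >= 0")
        if self.missing_mechanism not in ("mcar", "mnar"):
            raise ValueError(f"unknown missing mechanism {self.missing_mechanism!r}")
        n_dep = round(self.frac_dep * self.n_proteins)
        if 2 * self.n_exclusive_per_group + n_dep > self.n_proteins:
            raise ValueError(
                "exclusive + DEP allocation exceeds the number of proteins"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to each generated object."""

    seed: int
    params: dict = field(default_factory=dict)
    dep_effects: dict[str, float] = field(default_factory=dict)  # id -> signed d
    exclusive_ids: dict[str, list[str]] = field(default_factory=dict)  # group -> ids
    outlier_ids: list[str] = field(default_factory=list)
    hub_ids: list[str] = field(default_factory=list)
    enriched_categories: dict[str, dict[str, str]] = field(default_factory=dict)
    high_score_genes: list[str] = field(default_factory=list)

    @property
    def dep_ids(self) -> list[str]:
        return sorted(self.dep_effects)


def generate_abundance_dataset(
    params: SimulationParams,
) -> tuple[AbundanceDataset, SyntheticTruth]:
    """Simulate the log-abundance matrix and its planted truth.

    Per protein: baseline ~ Normal(baseline_mean, baseline_sd);
    replicate values ~ Normal(baseline [+ d * within_sd in the case
    group], within_sd). Missingness is applied everywhere except the
    planted-exclusive rows, whose pattern is set explicitly.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n, r = p.n_proteins, p.n_reps_per_group
    ctrl_label, case_label = p.group_labels

    width = max(5, len(str(n)))
    protein_ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    gene_symbols = [f"GENE{i:0{width}d}" for i in range(1, n + 1)]
    sample_ids = [f"{ctrl_label}_{j + 1}" for j in range(r)] + [
        f"{case_label}_{j + 1}" for j in range(r)
    ]
    group_of = {s: (ctrl_label if j < r else case_label) for j, s in enumerate(sample_ids)}

    n_dep = round(p.frac_dep * n)
    n_excl = p.n_exclusive_per_group
    special = rng.choice(n, size=n_dep + 2 * n_excl, replace=False)
    dep_idx = special[:n_dep]
    excl_ctrl_idx = special[n_dep : n_dep + n_excl]  # present in control only
    excl_case_idx = special[n_dep + n_excl :]

    d = rng.uniform(*p.effect_size_range, size=n_dep)
    n_out = round(p.frac_outlier_dep * n_dep)
    out_pos = rng.choice(n_dep, size=n_out, replace=False) if n_out else np.array([], int)
    d[out_pos] = rng.uniform(*p.outlier_effect_range, size=n_out)
    signs = rng.choice([-1.0, 1.0], size=n_dep)
    d *= signs

    baseline = rng.normal(p.baseline_mean, p.baseline_sd, size=n)
    mean = np.tile(baseline[:, None], (1, 2 * r))
    delta = np.zeros(n)
    delta[dep_idx] = d * p.within_sd
    mean[:, r:] += delta[:, None]
    values = rng.normal(mean, p.within_sd)

    if p.missing_mechanism == "mcar":
        miss = rng.random(values.shape) < p.missing_rate
    else:
        # intensity-dependent: missingness probability decays with rank of
        # the value, normalised so the expected overall rate is missing_rate
        order = values.argsort(axis=None).argsort().reshape(values.shape)
        w = 1.0 - order / values.size  # low values -> weight near 1
        w *= p.missing_rate * values.size / w.sum()
        miss = rng.random(values.shape) < np.clip(w, 0, 1)

    # exclusive rows override the random mask with their exact pattern
    for idx_set, present_cols, absent_cols in (
        (excl_ctrl_idx, np.arange(r), np.arange(r, 2 * r)),
        (excl_case_idx, np.arange(r, 2 * r), np.arange(r)),
    ):
        for i in idx_set:
            miss[i, :] = False
            miss[i, absent_cols] = True
            n_present = int(rng.integers(min(3, r), r + 1))
            hidden = rng.choice(present_cols, size=r - n_present, replace=False)
            miss[i, hidden] = True

    values[miss] = np.nan

    truth = SyntheticTruth(
        seed=p.seed,
        params=asdict(p),
        dep_effects={protein_ids[i]: float(dv) for i, dv in zip(dep_idx, d)},
        exclusive_ids={
            ctrl_label: sorted(protein_ids[i] for i in excl_ctrl_idx),
            case_label: sorted(protein_ids[i] for i in excl_case_idx),
        },
        outlier_ids=sorted(protein_ids[dep_idx[j]] for j in out_pos),
    )
    dataset = AbundanceDataset(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        group_of=group_of,
        values=values,
        gene_symbols=gene_symbols,
    )
    return dataset, truth


def generate_ppi_network(
    n_background: int = 100,
    n_hubs: int = 5,
    clique_size: int = 4,
    seed: int = 0,
    cliques_per_hub: int = 3,
    background_p: float = 0.02,
) -> tuple[PpiNetwork, SyntheticTruth]:
    """Sparse random background plus planted clique hubs.

    Each planted hub sits in ``cliques_per_hub`` disjoint maximal
    cliques of ``clique_size`` nodes (fresh members per clique), which
    makes it dominate Degree, MNC and MCC simultaneously. Edge scores
    are uniform in [0.9, 1.0].
    """
    if n_background <= 0 or clique_size < 2 or n_hubs < 0:
        raise ValueError("counts must be positive (clique_size >= 2)")
    rng = np.random.default_rng(seed)
    net = PpiNetwork()
    bg = [f"BG{i:04d}" for i in range(n_background)]
    net.graph.add_nodes_from(bg)
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < background_p:
                net.add_edge(bg[i], bg[j], float(rng.uniform(0.9, 1.0)))
    hubs = [f"HUB{i:02d}" for i in range(n_hubs)]
    for h, hub in enumerate(hubs):
        for c in range(cliques_per_hub):
            members = [hub] + [
                f"M{h:02d}_{c}_{k}" for k in range(clique_size - 1)
            ]
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    net.add_edge(
                        members[a_i], members[b_i], float(rng.uniform(0.9, 1.0))
                    )
    truth = SyntheticTruth(seed=seed, hub_ids=sorted(hubs))
    return net, truth


def generate_annotation_table(
    protein_ids: list[str],
    dep_effects: dict[str, float],
    enrichment_factor: float = 1.0,
    seed: int = 0,
    n_categories: int = 4,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Assign one category per ontology per protein, multinomially.

    Under ``enrichment_factor=1`` categories are independent of DEP
    direction (the null). Otherwise one designated category per ontology
    is over-represented among up-regulated planted DEPs by the factor,
    and a second one among down-regulated DEPs.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    enriched: dict[str, dict[str, str]] = {}
    for ont in ONTOLOGY_LIST:
        cats = [f"{ont}_cat{k + 1}" for k in range(n_categories)]
        enriched[ont] = {"up": cats[0], "down": cats[1]}
        base = np.ones(n_categories)
        p_up = base.copy()
        p_up[0] *= enrichment_factor
        p_down = base.copy()
        p_down[1] *= enrichment_factor
        for pid in protein_ids:
            d = dep_effects.get(pid)
            if d is None or enrichment_factor == 1:
                probs = base
            elif d > 0:
                probs = p_up
            else:
                probs = p_down
            cat = cats[rng.choice(n_categories, p=probs / probs.sum())]
            records.append({"id": pid, "ontology": ont, "category": cat})
    truth = SyntheticTruth(
        seed=seed, dep_effects=dict(dep_effects), enriched_categories=enriched
    )
    return AnnotationTable(records=pd.DataFrame(records)), truth


def generate_disease_table(
    genes: list[str],
    n_high: int = 10,
    threshold: float = 2.0,
    seed: int = 0,
) -> tuple[list[DiseaseAssociation], SyntheticTruth]:
    """Give exactly ``n_high`` genes a record scoring above ``threshold``."""
    if n_high > len(genes):
        raise ValueError("n_high exceeds the number of genes")
    rng = np.random.default_rng(seed)
    high = sorted(rng.choice(len(genes), size=n_high, replace=False).tolist())
    high_set = {genes[i] for i in high}
    channels = ("knowledge", "experimental", "textmining")
    records = []
    for g in genes:
        if g in high_set:
            score = float(rng.uniform(threshold + 0.1, threshold + 2.0))
            channel = channels[int(rng.integers(0, 3))]
        else:
            score = float(rng.uniform(0.0, threshold))
            channel = channels[int(rng.integers(0, 3))]
        records.append(
            DiseaseAssociation(
                gene=g,
                disease_id="DOID:1826",
                disease_name="Epilepsy",
                channel=channel,
                score=score,
            )
        )
    truth = SyntheticTruth(seed=seed, high_score_genes=sorted(high_set))
    return records, truth
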