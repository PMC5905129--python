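"""Ground-truth synthetic inputs for every pipeline stage.

Three generators with explicit, seeded randomness:

* two-group expression matrices with module-structured planted signal,
* isotopologue panels under configured tracer fluxes and natural abundance,
* dual-tracer DNA-nucleoside panels with known source fractions.

Each generator's truth object is the reference the downstream estimators
are validated against (parameter recovery is the pipeline's principal
acceptance surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .gsea import ExpressionDataset, NodeSetCollection
from .mid import MIDPanel, build_correction_matrix, parse_formula
from .sources import DualTracerPanel

__all__ = [
    "ExpressionTruth",
    "FluxTruth",
    "SourceTruth",
    "gen_node_sets",
    "gen_expression_dataset",
    "gen_mid_panel",
    "gen_dual_tracer_panel",
]


def _lognormal_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean; sd is the CV of the factor."""
    if sd == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(sd**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=shape)


@dataclass
class ExpressionTruth:
    """Planted two-group differential signal at module granularity."""

    planted_modules: Mapping[str, int] = field(default_factory=dict)  # module -> +1/-1
    effect_size: float = 0.0  # group-mean shift in units of within-group SD
    group_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for sign in self.planted_modules.values():
            if sign not in (+1, -1):
                raise ValueError("planted direction must be +1 or -1")


@dataclass
class FluxTruth:
    """True tracer fractional contributions per metabolite and group."""

    fc: Mapping[str, Mapping[str, float]]  # metabolite -> group -> FC
    formulas: Mapping[str, str]  # metabolite -> elemental formula
    tracer_enrichment: float = 0.5
    noise_sd: float = 0.05
    natural_abundance: bool = True
    base_intensity: float = 1e6
    tracer_element: str = "C"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tracer_enrichment <= 1):
            raise ValueError("tracer_enrichment must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        groups = None
        for met, per_group in self.fc.items():
            if met not in self.formulas:
                raise ValueError(f"no formula for metabolite {met!r}")
            if parse_formula(self.formulas[met]).get(self.tracer_element, 0) < 1:
                raise ValueError(f"{met!r} has no {self.tracer_element} atoms")
            if groups is None:
                groups = set(per_group)
            elif set(per_group) != groups:
                raise ValueError("all metabolites must list the same groups")
            for g, f in per_group.items():
                if not (0 <= f <= 1):
                    raise ValueError(f"FC must lie in [0,1], got {f} for {met}/{g}")
                if f > self.tracer_enrichment + 1e-12:
                    raise ValueError(
                        f"true FC {f} exceeds tracer enrichment "
                        f"{self.tracer_enrichment} for {met}/{g} (unreachable labeling)"
                    )

    @property
    def groups(self) -> list[str]:
        return list(next(iter(self.fc.values())))


@dataclass
class SourceTruth:
    """True partition of DNA dC between pre-existing, de novo and salvage."""

    f_preexisting: float
    f_denovo: float
    f_salvage: float
    total_intensity: float = 1e6
    denovo_shift_dist: Mapping[int, float] = field(default_factory=lambda: {5: 1.0})
    salvage_carbon_shift: int = 9
    noise_sd: float = 0.05
    label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.f_preexisting, self.f_denovo, self.f_salvage)
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("source fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ValueError("source fractions must sum to 1")
        if self.total_intensity <= 0:
            raise ValueError("total intensity must be positive")
        if abs(sum(self.denovo_shift_dist.values()) - 1.0) > 1e-9:
            raise ValueError("de novo shift distribution must sum to 1")
        for shift in self.denovo_shift_dist:
            if shift < 1:
                raise ValueError("de novo carbon shifts must be >= 1")


def gen_node_sets(
    n_modules: int,
    nodes_per_module: int = 8,
    n_extra_nodes: int = 0,
    disjoint: bool = True,
    seed: int = 0,
) -> NodeSetCollection:
    """Random KEGG-module-style collection over synthetic EC node ids.

    With ``disjoint`` each module owns its own nodes (independent module
    statistics); otherwise members are drawn with replacement from the
    shared universe.
    """
    rng = np.random.default_rng(seed)
    if disjoint:
        n_nodes = n_modules * nodes_per_module + n_extra_nodes
        nodes = [f"ec:{i:05d}" for i in range(n_nodes)]
        perm = rng.permutation(n_nodes)
        sets = {
            f"M{m:04d}": frozenset(
                nodes[i] for i in perm[m * nodes_per_module : (m + 1) * nodes_per_module]
            )
            for m in range(n_modules)
        }
    else:
        n_nodes = max(n_modules * nodes_per_module // 2, nodes_per_module) + n_extra_nodes
        nodes = np.array([f"ec:{i:05d}" for i in range(n_nodes)], dtype=object)
        sets = {
            f"M{m:04d}": frozenset(rng.choice(nodes, size=nodes_per_module, replace=False))
            for m in range(n_modules)
        }
    return NodeSetCollection(sets=sets)


def gen_expression_dataset(
    n_probes: int,
    samples_per_group: tuple[int, int],
    node_sets: NodeSetCollection,
    truth: ExpressionTruth,
) -> ExpressionDataset:
    """Two-group expression matrix with planted module signal.

    Background probes are i.i.d. standard normal (log-scale intensities,
    within-group SD 1).  Probes of planted modules get a group-mean
    difference of ``effect_size`` in the planted direction (positive =
    higher in the first group).  Every EC node in the collection maps to
    one gene; at least one node carries two probes so that collapsing is
    exercised; leftover probe budget is spread round-robin as additional
    candidate probes.
    """
    na, nb = samples_per_group
    if na < 1 or nb < 1:
        raise ValueError("both phenotype groups must be non-empty")
    for mid in truth.planted_modules:
        if mid not in node_sets.sets:
            raise ValueError(f"planted module {mid!r} absent from the node-set collection")
    ecs = sorted(set().union(*node_sets.sets.values()))
    if n_probes < len(ecs) + 1:
        raise ValueError(f"need at least {len(ecs) + 1} probes for {len(ecs)} nodes")

    probe_to_gene: dict[str, str] = {}
    gene_to_ec: dict[str, tuple[str, ...]] = {}
    probe_ec: list[str] = []
    probes: list[str] = []
    counter: dict[str, int] = {}

    def add_probe(ec: str) -> None:
        k = counter.get(ec, 0)
        counter[ec] = k + 1
        probe = f"P@{ec}#{k}"
        gene = f"G@{ec}"
        probes.append(probe)
        probe_to_gene[probe] = gene
        gene_to_ec[gene] = (ec,)
        probe_ec.append(ec)

    for ec in ecs:
        add_probe(ec)
    add_probe(ecs[0])  # a second probe on a shared EC: collapsing is exercised
    i = 0
    while len(probes) < n_probes:
        add_probe(ecs[i % len(ecs)])
        i += 1

    if truth.group_labels is not None:
        labels = list(truth.group_labels)
        if len(labels) != na + nb:
            raise ValueError("group_labels length must match total sample count")
        classes = list(dict.fromkeys(labels))
        if len(classes) != 2:
            raise ValueError("group_labels must contain exactly two groups")
    else:
        classes = ["groupA", "groupB"]
        labels = [classes[0]] * na + [classes[1]] * nb
    sample_ids = [f"S{i:03d}" for i in range(len(labels))]

    rng = np.random.default_rng(truth.seed)
    mat = rng.standard_normal((len(probes), len(labels)))
    mask_a = np.array([lab == classes[0] for lab in labels])
    for mid, sign in truth.planted_modules.items():
        members = node_sets[mid]
        rows = [i for i, ec in enumerate(probe_ec) if ec in members]
        mat[np.ix_(rows, mask_a)] += sign * truth.effect_size

    values = pd.DataFrame(mat, index=probes, columns=sample_ids)
    return ExpressionDataset(
        values=values,
        labels=pd.Series(labels, index=sample_ids),
        probe_to_gene=probe_to_gene,
        gene_to_ec=gene_to_ec,
        classes=(classes[0], classes[1]),
    )


def gen_mid_panel(truth: FluxTruth, n_replicates: int) -> MIDPanel:
    """Isotopologue panel under a binomial-mixture labeling model.

    A fraction ``FC / e`` of molecules is tracer-derived with per-atom
    labeling probability ``e`` (the tracer enrichment); the remainder is
    unlabeled.  Natural abundance is then convolved in (unless disabled)
    and multiplicative lognormal noise applied.  Emits per-sample
    internal-standard intensity and cell count.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    e = truth.tracer_enrichment
    groups = truth.groups
    samples = [f"{g}_r{i + 1}" for g in groups for i in range(n_replicates)]
    sample_group = {s: s.rsplit("_r", 1)[0] for s in samples}

    blocks = []
    index = []
    for met in truth.fc:
        n = parse_formula(truth.formulas[met])[truth.tracer_element]
        C = (
            build_correction_matrix(truth.formulas[met], truth.tracer_element)
            if truth.natural_abundance
            else np.eye(n + 1)
        )
        rows = np.zeros((n + 1, len(samples)))
        for j, s in enumerate(samples):
            f = truth.fc[met][sample_group[s]]
            q = f / e  # fraction of molecules that are tracer-derived
            ideal = (1 - q) * np.eye(n + 1)[0] + q * binom.pmf(np.arange(n + 1), n, e)
            observed = C @ ideal * truth.base_intensity
            rows[:, j] = observed * _lognormal_noise(rng, truth.noise_sd, n + 1)
        blocks.append(rows)
        index.extend((met, i) for i in range(n + 1))
    data = pd.DataFrame(
        np.vstack(blocks),
        index=pd.MultiIndex.from_tuples(index, names=["metabolite", "isotopologue_index"]),
        columns=samples,
    )
    samples_frame = pd.DataFrame(
        {
            "internal_standard_intensity": 1e5
            * _lognormal_noise(rng, truth.noise_sd, len(samples)),
            "cell_count": rng.integers(int(9e5), int(1.1e6), size=len(samples)),
            "group": [sample_group[s] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return MIDPanel(
        data=data,
        formulas=pd.Series(dict(truth.formulas)),
        samples=samples_frame,
        tracer_element=truth.tracer_element,
        tracer_enrichment=e,
    )


def gen_dual_tracer_panel(truth: SourceTruth, n_samples: int) -> DualTracerPanel:
    """Dual-tracer dC channel intensities with known source fractions.

    Pre-existing signal sits at (0 carbons, 0 nitrogens); de novo signal is
    nitrogen-free with a carbon shift from ``denovo_shift_dist``
    (concentrated at +5 by default); salvage signal carries three heavy
    nitrogens.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(truth.seed)
    channels: list[tuple[int, int, float]] = [(0, 0, truth.f_preexisting)]
    for shift, prob in sorted(truth.denovo_shift_dist.items()):
        channels.append((shift, 0, truth.f_denovo * prob))
    channels.append((truth.salvage_carbon_shift, 3, truth.f_salvage))
    rows = []
    for i in range(n_samples):
        sample = f"T{i:03d}"
        noise = _lognormal_noise(rng, truth.noise_sd, len(channels))
        for (shift, n15, frac), z in zip(channels, noise):
            rows.append((sample, shift, n15, truth.total_intensity * frac * z))
    data = pd.DataFrame(rows, columns=["sample", "carbon_shift", "n15_count", "intensity"])
    labels = None
    if truth.label is not None:
        labels = pd.Series(truth.label, index=data["sample"].unique())
    return DualTracerPanel(data=data, labels=labels)
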