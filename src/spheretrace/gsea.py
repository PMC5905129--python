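"""Enzyme-activity-collapsed gene-set enrichment.

Probes are collapsed onto enzyme-activity nodes (EC numbers) by retaining,
per node, the candidate probeset with the maximum absolute ranking metric.
Named modules of EC nodes are then scored with a running-sum enrichment
statistic, normalized against a permutation null (NES), filtered by
represented-node count, and compared across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "NodeSetCollection",
    "RankedNodeList",
    "ModuleEnrichment",
    "ConcordanceResult",
    "snr_metric",
    "collapse_to_nodes",
    "enrichment_score",
    "permutation_nes",
    "score_collection",
    "filter_modules",
    "cross_dataset_concordance",
]

SD_FLOOR_REL = 0.2
SD_FLOOR_ABS = 0.005


@dataclass
class ExpressionDataset:
    """Probe-level intensity matrix with a two-class phenotype.

    ``classes[0]`` is the positive direction: positive metrics mean higher
    expression in that class.
    """

    values: pd.DataFrame  # probes x samples
    labels: pd.Series  # sample -> class label
    probe_to_gene: Mapping[str, str]
    gene_to_ec: Mapping[str, Sequence[str]]
    classes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix must be finite")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("every sample needs a phenotype label")
        found = list(pd.unique(self.labels))
        if len(found) != 2:
            raise ValueError(f"exactly two phenotype classes required, got {found}")
        if self.classes is None:
            self.classes = (found[0], found[1])
        elif set(self.classes) != set(found):
            raise ValueError("declared classes do not match labels")
        counts = self.labels.value_counts()
        if counts.min() < 2:
            raise ValueError("need >= 2 samples per class")

    @property
    def class_mask(self) -> np.ndarray:
        """Boolean mask over samples: True for ``classes[0]``."""
        return (self.labels == self.classes[0]).to_numpy()


@dataclass
class NodeSetCollection:
    """Named modules whose members are enzyme-activity node ids."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for mid, members in self.sets.items():
            if not members:
                raise ValueError(f"module {mid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, module_id: str) -> frozenset[str]:
        return self.sets[module_id]

    def display_name(self, module_id: str) -> str:
        return self.names.get(module_id, module_id)


@dataclass
class RankedNodeList:
    """Nodes ordered by descending metric (ties broken by node id)."""

    nodes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=object)
        self.metrics = np.asarray(self.metrics, dtype=float)
        if self.nodes.shape != self.metrics.shape:
            raise ValueError("nodes and metrics must be aligned")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids in ranked list")

    def __len__(self) -> int:
        return len(self.nodes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.metrics, index=self.nodes)


@dataclass
class ModuleEnrichment:
    module_id: str
    n_nodes: int
    es: float
    nes: float
    p: float
    enriched_in: str
    q: float = float("nan")
    flagged: bool = False


@dataclass
class ConcordanceResult:
    nes_pairs: pd.DataFrame  # module x {nes_a, nes_b}
    pearson: float
    spearman: float
    tau: float
    shared_up: list[str]
    shared_down: list[str]


def _floored_sd(x: np.ndarray, axis: int = -1) -> np.ndarray:
    sd = np.std(x, axis=axis, ddof=1)
    mean = np.mean(x, axis=axis)
    return np.maximum(sd, np.maximum(SD_FLOOR_REL * np.abs(mean), SD_FLOOR_ABS))


def snr_metric(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Signal-to-noise ratio ``(mean_a - mean_b) / (sd_a + sd_b)``.

    Each group SD is floored at ``max(sd, 0.2 |mean|, 0.005)`` so the
    metric stays finite for constant probes.  Antisymmetric under group
    swap.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    return float((a.mean() - b.mean()) / (_floored_sd(a) + _floored_sd(b)))


def _probe_metrics(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized SNR for every probe row; ``mask_a`` marks the positive class."""
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    return (a.mean(axis=1) - b.mean(axis=1)) / (_floored_sd(a) + _floored_sd(b))


class _CollapseEngine:
    """Precomputed probe->EC machinery for fast repeated collapsing.

    Nodes are stored lexicographically sorted and each node's candidate
    probe indices sorted by probe id, so argmax of |metric| (first
    occurrence on ties) realises the deterministic tie-break: node id,
    then probe id.
    """

    def __init__(self, dataset: ExpressionDataset):
        probe_ids = list(dataset.values.index)
        probe_pos = {p: i for i, p in enumerate(probe_ids)}
        node_probes: dict[str, list[str]] = {}
        for probe in probe_ids:
            gene = dataset.probe_to_gene.get(probe)
            if gene is None:
                continue
            for ec in dataset.gene_to_ec.get(gene, ()):
                node_probes.setdefault(ec, []).append(probe)
        if not node_probes:
            raise ValueError("annotation covers no probes")
        self.nodes = np.array(sorted(node_probes), dtype=object)
        self.groups = [
            np.array([probe_pos[p] for p in sorted(node_probes[ec])], dtype=np.intp)
            for ec in self.nodes
        ]
        self.values = dataset.values.to_numpy(dtype=float)
        self.mask = dataset.class_mask

    def node_metrics(self, mask_a: np.ndarray) -> np.ndarray:
        pm = _probe_metrics(self.values, mask_a)
        apm = np.abs(pm)
        out = np.empty(len(self.nodes))
        for i, idx in enumerate(self.groups):
            out[i] = pm[idx[np.argmax(apm[idx])]]
        return out

    def rank_order(self, node_metrics: np.ndarray) -> np.ndarray:
        """Indices into ``self.nodes`` in descending-metric order (stable)."""
        return np.lexsort((np.arange(len(node_metrics)), -node_metrics))


def collapse_to_nodes(dataset: ExpressionDataset) -> RankedNodeList:
    """Collapse probes to EC nodes by maximum-|SNR| probeset, ranked descending."""
    eng = _CollapseEngine(dataset)
    metrics = eng.node_metrics(eng.mask)
    order = eng.rank_order(metrics)
    return RankedNodeList(nodes=eng.nodes[order], metrics=metrics[order])


def _es_from_mask(metrics: np.ndarray, hit: np.ndarray, weight_exponent: float) -> float:
    """Running-sum ES given ranked metrics and a ranked-order hit mask."""
    n = len(metrics)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("module not represented in ranked list")
    if nh == n:
        return 1.0  # degenerate: no misses possible
    w = np.where(hit, np.abs(metrics) ** weight_exponent, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        w = hit.astype(float)
        wsum = float(nh)
    dev = np.cumsum(w / wsum - (~hit) / (n - nh))
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def enrichment_score(
    ranked: RankedNodeList, node_set: Iterable[str], weight_exponent: float = 1.0
) -> float:
    """Signed maximum deviation of the GSEA running sum; always in [-1, 1]."""
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    members = set(node_set)
    hit = np.fromiter((n in members for n in ranked.nodes), dtype=bool, count=len(ranked))
    return _es_from_mask(ranked.metrics, hit, weight_exponent)


def _nes_and_p(es: float, nulls: np.ndarray, n_perm: int) -> tuple[float, float, bool]:
    if es == 0.0:
        return 0.0, 1.0, False
    same = nulls[np.sign(nulls) == np.sign(es)]
    if len(same) == 0:
        return float("nan"), 1.0 / (n_perm + 1), True
    nes = es / np.mean(np.abs(same))
    p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
    return float(nes), float(p), False


def _choose_mode(dataset: ExpressionDataset, mode: str) -> str:
    if mode == "auto":
        return "phenotype" if dataset.labels.value_counts().min() >= 7 else "node"
    if mode not in ("phenotype", "node"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if mode == "phenotype" and dataset.labels.value_counts().min() < 7:
        raise ValueError("phenotype permutation needs >= 7 samples per class")
    return mode


def _null_es(
    eng: _CollapseEngine,
    hit_masks: list[np.ndarray],  # in node-index space (unranked)
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
    mode: str,
) -> np.ndarray:
    """Null ES matrix of shape (n_perm, n_modules)."""
    n_nodes = len(eng.nodes)
    out = np.empty((n_perm, len(hit_masks)))
    if mode == "phenotype":
        for t in range(n_perm):
            pmask = rng.permutation(eng.mask)
            metrics = eng.node_metrics(pmask)
            order = eng.rank_order(metrics)
            mr = metrics[order]
            for m, mask in enumerate(hit_masks):
                out[t, m] = _es_from_mask(mr, mask[order], weight_exponent)
    else:  # node permutation: observed ranking, random member positions
        metrics = eng.node_metrics(eng.mask)
        order = eng.rank_order(metrics)
        mr = metrics[order]
        for m, mask in enumerate(hit_masks):
            k = int(mask.sum())
            for t in range(n_perm):
                fake = np.zeros(n_nodes, dtype=bool)
                fake[rng.choice(n_nodes, size=k, replace=False)] = True
                out[t, m] = _es_from_mask(mr, fake, weight_exponent)
    return out


def permutation_nes(
    dataset: ExpressionDataset,
    node_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    mode: str = "auto",
    module_id: str = "module",
) -> ModuleEnrichment:
    """Permutation-normalized enrichment for one module.

    NES is the observed ES divided by the mean |ES| of same-sign null
    scores; p is the same-sign exceedance fraction with a +1 pseudo-count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mode = _choose_mode(dataset, mode)
    eng = _CollapseEngine(dataset)
    members = set(node_set)
    mask = np.fromiter((n in members for n in eng.nodes), dtype=bool, count=len(eng.nodes))
    metrics = eng.node_metrics(eng.mask)
    order = eng.rank_order(metrics)
    es = _es_from_mask(metrics[order], mask[order], weight_exponent)
    rng = np.random.default_rng(seed)
    nulls = _null_es(eng, [mask], n_perm, rng, weight_exponent, mode)[:, 0]
    nes, p, flagged = _nes_and_p(es, nulls, n_perm)
    enriched_in = dataset.classes[0] if es >= 0 else dataset.classes[1]
    return ModuleEnrichment(
        module_id=module_id,
        n_nodes=int(mask.sum()),
        es=es,
        nes=nes,
        p=p,
        enriched_in=enriched_in,
        flagged=flagged,
    )


def score_collection(
    dataset: ExpressionDataset,
    collection: NodeSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    mode: str = "auto",
    min_nodes: int = 3,
    max_nodes: int = 500,
) -> list[ModuleEnrichment]:
    """Score every size-filtered module, sharing one permutation null.

    All modules see the same permuted rankings (the canonical scheme);
    Benjamini-Hochberg q-values are attached across modules.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mode = _choose_mode(dataset, mode)
    eng = _CollapseEngine(dataset)
    metrics = eng.node_metrics(eng.mask)
    order = eng.rank_order(metrics)
    ranked = RankedNodeList(nodes=eng.nodes[order], metrics=metrics[order])
    kept = filter_modules(collection, ranked, min_nodes=min_nodes, max_nodes=max_nodes)
    module_ids = sorted(kept.sets)
    node_pos = {n: i for i, n in enumerate(eng.nodes)}
    masks = []
    for mid in module_ids:
        mask = np.zeros(len(eng.nodes), dtype=bool)
        for node in kept[mid]:
            if node in node_pos:
                mask[node_pos[node]] = True
        masks.append(mask)
    mr = metrics[order]
    observed = [_es_from_mask(mr, mask[order], weight_exponent) for mask in masks]
    rng = np.random.default_rng(seed)
    nulls = _null_es(eng, masks, n_perm, rng, weight_exponent, mode)
    results = []
    for m, mid in enumerate(module_ids):
        nes, p, flagged = _nes_and_p(observed[m], nulls[:, m], n_perm)
        results.append(
            ModuleEnrichment(
                module_id=mid,
                n_nodes=int(masks[m].sum()),
                es=observed[m],
                nes=nes,
                p=p,
                enriched_in=dataset.classes[0] if observed[m] >= 0 else dataset.classes[1],
                flagged=flagged,
            )
        )
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def filter_modules(
    collection: NodeSetCollection,
    ranked: RankedNodeList,
    min_nodes: int = 3,
    max_nodes: int = 500,
) -> NodeSetCollection:
    """Keep modules with min_nodes <= represented-node count <= max_nodes."""
    present = set(ranked.nodes)
    kept = {
        mid: members
        for mid, members in collection.sets.items()
        if min_nodes <= len(members & present) <= max_nodes
    }
    return NodeSetCollection(sets=kept, names={m: collection.display_name(m) for m in kept})


def cross_dataset_concordance(
    enrich_a: Sequence[ModuleEnrichment],
    enrich_b: Sequence[ModuleEnrichment],
    tau: float = 1.2,
) -> ConcordanceResult:
    """Pair NES values by module across two datasets and intersect at |NES| > tau."""
    a = {r.module_id: r.nes for r in enrich_a if np.isfinite(r.nes)}
    b = {r.module_id: r.nes for r in enrich_b if np.isfinite(r.nes)}
    common = sorted(set(a) & set(b))
    if len(common) < 3:
        raise ValueError(f"need >= 3 modules scored in both datasets, got {len(common)}")
    pairs = pd.DataFrame(
        {"nes_a": [a[m] for m in common], "nes_b": [b[m] for m in common]}, index=common
    )
    pearson = float(stats.pearsonr(pairs["nes_a"], pairs["nes_b"]).statistic)
    spearman = float(stats.spearmanr(pairs["nes_a"], pairs["nes_b"]).statistic)
    shared_up = [m for m in common if a[m] > tau and b[m] > tau]
    shared_down = [m for m in common if a[m] < -tau and b[m] < -tau]
    return ConcordanceResult(
        nes_pairs=pairs,
        pearson=pearson,
        spearman=spearman,
        tau=tau,
        shared_up=shared_up,
        shared_down=shared_down,
    )
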