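"""Label sets, multi-rotation inference, Top-K retrieval metrics and
reliability analyses for fragment-fingerprint predictions.

Evaluation protocol: for each test example the model is run ``n_rotations``
times (default 8), each time re-rendering the voxel grid under a fresh
uniform random rotation, and the predicted fingerprints are averaged. The
averaged prediction is ranked against a label set — deduplicated candidate
fragments with precomputed binary fingerprints — by cosine similarity, and
Top-K accuracy counts how often the ground-truth fragment identity appears
among the K highest-ranked candidates.

The analytic random baseline for uniform selection of K distinct fragments
from a label set of N is 100*K/N percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragmenter import (
    FragmentationExample,
    PropertyLabel,
    classify_property,
    fragment_fingerprint,
)
from .mol import InputError, Molecule
from .network import FragNet
from .voxelizer import prepare_example, random_rotation, voxelize_prepared

#: the K values reported by default
DEFAULT_K = (1, 8, 16, 32, 64)

#: reliability-binning defaults: 0.025-wide bins from 0.80 to 1.00 plus a
#: catch-all below 0.80 (the top bin covers similarities above 0.975)
DEFAULT_BIN_EDGES = tuple([-1.0] + list(np.arange(0.80, 1.0, 0.025)) + [1.0 + 1e-9])


@dataclass
class LabelSet:
    """Deduplicated candidate fragments with precomputed binary fingerprints."""

    identities: list[str]  # canonical fragment identities, lexicographic order
    fingerprints: np.ndarray  # (N, 2048) uint8
    properties: list[PropertyLabel]
    provenance: str = ""

    @property
    def size(self) -> int:
        return len(self.identities)


def build_label_set(examples: list[FragmentationExample], provenance: str = "") -> LabelSet:
    """Unique fragments of an example set, ordered by canonical identity."""
    if not examples:
        raise InputError("cannot build a label set from zero examples")
    by_identity: dict[str, Molecule] = {}
    for x in examples:
        if x.fragment_identity is not None:
            by_identity.setdefault(x.fragment_identity, x.fragment)
    identities = sorted(by_identity)
    fps = np.stack([fragment_fingerprint(by_identity[s]) for s in identities])
    props = [classify_property(by_identity[s]) for s in identities]
    return LabelSet(identities=identities, fingerprints=fps, properties=props, provenance=provenance)


def predict_fingerprint(
    model: FragNet,
    receptor: Molecule,
    trimmed: Molecule,
    branch_atom: int,
    n_rotations: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Rotation-averaged fingerprint prediction (element-wise mean)."""
    if n_rotations < 1:
        raise InputError("n_rotations must be >= 1")
    prepared = prepare_example(receptor, trimmed, branch_atom)
    rng = np.random.default_rng(seed)
    rotations = [random_rotation(int(s)) for s in rng.integers(2**31, size=n_rotations)]
    grids = np.stack([voxelize_prepared(prepared, rot).values for rot in rotations])
    preds = model.forward(grids, train=False)
    return preds.mean(axis=0)


def cosine_similarity(prediction: np.ndarray, fingerprints: np.ndarray) -> np.ndarray:
    p = np.asarray(prediction, dtype=np.float64)
    f = np.asarray(fingerprints, dtype=np.float64)
    pn = max(float(np.linalg.norm(p)), 1e-12)
    fn = np.maximum(np.linalg.norm(f, axis=1), 1e-12)
    return (f @ p) / (fn * pn)


@dataclass
class RankedSelection:
    """Label-set ranking for one example."""

    ground_truth: str
    identities: list[str]  # descending similarity; ties by identity
    similarities: np.ndarray


def rank_label_set(prediction: np.ndarray, labels: LabelSet) -> tuple[list[str], np.ndarray]:
    """Label identities in descending cosine similarity (ties: lexicographic)."""
    if prediction.shape[0] != labels.fingerprints.shape[1]:
        raise InputError("prediction and label fingerprints have different lengths")
    sims = cosine_similarity(prediction, labels.fingerprints)
    # identities are pre-sorted, so stable sort on -sim yields the tie rule
    order = np.argsort(-sims, kind="stable")
    return [labels.identities[i] for i in order], sims[order]


@dataclass
class TopKResult:
    selections: list[RankedSelection]
    label_set_size: int
    accuracies: dict[int, float] = field(default_factory=dict)  # K -> percent


def evaluate_examples(
    model: FragNet,
    examples: list[FragmentationExample],
    receptors: dict[str, Molecule],
    labels: LabelSet,
    k_values: tuple[int, ...] = DEFAULT_K,
    n_rotations: int = 8,
    seed: int = 0,
) -> TopKResult:
    """Full retrieval evaluation: rotation-averaged prediction, ranking, Top-K."""
    label_ids = set(labels.identities)
    selections: list[RankedSelection] = []
    rng = np.random.default_rng(seed)
    for x in examples:
        if x.fragment_identity not in label_ids:
            raise InputError(
                f"ground-truth fragment {x.fragment_identity!r} missing from label set"
            )
        pred = predict_fingerprint(
            model,
            receptors[x.entry_id],
            x.trimmed_ligand,
            x.branch_atom,
            n_rotations=n_rotations,
            seed=int(rng.integers(2**31)),
        )
        ids, sims = rank_label_set(pred, labels)
        selections.append(
            RankedSelection(ground_truth=x.fragment_identity, identities=ids, similarities=sims)
        )
    result = TopKResult(selections=selections, label_set_size=labels.size)
    for k in k_values:
        if k <= labels.size:
            result.accuracies[k] = topk_accuracy(selections, k)
    return result


def topk_accuracy(selections: list[RankedSelection], k: int) -> float:
    """Percent of examples whose ground truth is within the top k ranks."""
    if not selections:
        raise InputError("no selections to score")
    hits = sum(1 for s in selections if s.ground_truth in s.identities[:k])
    return 100.0 * hits / len(selections)


def random_baseline(n: int, k: int) -> float:
    """Expected Top-K percent when drawing K distinct fragments uniformly from N."""
    if not (1 <= k <= n):
        raise InputError(f"require 1 <= K <= N, got K={k}, N={n}")
    return 100.0 * k / n


@dataclass
class SimilarityBin:
    lo: float
    hi: float
    count: int
    accuracy: float | None  # None for empty bins
    standard_error: float | None


def binned_accuracy(
    selections: list[RankedSelection],
    top_m: int = 16,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> list[SimilarityBin]:
    """Reliability analysis: accuracy of the pooled top-``top_m`` selections
    binned by cosine similarity, with binomial standard errors."""
    edges = np.asarray(bin_edges)
    counts = np.zeros(len(edges) - 1, dtype=int)
    correct = np.zeros(len(edges) - 1, dtype=int)
    for s in selections:
        m = min(top_m, len(s.identities))
        idx = np.clip(np.searchsorted(edges, s.similarities[:m], side="right") - 1, 0, len(counts) - 1)
        for rank in range(m):
            b = idx[rank]
            counts[b] += 1
            if s.identities[rank] == s.ground_truth:
                correct[b] += 1
    bins: list[SimilarityBin] = []
    for i in range(len(counts)):
        if counts[i] == 0:
            bins.append(SimilarityBin(float(edges[i]), float(edges[i + 1]), 0, None, None))
            continue
        p = correct[i] / counts[i]
        se = float(np.sqrt(p * (1 - p) / counts[i]))
        bins.append(
            SimilarityBin(float(edges[i]), float(edges[i + 1]), int(counts[i]), 100.0 * p, 100.0 * se)
        )
    return bins


def property_match_rate(
    selections: list[RankedSelection],
    labels: LabelSet,
    expected: str,
) -> float:
    """Percent of examples whose rank-1 fragment has the expected property.

    ``expected`` is one of small/large/aromatic/aliphatic/acid/base.
    """
    prop_of = dict(zip(labels.identities, labels.properties))

    def matches(p: PropertyLabel) -> bool:
        if expected == "small":
            return p.size_class == "small"
        if expected == "large":
            return p.size_class == "large"
        if expected == "aromatic":
            return p.aromatic
        if expected == "aliphatic":
            return p.aliphatic
        if expected == "acid":
            return p.acidic
        if expected == "base":
            return p.basic
        raise InputError(f"unknown property {expected!r}")

    if not selections:
        raise InputError("no selections to score")
    hits = 0
    for s in selections:
        top1 = s.identities[0]
        if top1 not in prop_of:
            raise InputError(f"label {top1!r} has no property annotation")
        if matches(prop_of[top1]):
            hits += 1
    return 100.0 * hits / len(selections)
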