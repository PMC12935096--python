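"""Leakage-controlled train/validation/test splits.

Two split schemes are provided:

* **Family split with high-priority deduplication.** Entries are assigned to
  splits whole-family-at-a-time (no protein family ever straddles splits),
  targeting the requested fractions by entry count. Deduplication then
  enforces ligand-identity independence with a strict privilege order
  train > validation > test: examples whose ligand identity already occurs
  in a more privileged split are removed from the less privileged one, and
  the training set never shrinks.

* **Butina ligand-cluster split** for fine-tuning datasets, where all
  receptors belong to one family: ligands are clustered by the Butina leader
  algorithm on Morgan-fingerprint Tanimoto similarity (cutoff 0.4) and whole
  clusters are assigned 60/20/20 by cluster count.

Both schemes are deterministic given a seed and invariant to input order
(inputs are sorted internally before any seeded sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina

from .fragmenter import SMALL_MAX_HEAVY, FragmentationExample
from .mol import ComplexEntry, InputError

SPLITS = ("train", "val", "test")

#: Tanimoto cutoff for ligand clustering in the fine-tuning split
BUTINA_CUTOFF = 0.4


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # entry_id -> split
    fractions: tuple[float, float, float]
    seed: int
    removal_log: list[tuple[str, str | None, str, str]] = field(default_factory=list)
    # (entry_id, ligand_identity, removed_from, reason); removed_from is never "train"

    def entries_in(self, split: str) -> list[str]:
        return sorted(e for e, s in self.assignment.items() if s == split)

    def split_of(self, entry_id: str) -> str | None:
        return self.assignment.get(entry_id)


@dataclass
class LigandCluster:
    cluster_id: int
    members: list[str]  # canonical ligand identities
    assigned_split: str | None = None


def _check_fractions(fractions) -> tuple[float, float, float]:
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or abs(sum(f) - 1.0) > 1e-9 or any(x < 0 for x in f):
        raise InputError(f"fractions must be three non-negative numbers summing to 1, got {fractions}")
    return f


def _greedy_assign(
    groups: list[tuple[str, int]], fractions: tuple[float, float, float], seed: int
) -> dict[str, str]:
    """Assign groups (id, weight) to splits, largest current deficit first.

    Groups are shuffled with a seeded RNG after an internal sort, so the
    result does not depend on input order.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(groups)
    order = rng.permutation(len(groups))
    total = sum(w for _, w in groups)
    placed = {s: 0 for s in SPLITS}
    out: dict[str, str] = {}
    for k in order:
        gid, weight = groups[k]
        deficits = {s: fractions[i] * total - placed[s] for i, s in enumerate(SPLITS)}
        target = max(SPLITS, key=lambda s: deficits[s])
        out[gid] = target
        placed[target] += weight
    return out


def family_split(
    entries: list[ComplexEntry],
    fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole protein families to train/val/test near the target fractions."""
    if not entries:
        raise InputError("family_split requires at least one entry")
    fr = _check_fractions(fractions)
    families: dict[str, list[str]] = {}
    for e in entries:
        families.setdefault(e.family_id, []).append(e.entry_id)
    fam_assign = _greedy_assign([(f, len(ids)) for f, ids in families.items()], fr, seed)
    assignment = {eid: fam_assign[fam] for fam, ids in families.items() for eid in ids}
    return SplitAssignment(assignment=assignment, fractions=fr, seed=seed)


# -- high-priority deduplication --------------------------------------------


def dedup_high_priority(
    assignment: SplitAssignment, examples: list[FragmentationExample]
) -> tuple[SplitAssignment, list[FragmentationExample]]:
    """Enforce ligand-identity independence with train > val > test privilege.

    In order: (i) val/test examples without a ligand identity are removed;
    (ii) val/test examples whose ligand identity occurs in train are removed;
    (iii) test examples whose ligand identity occurs in val are removed.
    Training examples are never removed. Entries left with no surviving
    examples are dropped from the assignment, with provenance recorded in
    the removal log.
    """
    split_of = dict(assignment.assignment)
    log = list(assignment.removal_log)

    def ligands_of(split: str) -> set[str]:
        return {
            x.ligand_identity
            for x in examples
            if x.ligand_identity is not None and split_of.get(x.entry_id) == split
        }

    surviving: list[FragmentationExample] = []
    train_ligands = ligands_of("train")
    # pass 1: missing identity + train-overlap removal from val/test
    kept: list[FragmentationExample] = []
    for x in examples:
        split = split_of.get(x.entry_id)
        if split in ("val", "test"):
            if x.ligand_identity is None:
                log.append((x.entry_id, None, split, "missing_identity"))
                continue
            if x.ligand_identity in train_ligands:
                log.append((x.entry_id, x.ligand_identity, split, "ligand_in_train"))
                continue
        kept.append(x)
    # pass 2: val-overlap removal from test
    val_ligands = {
        x.ligand_identity
        for x in kept
        if x.ligand_identity is not None and split_of.get(x.entry_id) == "val"
    }
    for x in kept:
        split = split_of.get(x.entry_id)
        if split == "test" and x.ligand_identity in val_ligands:
            log.append((x.entry_id, x.ligand_identity, "test", "ligand_in_val"))
            continue
        surviving.append(x)

    populated = {x.entry_id for x in surviving}
    new_assignment = {e: s for e, s in split_of.items() if e in populated}
    return (
        SplitAssignment(
            assignment=new_assignment,
            fractions=assignment.fractions,
            seed=assignment.seed,
            removal_log=log,
        ),
        surviving,
    )


# -- targeted subsets --------------------------------------------------------


def subset_by_size(
    examples: list[FragmentationExample], min_heavy: int = 1, max_heavy: int | None = None
) -> list[FragmentationExample]:
    """Examples whose fragment heavy-atom count lies in [min_heavy, max_heavy]."""
    out = []
    for x in examples:
        if x.fragment_heavy_atoms < min_heavy:
            continue
        if max_heavy is not None and x.fragment_heavy_atoms > max_heavy:
            continue
        out.append(x)
    return out


def small_fragment_subset(examples: list[FragmentationExample]) -> list[FragmentationExample]:
    return subset_by_size(examples, max_heavy=SMALL_MAX_HEAVY)


def large_fragment_subset(examples: list[FragmentationExample]) -> list[FragmentationExample]:
    return subset_by_size(examples, min_heavy=SMALL_MAX_HEAVY + 1)


def subset_by_property(
    examples: list[FragmentationExample], property_name: str
) -> list[FragmentationExample]:
    """Filter by fragment property class.

    ``acid``/``base`` subsets exclude fragments that are simultaneously
    acidic and basic (ambivalent fragments carry no clean supervision
    signal for either targeted model).
    """
    known = {"aromatic", "aliphatic", "acid", "base"}
    if property_name not in known:
        raise InputError(f"unknown property {property_name!r}; expected one of {sorted(known)}")
    out = []
    for x in examples:
        p = x.properties
        if p is None:
            raise InputError(f"example {x.entry_id} has no precomputed property label")
        if property_name == "aromatic" and p.aromatic:
            out.append(x)
        elif property_name == "aliphatic" and p.aliphatic:
            out.append(x)
        elif property_name == "acid" and p.acidic and not p.basic:
            out.append(x)
        elif property_name == "base" and p.basic and not p.acidic:
            out.append(x)
    return out


# -- Butina ligand-cluster split ---------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def butina_cluster_split(
    examples: list[FragmentationExample],
    tanimoto_cutoff: float = BUTINA_CUTOFF,
    fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[LigandCluster], dict[str, str]]:
    """Cluster ligands (Butina leader algorithm, Morgan fp Tanimoto) and
    assign whole clusters to splits by cluster count.

    Returns the clusters and a mapping ligand_identity -> split; all examples
    of a ligand follow its cluster. Ligands are sorted by canonical identity
    before clustering so the result is input-order invariant; Butina ranks
    candidate centers by neighbor count with ties falling back to that
    identity order.
    """
    fr = _check_fractions(fractions)
    identities = sorted({x.ligand_identity for x in examples if x.ligand_identity is not None})
    if not identities:
        raise InputError("butina_cluster_split requires at least one identified ligand")
    fps = [_MORGAN.GetFingerprint(Chem.MolFromSmiles(s)) for s in identities]
    # condensed lower-triangle distance list, as Butina.ClusterData expects
    dists: list[float] = []
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    raw = Butina.ClusterData(dists, len(fps), 1.0 - tanimoto_cutoff, isDistData=True)
    clusters = [
        LigandCluster(cluster_id=k, members=sorted(identities[i] for i in idxs))
        for k, idxs in enumerate(sorted(raw, key=lambda c: sorted(c)))
    ]
    assign = _greedy_assign([(str(c.cluster_id), 1) for c in clusters], fr, seed)
    ligand_split: dict[str, str] = {}
    for c in clusters:
        c.assigned_split = assign[str(c.cluster_id)]
        for smiles in c.members:
            ligand_split[smiles] = c.assigned_split
    return clusters, ligand_split
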