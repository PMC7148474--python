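"""Reference-set classification with the learned similarity metric.

A query image q is assigned to the species whose reference set C_i it is
closest to on average:

    S_i(q) = (1/|C_i|) * sum_{x in C_i} d(q, x),      C* = argmin_i S_i(q)

where d is the Euclidean distance between embeddings under the trained
Siamese weights.  Top-k accuracy accepts the k species with the smallest
average distance.  Because the metric is class-count independent, species
never seen in training participate simply by providing a few reference
images — no retraining is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NetworkHandle, embed_batch

__all__ = [
    "ReferenceSet",
    "Prediction",
    "average_similarity",
    "predict",
    "topk_accuracy",
    "evaluate_transfer",
    "reference_sets_from_samples",
]


@dataclass
class ReferenceSet:
    """A species label with its k reference images.

    Embeddings are cached lazily per weight state; call
    :meth:`ensure_embeddings` after any weight update.
    """

    species_id: str
    images: list[np.ndarray]
    embeddings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.images) == 0:
            raise ValueError("reference set must contain at least one image")

    def ensure_embeddings(self, net: NetworkHandle) -> np.ndarray:
        if self.embeddings is None or len(self.embeddings) != len(self.images):
            self.embeddings = embed_batch(net, np.stack(self.images)).astype(np.float64)
        return self.embeddings


@dataclass
class Prediction:
    """Species ranked by ascending average distance, with their scores."""

    ranked_species: list[str]
    scores: list[float]


def reference_sets_from_samples(samples, max_per_species: int | None = None):
    """Group labeled samples into one ReferenceSet per species (sorted labels)."""
    groups: dict[str, list[np.ndarray]] = {}
    for s in samples:
        groups.setdefault(s.species_id, []).append(s.image)
    return [ReferenceSet(k, v if max_per_species is None else v[:max_per_species])
            for k, v in sorted(groups.items())]


def mean_distances(q_emb: np.ndarray, reference_sets, net: NetworkHandle) -> np.ndarray:
    """S_i for one query embedding against every reference set."""
    return np.array([
        float(np.linalg.norm(rs.ensure_embeddings(net) - q_emb[None, :], axis=1).mean())
        for rs in reference_sets])


def average_similarity(q: np.ndarray, Ci: ReferenceSet, net: NetworkHandle) -> float:
    """Mean learned distance from the query to the images of one species."""
    q_emb = embed_batch(net, q)[0].astype(np.float64)
    return float(mean_distances(q_emb, [Ci], net)[0])


def _rank(scores: np.ndarray, labels: list[str]) -> list[int]:
    # ascending score, ties toward the lexicographically smaller species
    return sorted(range(len(labels)), key=lambda i: (scores[i], labels[i]))


def predict(q: np.ndarray, reference_sets, net: NetworkHandle,
            k: int = 1) -> Prediction:
    """Rank all reference species by average distance and keep the top k."""
    reference_sets = list(reference_sets)
    if not reference_sets:
        raise ValueError("need at least one reference set")
    if k > len(reference_sets):
        raise ValueError(f"k={k} exceeds the {len(reference_sets)} reference sets")
    labels = [rs.species_id for rs in reference_sets]
    q_emb = embed_batch(net, q)[0].astype(np.float64)
    scores = mean_distances(q_emb, reference_sets, net)
    order = _rank(scores, labels)[:k]
    return Prediction([labels[i] for i in order], [float(scores[i]) for i in order])


def topk_accuracy(test_set, reference_sets, net: NetworkHandle, k: int = 1) -> float:
    """Fraction of test images whose true species ranks within the top k."""
    reference_sets = list(reference_sets)
    known = {rs.species_id for rs in reference_sets}
    test_set = list(test_set)
    if not test_set:
        raise ValueError("empty test set")
    missing = {s.species_id for s in test_set} - known
    if missing:
        raise ValueError(f"no reference set for species: {sorted(missing)}")
    labels = [rs.species_id for rs in reference_sets]
    q_embs = embed_batch(net, np.stack([s.image for s in test_set])).astype(np.float64)
    hits = 0
    for s, q_emb in zip(test_set, q_embs):
        scores = mean_distances(q_emb, reference_sets, net)
        top = [labels[i] for i in _rank(scores, labels)[:k]]
        hits += s.species_id in top
    return hits / len(test_set)


def evaluate_transfer(net: NetworkHandle, seen_reference_sets, novel_species,
                      ks=(1, 3)) -> dict:
    """Score never-seen species against the union of all reference sets.

    ``novel_species`` is a list of ``(species_id, reference_images,
    test_images)`` triples.  Queries compete jointly against the seen
    species and every novel species, exactly the open-set regime the
    Siamese metric targets; the network is not retrained.  Returns a
    per-species top-k table for the novel species plus averages.
    """
    seen_labels = {rs.species_id for rs in seen_reference_sets}
    novel_labels = [sp for sp, _, _ in novel_species]
    overlap = seen_labels & set(novel_labels)
    if overlap:
        raise ValueError(f"novel species overlap the seen ones: {sorted(overlap)}")
    all_sets = list(seen_reference_sets) + [
        ReferenceSet(sp, list(refs)) for sp, refs, _ in novel_species]
    labels = [rs.species_id for rs in all_sets]
    per_species: dict[str, dict[str, float]] = {}
    for sp, _, test_imgs in novel_species:
        if len(test_imgs) == 0:
            raise ValueError(f"novel species {sp} has no test images")
        q_embs = embed_batch(net, np.stack(list(test_imgs))).astype(np.float64)
        accs = {}
        for k in ks:
            hits = 0
            for q_emb in q_embs:
                scores = mean_distances(q_emb, all_sets, net)
                hits += sp in [labels[i] for i in _rank(scores, labels)[:k]]
            accs[f"top{k}"] = hits / len(q_embs)
        per_species[sp] = accs
    result = {"per_species": per_species, "n_classes_total": len(all_sets)}
    for k in ks:
        vals = [per_species[sp][f"top{k}"] for sp in novel_labels]
        result[f"average_top{k}"] = float(np.mean(vals)) if vals else float("nan")
    return result
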