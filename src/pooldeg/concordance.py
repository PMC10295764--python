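"""Gene-set comparison statistics.

Implements the concordance measures used to compare DEG lists between
experimental designs: pairwise overlap with the smallest-set denominator,
fold enrichment of an intersection over its independence expectation with a
hypergeometric upper-tail p-value, recall ("identification") and precision
("accuracy") of a candidate list against a reference list, exhaustive
Venn-style partition of 2-4 sets by membership pattern, and offline gene
identifier harmonization via a two-column mapping table.

Percentages are computed at full precision; display rounding is half-up to
the nearest integer (as commonly printed), with full precision retained in
machine output. A hypergeometric tail too small for double precision is
reported on the natural-log scale rather than as a literal zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "OverlapResult",
    "MultiwayOverlap",
    "pairwise_overlap",
    "fold_enrichment",
    "identification_fraction",
    "accuracy_fraction",
    "multiway_overlap",
    "harmonize_ids",
    "read_gene_list",
    "write_gene_list",
    "read_id_mapping",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round a nonnegative value half-up to the nearest integer."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers in a stated namespace."""

    label: str
    ids: frozenset[str]
    namespace: str = "unspecified"

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(self.ids))
        if any(not i for i in self.ids):
            raise ValueError(f"GeneSet {self.label!r} contains empty "
                             "identifiers")

    def __len__(self) -> int:
        return len(self.ids)


def read_gene_list(path, label: str | None = None,
                   namespace: str = "unspecified") -> GeneSet:
    """Read a plain-text gene list, one identifier per line."""
    with open(path) as fh:
        ids = [line.strip() for line in fh]
    ids = [i for i in ids if i]
    if not ids:
        raise ValueError(f"gene list {path} is empty")
    from pathlib import Path
    return GeneSet(label or Path(path).stem, frozenset(ids), namespace)


def write_gene_list(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(gene_set.ids):
            fh.write(f"{i}\n")


@dataclass
class OverlapResult:
    """Pairwise comparison of two gene sets.

    ``percent_overlap`` is 100 * |A∩B| / min(|A|, |B|). Enrichment fields are
    populated only by :func:`fold_enrichment`.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_intersection: int
    n_only_a: int
    n_only_b: int
    percent_overlap: float
    background_size: int | None = None
    fold_enrichment: float | None = None
    hypergeometric_p: float | None = None
    log_hypergeometric_p: float | None = None

    @property
    def percent_overlap_rounded(self) -> int:
        return round_half_up(self.percent_overlap)

    def validate(self) -> None:
        if self.n_a != self.n_intersection + self.n_only_a:
            raise ValueError("OverlapResult: n_a != intersection + only_a")
        if self.n_b != self.n_intersection + self.n_only_b:
            raise ValueError("OverlapResult: n_b != intersection + only_b")
        if not (0.0 <= self.percent_overlap <= 100.0):
            raise ValueError("OverlapResult: percent_overlap outside [0, 100]")

    def to_dict(self) -> dict:
        d = {
            "label_a": self.label_a, "label_b": self.label_b,
            "n_a": self.n_a, "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_only_a": self.n_only_a, "n_only_b": self.n_only_b,
            "percent_overlap": self.percent_overlap,
            "percent_overlap_rounded": self.percent_overlap_rounded,
        }
        if self.background_size is not None:
            d.update(background_size=self.background_size,
                     fold_enrichment=self.fold_enrichment,
                     hypergeometric_p=self.hypergeometric_p,
                     log_hypergeometric_p=self.log_hypergeometric_p)
        return d


def _check_pair(a: GeneSet, b: GeneSet) -> None:
    if a.namespace != b.namespace:
        raise ValueError(
            f"namespace mismatch: {a.label!r} uses {a.namespace!r} but "
            f"{b.label!r} uses {b.namespace!r}; harmonize first")
    if not a.ids:
        raise ValueError(f"gene set {a.label!r} is empty")
    if not b.ids:
        raise ValueError(f"gene set {b.label!r} is empty")


def pairwise_overlap(a: GeneSet, b: GeneSet) -> OverlapResult:
    """Exact intersection/difference counts plus percent overlap relative to
    the smaller set."""
    _check_pair(a, b)
    inter = len(a.ids & b.ids)
    res = OverlapResult(
        label_a=a.label, label_b=b.label, n_a=len(a), n_b=len(b),
        n_intersection=inter, n_only_a=len(a) - inter, n_only_b=len(b) - inter,
        percent_overlap=100.0 * inter / min(len(a), len(b)),
    )
    res.validate()
    return res


def fold_enrichment(a: GeneSet, b: GeneSet,
                    background_size: int) -> OverlapResult:
    """Overlap with enrichment statistics on a stated background universe.

    ``fold_enrichment`` is the observed intersection divided by its
    independence expectation |A||B|/N. ``hypergeometric_p`` is the upper-tail
    probability of drawing at least the observed intersection when |A| items
    are sampled without replacement from a universe of N containing |B|
    successes (symmetric in A and B).
    """
    _check_pair(a, b)
    union = len(a.ids | b.ids)
    if background_size < union:
        raise ValueError(
            f"background_size {background_size} is smaller than the union "
            f"of the two sets ({union})")
    res = pairwise_overlap(a, b)
    k, n, K, N = res.n_intersection, res.n_a, res.n_b, background_size
    res.background_size = N
    res.fold_enrichment = k / (n * K / N)
    res.hypergeometric_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    res.log_hypergeometric_p = float(stats.hypergeom.logsf(k - 1, N, K, n))
    res.validate()
    return res


def identification_fraction(candidate: GeneSet, reference: GeneSet) -> float:
    """Percent of the reference recovered: 100 * |candidate ∩ reference| /
    |reference| (recall)."""
    if not reference.ids:
        raise ValueError(f"reference set {reference.label!r} is empty")
    return 100.0 * len(candidate.ids & reference.ids) / len(reference)


def accuracy_fraction(candidate: GeneSet, reference: GeneSet) -> float:
    """Percent of the candidate that is in the reference: 100 *
    |candidate ∩ reference| / |candidate| (precision)."""
    if not candidate.ids:
        raise ValueError(f"candidate set {candidate.label!r} is empty")
    return 100.0 * len(candidate.ids & reference.ids) / len(candidate)


@dataclass
class MultiwayOverlap:
    """Venn-style partition of 2-4 sets: for every nonempty subset of set
    labels, the number of ids belonging to exactly those sets."""

    labels: tuple[str, ...]
    counts: dict[tuple[str, ...], int]
    union_size: int

    def validate(self) -> None:
        if sum(self.counts.values()) != self.union_size:
            raise ValueError("MultiwayOverlap: pattern counts do not sum to "
                             "the union size")

    def margin(self, label: str) -> int:
        """Size of one input set, reconstructed from the pattern counts."""
        return sum(c for pat, c in self.counts.items() if label in pat)

    def count_exactly(self, labels: Iterable[str]) -> int:
        key = tuple(l for l in self.labels if l in set(labels))
        return self.counts.get(key, 0)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "union_size": self.union_size,
            "counts": {"&".join(pat): c for pat, c in self.counts.items()},
        }


def multiway_overlap(sets: Sequence[GeneSet]) -> MultiwayOverlap:
    """Exact partition of the union of 2-4 sets by membership pattern."""
    if not (2 <= len(sets) <= 4):
        raise ValueError(f"multiway_overlap takes 2-4 sets, got {len(sets)}")
    namespaces = {s.namespace for s in sets}
    if len(namespaces) > 1:
        raise ValueError(f"namespace mismatch across sets: "
                         f"{sorted(namespaces)}; harmonize first")
    labels = tuple(s.label for s in sets)
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be distinct")

    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            counts[tuple(labels[i] for i in combo)] = 0
    union = set().union(*(s.ids for s in sets))
    for gid in union:
        pat = tuple(labels[i] for i, s in enumerate(sets) if gid in s.ids)
        counts[pat] += 1
    result = MultiwayOverlap(labels, counts, len(union))
    result.validate()
    return result


# ---------------------------------------------------------------------------
# identifier harmonization
# ---------------------------------------------------------------------------

def read_id_mapping(path) -> dict[str, str]:
    """Read a two-column old-id -> new-id tab-separated mapping table.

    Duplicate old-id rows are tolerated when they agree and rejected when
    they conflict.
    """
    t = pd.read_csv(path, sep="\t", header=None, dtype=str,
                    names=["old", "new"], comment="#")
    mapping: dict[str, str] = {}
    for old, new in zip(t["old"], t["new"]):
        if old in mapping and mapping[old] != new:
            raise ValueError(f"conflicting mapping for id {old!r}: "
                             f"{mapping[old]!r} vs {new!r}")
        mapping[old] = new
    return mapping


def harmonize_ids(gene_set: GeneSet, mapping: Mapping[str, str],
                  new_namespace: str = "harmonized",
                  ) -> tuple[GeneSet, list[str]]:
    """Translate a gene set into a new identifier namespace.

    Mapped ids are deduplicated (many old ids may collapse onto one current
    id); ids absent from the mapping are dropped from the set and returned as
    the unmapped report — mirroring gene identifiers that have been retired
    and no longer denote genes.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for gid in sorted(gene_set.ids):
        if gid in mapping:
            mapped.add(mapping[gid])
        else:
            unmapped.append(gid)
    return (GeneSet(gene_set.label, frozenset(mapped), new_namespace),
            unmapped)
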