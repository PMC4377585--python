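"""Overlap of variants with regulatory-feature tracks.

Evidence that would come from regulatory databases (promoter/enhancer
calls, motifs, DNase footprints, eQTLs, conserved elements, TFBS,
ChIP-seq protein binding) is consumed as class-labelled BED tracks, so the
overlap computation is reproducible offline. Profiles record the distinct
feature classes covering each variant: two tracks of the same class count
once.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .models import RegulatoryFeatureClass, RegulatoryProfile, TrackFeature, Variant


def overlap_features(
    variants: Sequence[Variant], tracks: Iterable[TrackFeature]
) -> dict[str, RegulatoryProfile]:
    """Per-variant profile of distinct overlapping feature classes.

    Containment follows the BED half-open convention: a feature with BED
    coordinates (start, end) covers 1-based positions start+1 .. end.
    """
    trees: dict[str, IntervalTree] = {}
    for feat in tracks:
        trees.setdefault(feat.contig, IntervalTree()).addi(
            feat.start + 1, feat.end + 1, feat.feature_class
        )
    profiles: dict[str, RegulatoryProfile] = {}
    for v in variants:
        tree = trees.get(v.contig)
        classes = frozenset(iv.data for iv in tree[v.position]) if tree else frozenset()
        profiles[v.id] = RegulatoryProfile(variant_id=v.id, classes=classes)
    return profiles


def feature_count_distribution(
    profiles: Mapping[str, RegulatoryProfile],
) -> dict[int, int]:
    """Histogram: number of distinct feature classes k -> variant count.

    Mass is conserved (the counts sum to the number of variants); the
    fraction covered by at least one class is 1 - histogram[0] / N.
    """
    hist: dict[int, int] = {}
    for profile in profiles.values():
        hist[profile.n_classes] = hist.get(profile.n_classes, 0) + 1
    return dict(sorted(hist.items()))


def coverage_fraction(profiles: Mapping[str, RegulatoryProfile]) -> float:
    """Fraction of variants overlapping at least one feature class."""
    if not profiles:
        return 0.0
    covered = sum(1 for p in profiles.values() if p.n_classes >= 1)
    return covered / len(profiles)


def class_counts(
    profiles: Mapping[str, RegulatoryProfile],
) -> dict[RegulatoryFeatureClass, int]:
    """Number of variants overlapping each feature class (with multiplicity
    across classes: a variant covered by two classes contributes to both)."""
    counts = {cls: 0 for cls in RegulatoryFeatureClass}
    for profile in profiles.values():
        for cls in profile.classes:
            counts[cls] += 1
    return counts
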