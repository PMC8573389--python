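"""Network-pattern calls from a thresholded network plus the channel-region map.

The qualitative spatial patterns described for these networks — frontal
localized, posterior (parietal/occipital), anterior-posterior, or distributed
— are made explicit here by an edge-class dominance rule: every retained edge
is assigned to exactly one class (both ends frontal; both ends posterior; one
frontal and one posterior end; anything else), and the pattern label is the
specific class whose edge fraction reaches ``theta`` (default 0.5), falling
back to "distributed".  Central and temporal channels count only toward the
"other" class.

This replaces a visual-inspection judgement with a reproducible rule; the gap
between the two is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ThresholdedNetwork

ANTERIOR = frozenset({"frontal"})
POSTERIOR = frozenset({"parietal", "occipital"})

LABEL_FRONTAL = "frontal"
LABEL_POSTERIOR = "posterior"
LABEL_ANTERIOR_POSTERIOR = "anterior_posterior"
LABEL_DISTRIBUTED = "distributed"

EDGE_CLASSES = ("intra_frontal", "intra_posterior", "anterior_posterior", "other")

_CLASS_TO_LABEL = {
    "intra_frontal": LABEL_FRONTAL,
    "intra_posterior": LABEL_POSTERIOR,
    "anterior_posterior": LABEL_ANTERIOR_POSTERIOR,
}


@dataclass
class PatternCall:
    label: str
    fractions: dict[str, float]
    n_edges: int


def edge_class_fractions(network: ThresholdedNetwork) -> tuple[dict[str, float], int]:
    """Fraction of retained edges in each spatial class.

    Returns ``(fractions, n_edges)``; an empty network yields all-zero
    fractions with ``n_edges == 0`` as the flag.
    """
    regions = [network.region_of[c] for c in network.channel_labels]
    counts = dict.fromkeys(EDGE_CLASSES, 0)
    for i, j in network.edge_list():
        ri, rj = regions[i], regions[j]
        if ri in ANTERIOR and rj in ANTERIOR:
            counts["intra_frontal"] += 1
        elif ri in POSTERIOR and rj in POSTERIOR:
            counts["intra_posterior"] += 1
        elif (ri in ANTERIOR and rj in POSTERIOR) or (ri in POSTERIOR and rj in ANTERIOR):
            counts["anterior_posterior"] += 1
        else:
            counts["other"] += 1
    n_edges = sum(counts.values())
    if n_edges == 0:
        return dict.fromkeys(EDGE_CLASSES, 0.0), 0
    return {k: v / n_edges for k, v in counts.items()}, n_edges


def classify_pattern(fractions: dict[str, float], theta: float = 0.5) -> str:
    """Dominance rule: the specific class whose fraction reaches ``theta``;
    ties broken by the larger fraction; otherwise "distributed"."""
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    best_label, best_frac = LABEL_DISTRIBUTED, -1.0
    for cls, label in _CLASS_TO_LABEL.items():
        f = fractions.get(cls, 0.0)
        if f >= theta and f > best_frac:
            best_label, best_frac = label, f
    return best_label


def call_pattern(network: ThresholdedNetwork, theta: float = 0.5) -> PatternCall:
    """Edge-class fractions + dominance label for one network."""
    fractions, n_edges = edge_class_fractions(network)
    label = classify_pattern(fractions, theta) if n_edges else LABEL_DISTRIBUTED
    return PatternCall(label=label, fractions=fractions, n_edges=n_edges)


def pattern_counts(calls_by_period: dict[str, list[str]], label: str) -> np.ndarray:
    """2x2 contingency table of a pattern label across two periods.

    Rows are periods in ("ictal", "termination") order when present (else the
    dict's order); columns are (label, not-label).  Feeds Fisher's exact test.
    """
    order = [p for p in ("ictal", "termination") if p in calls_by_period]
    order += [p for p in calls_by_period if p not in order]
    if len(order) != 2:
        raise ValueError("need calls for exactly two periods")
    rows = []
    for period in order:
        calls = calls_by_period[period]
        if len(calls) == 0:
            raise ValueError(f"no calls for period {period!r}")
        k = sum(c == label for c in calls)
        rows.append([k, len(calls) - k])
    return np.asarray(rows, dtype=int)
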