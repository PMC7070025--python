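"""Cross-compartment taxon transport-pattern classification.

Amplicon-derived taxon tables (OTUs or ASVs; the logic is identical) from
five compartments — seep sediment, Bubble Catcher vent deployments, the
overlying water column, Bubble Catcher deployments over an engineered gas
outlet, and bubble-free control deployments — are filtered and each taxon's
group-presence set is mapped to a transport pattern:

* all_groups                — present in all four non-control compartments
* bentho_pelagic            — sediment + BC vent + water column: the
                              signature of bubble-mediated dislocation with
                              establishment in the water column
* transported_not_established — sediment + BC vent only: lifted by bubbles
                              but not detected in the water column
* sediment_only             — never leaves the benthos
* water_associated          — water column and/or engineered catcher only,
                              no sediment signal
* other                     — any remaining combination

Filtering: taxa seen in any control sample are removed (contamination
rule), then taxa present in fewer than k (default 2) non-control groups
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NON_CONTROL_GROUPS = ("sediment", "BC_vent", "water_column", "BC_engineered")
CONTROL_GROUP = "control"

_PATTERN_LABELS = {
    frozenset(NON_CONTROL_GROUPS): "all_groups",
    frozenset({"sediment", "BC_vent", "water_column"}): "bentho_pelagic",
    frozenset({"sediment", "BC_vent"}): "transported_not_established",
    frozenset({"sediment"}): "sediment_only",
}


@dataclass
class GroupedAbundance:
    """A samples x taxa count table with a sample -> group map."""

    counts: pd.DataFrame          # samples (rows) x taxa (columns)
    groups: pd.Series             # index = samples, values in the 5 groups

    def __post_init__(self):
        if not self.counts.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.counts.index)
            if self.groups.isna().any():
                raise ValueError("every sample must be mapped to a group")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def control_samples(self) -> pd.Index:
        return self.groups.index[self.groups == CONTROL_GROUP]


@dataclass
class TransportPattern:
    taxon_id: str
    presence: frozenset     # over the four non-control groups
    label: str


def pattern_label(presence) -> str:
    """Deterministic label for a presence set over the non-control groups."""
    p = frozenset(presence)
    if p in _PATTERN_LABELS:
        return _PATTERN_LABELS[p]
    if p and p <= {"water_column", "BC_engineered"}:
        return "water_associated"
    return "other"


def relative_abundance(grouped: GroupedAbundance,
                       denominator_taxa=None) -> tuple:
    """Per-sample relative abundances and per-group means.

    Each sample's counts are divided by its total; with
    ``denominator_taxa`` given, the denominator is restricted to that taxon
    subset (e.g. methanotrophic reads only). Group mean is the arithmetic
    mean over the group's samples.

    Returns (per-sample DataFrame, group-mean DataFrame: groups x taxa).
    """
    counts = grouped.counts
    denom_cols = counts.columns if denominator_taxa is None else list(denominator_taxa)
    totals = counts[denom_cols].sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total count: {empty}")
    rel = counts.div(totals, axis=0)
    group_means = rel.groupby(grouped.groups).mean()
    return rel, group_means


def remove_control_taxa(grouped: GroupedAbundance) -> GroupedAbundance:
    """Drop every taxon with a nonzero count in any control sample."""
    ctrl = grouped.control_samples()
    if len(ctrl) == 0:
        return GroupedAbundance(grouped.counts.copy(), grouped.groups.copy())
    contaminated = (grouped.counts.loc[ctrl] > 0).any(axis=0)
    kept = grouped.counts.loc[:, ~contaminated]
    return GroupedAbundance(kept.copy(), grouped.groups.copy())


def presence_matrix(grouped: GroupedAbundance,
                    detection_floor: float = 0.0) -> pd.DataFrame:
    """Boolean non-control-groups x taxa presence matrix: group-mean
    relative abundance above the detection floor (strictly, for floor 0:
    any nonzero group mean counts as present). Control samples are excluded
    from the computation (they may be empty after contamination removal)."""
    mask = (grouped.groups != CONTROL_GROUP) & (grouped.counts.sum(axis=1) > 0)
    sub = GroupedAbundance(grouped.counts.loc[mask], grouped.groups.loc[mask])
    _, gm = relative_abundance(sub)
    gm = gm.reindex([g for g in NON_CONTROL_GROUPS if g in gm.index])
    return gm > detection_floor


def select_min_groups(grouped: GroupedAbundance, k: int = 2,
                      detection_floor: float = 0.0) -> GroupedAbundance:
    """Keep taxa present (above the floor) in at least k non-control groups."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pres = presence_matrix(grouped, detection_floor)
    kept = pres.columns[pres.sum(axis=0) >= k]
    return GroupedAbundance(grouped.counts.loc[:, kept].copy(), grouped.groups.copy())


def classify_pattern(grouped: GroupedAbundance,
                     detection_floor: float = 0.0) -> list:
    """TransportPattern per taxon from its non-control presence set."""
    pres = presence_matrix(grouped, detection_floor)
    out = []
    for taxon in pres.columns:
        present = frozenset(pres.index[pres[taxon]])
        out.append(TransportPattern(taxon_id=taxon, presence=present,
                                    label=pattern_label(present)))
    return out


def pattern_tally(patterns) -> pd.Series:
    """Count of taxa per transport-pattern label."""
    return pd.Series([p.label for p in patterns]).value_counts()


def transport_pipeline(counts: pd.DataFrame, groups: pd.Series, k: int = 2,
                       detection_floor: float = 0.0) -> tuple:
    """Contamination removal, minimum-group selection, classification.

    Order is fixed: remove control taxa, re-derive relative abundances on
    the retained taxa, select, classify. Returns (patterns, tally,
    group-mean relative abundances of the retained taxa).
    """
    grouped = GroupedAbundance(counts, groups)
    grouped = remove_control_taxa(grouped)
    grouped = select_min_groups(grouped, k=k, detection_floor=detection_floor)
    patterns = classify_pattern(grouped, detection_floor=detection_floor)
    mask = (grouped.groups != CONTROL_GROUP) & (grouped.counts.sum(axis=1) > 0)
    _, gm = relative_abundance(
        GroupedAbundance(grouped.counts.loc[mask], grouped.groups.loc[mask]))
    return patterns, pattern_tally(patterns), gm
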