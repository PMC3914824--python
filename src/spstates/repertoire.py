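"""SP clusters, per-condition repertoires, and universality categories.

Resonance frequencies of the same physiological oscillation jitter by
about +-0.5 Hz between sessions and subjects, so SP classes whose
dominant peaks agree within one 0.5 Hz bin (position-wise, with equal
peak counts) are grouped into *clusters* — the unit of repertoire
membership. A cluster enters a condition's *repertoire* when it appears,
in at least one channel, for at least 80% of that condition's subjects.
Across C conditions each cluster is then *unique* (seen in exactly one
condition), *universal* (seen in >= ceil(0.85*C) conditions) or
*optional* (anything between). Morphology counts a cluster's dominant
peaks (one to four), or calls it polyrhythmic when peaks occupy the
majority of the studied range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import BIN_FREQS

__all__ = [
    "RepertoireConfig",
    "SPCluster",
    "Repertoire",
    "UniversalityTable",
    "DEFAULT_BAND_MAP",
    "cluster_sp_classes",
    "map_to_clusters",
    "subject_presence",
    "build_repertoire",
    "categorize_clusters",
    "universality_category",
    "morphology",
    "band_label",
]

#: Conventional sub-band boundaries (Hz). The literature fixes only the
#: broad delta/theta/alpha/beta split; the finer sub-divisions are a
#: configuration, not a constant of the method.
DEFAULT_BAND_MAP: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 3.5),
    ("theta1", 4.0, 5.0),
    ("theta2", 5.5, 6.0),
    ("theta3", 6.5, 7.5),
    ("alpha1", 8.0, 9.0),
    ("alpha2", 9.5, 10.5),
    ("alpha3", 11.0, 12.5),
    ("beta1", 13.0, 17.5),
    ("beta2", 18.0, 23.5),
    ("beta3", 24.0, 30.0),
)

_MORPH_NAMES = {1: "one dominant peak", 2: "two dominant peaks",
                3: "three dominant peaks", 4: "four dominant peaks"}


@dataclass(frozen=True)
class RepertoireConfig:
    peak_tolerance_bins: int = 1
    subject_fraction: float = 0.80
    universal_fraction: float = 0.85
    polyrhythmic_min_peaks: int = 5
    band_map: tuple[tuple[str, float, float], ...] = DEFAULT_BAND_MAP

    def __post_init__(self) -> None:
        if not (0 < self.subject_fraction <= 1 and 0 < self.universal_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")


@dataclass
class SPCluster:
    """A group of peak-compatible SP classes across channels."""

    cluster_id: int
    member_classes: list[tuple[str, int]]
    representative_peaks: list[float]
    morphology: str

    @property
    def n_peaks(self) -> int:
        return len(self.representative_peaks)


@dataclass
class Repertoire:
    """Clusters present for one condition, with mean occurrence rates.

    occurrence[cluster_id][channel] = relative frequency of the
    cluster's windows, averaged over epochs and subjects per channel.
    """

    condition: str
    cluster_ids: set[int]
    occurrence: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Repertoire size N2 = number of included clusters."""
        return len(self.cluster_ids)


@dataclass
class UniversalityTable:
    """Cross-condition accounting: N1 and category per cluster, N2 per condition."""

    table: pd.DataFrame        # cluster_id, n1, category
    repertoire_sizes: dict[str, int]


def morphology(peaks, cfg: RepertoireConfig | None = None) -> str:
    """Morphology category from the dominant-peak count."""
    cfg = cfg or RepertoireConfig()
    n = len(peaks)
    if n == 0:
        raise ValueError("a cluster must have at least one dominant peak")
    if n >= cfg.polyrhythmic_min_peaks:
        return "polyrhythmic"
    return _MORPH_NAMES.get(n, f"{n} dominant peaks")


def _compatible(p1: np.ndarray, p2: np.ndarray, tol: int) -> bool:
    """Equal peak counts and sorted peak bins within tol, position-wise."""
    if len(p1) != len(p2):
        return False
    return bool(np.all(np.abs(np.sort(p1) - np.sort(p2)) <= tol))


def cluster_sp_classes(
    entries: list[tuple[str, int, np.ndarray, int]],
    cfg: RepertoireConfig | None = None,
) -> list[SPCluster]:
    """Group SP classes into +-0.5 Hz clusters.

    ``entries`` are (channel, class_id, peak_bins, frequency_count)
    tuples — one per actual template. Clusters form greedily: the most
    frequent unassigned class seeds a cluster and absorbs every
    unassigned class compatible with it (equal peak counts, sorted peak
    bins differing by at most peak_tolerance_bins position-wise). Ties
    rank by lower class_id, then channel order. Every class lands in
    exactly one cluster.
    """
    cfg = cfg or RepertoireConfig()
    order = sorted(range(len(entries)),
                   key=lambda i: (-entries[i][3], entries[i][1], i))
    unassigned = set(range(len(entries)))
    clusters: list[SPCluster] = []
    for i in order:
        if i not in unassigned:
            continue
        ch, cid, peaks, _ = entries[i]
        peaks = np.asarray(peaks, dtype=int)
        members = [i]
        for j in order:
            if j != i and j in unassigned and _compatible(
                    peaks, np.asarray(entries[j][2], int), cfg.peak_tolerance_bins):
                members.append(j)
        unassigned -= set(members)
        rep = [float(BIN_FREQS[k]) for k in np.sort(peaks)]
        clusters.append(SPCluster(
            cluster_id=len(clusters) + 1,
            member_classes=[(entries[m][0], entries[m][1]) for m in members],
            representative_peaks=rep,
            morphology=morphology(rep, cfg),
        ))
    return clusters


def map_to_clusters(labels: pd.DataFrame, clusters: list[SPCluster]) -> pd.Series:
    """Map per-window (channel, class_id) labels to cluster ids."""
    lut = {mc: c.cluster_id for c in clusters for mc in c.member_classes}
    keys = list(zip(labels["channel"], labels["class_id"]))
    return pd.Series([lut[k] for k in keys], index=labels.index, name="cluster_id")


def subject_presence(labels: pd.DataFrame, cluster_id: int, subject: str,
                     condition: str) -> bool:
    """Mean per-epoch occurrence of the cluster > 0 in at least one channel.

    Equivalent to: the cluster was labelled at least once for this
    subject in this condition.
    """
    sub = labels[(labels["subject"] == subject) & (labels["condition"] == condition)]
    return bool((sub["cluster_id"] == cluster_id).any())


def build_repertoire(
    labels: pd.DataFrame,
    condition: str,
    clusters: list[SPCluster],
    cfg: RepertoireConfig | None = None,
) -> Repertoire:
    """Repertoire of one condition: clusters present for >= 80% of subjects.

    ``labels`` must carry columns subject, condition, channel, epoch,
    window, cluster_id. Occurrence rates are the cluster's relative
    window frequency per epoch, averaged separately for each channel
    across all epochs and subjects.
    """
    cfg = cfg or RepertoireConfig()
    sub = labels[labels["condition"] == condition]
    subjects = sub["subject"].unique()
    if subjects.size == 0:
        raise ValueError(f"no subjects for condition {condition!r}")
    included: set[int] = set()
    for c in clusters:
        n_present = sum(
            subject_presence(sub, c.cluster_id, s, condition) for s in subjects
        )
        if n_present / subjects.size >= cfg.subject_fraction:
            included.add(c.cluster_id)
    occurrence: dict[int, dict[str, float]] = {}
    grp = sub.groupby(["channel", "subject", "epoch"])["cluster_id"]
    rates = grp.value_counts(normalize=True).rename("rate").reset_index()
    units = (sub.drop_duplicates(["channel", "subject", "epoch"])
             .groupby("channel").size())
    for cid in included:
        per_ch = (rates[rates["cluster_id"] == cid]
                  .groupby("channel")["rate"].sum())
        occurrence[cid] = {ch: float(per_ch.get(ch, 0.0)) / int(units[ch])
                           for ch in units.index}
    return Repertoire(condition, included, occurrence)


def universality_category(n1: int, n_conditions: int,
                          universal_fraction: float = 0.85) -> str:
    """unique (N1=1) / universal (N1 >= ceil(f*C)) / optional (between)."""
    if n1 < 1:
        raise ValueError("a categorized cluster must occur somewhere")
    if n1 == 1:
        return "unique"
    if n1 >= math.ceil(universal_fraction * n_conditions):
        return "universal"
    return "optional"


def categorize_clusters(
    repertoires: list[Repertoire], cfg: RepertoireConfig | None = None
) -> UniversalityTable:
    """Cross-condition N1 counts and the universal/optional/unique split.

    Only clusters that entered at least one repertoire are categorized;
    repertoire sizes (N2) are reported per condition.
    """
    cfg = cfg or RepertoireConfig()
    if len(repertoires) < 2:
        raise ValueError("need at least two conditions to categorize")
    n_cond = len(repertoires)
    all_ids = sorted(set().union(*(r.cluster_ids for r in repertoires)))
    rows = []
    for cid in all_ids:
        n1 = sum(cid in r.cluster_ids for r in repertoires)
        rows.append({"cluster_id": cid, "n1": n1,
                     "category": universality_category(n1, n_cond,
                                                       cfg.universal_fraction)})
    table = pd.DataFrame(rows, columns=["cluster_id", "n1", "category"])
    sizes = {r.condition: r.size for r in repertoires}
    return UniversalityTable(table, sizes)


def band_label(freq: float, band_map=DEFAULT_BAND_MAP) -> str:
    """Name of the band whose interval contains ``freq`` (inclusive)."""
    if not (1.0 <= freq <= 30.0):
        raise ValueError(f"frequency {freq} Hz outside [1, 30]")
    for name, lo, hi in band_map:
        if lo <= freq <= hi:
            return name
    raise ValueError(f"frequency {freq} Hz not covered by the band map")
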