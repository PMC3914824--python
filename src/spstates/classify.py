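"""Probability-classification of short-term spectral patterns.

The classifier learns, unsupervised, a small set of template spectra from
the pooled SPs of a whole study and then labels every window. Four steps:

1. *Standard set*: pooled SPs are reduced to their dominant-peak
   signatures (60% rule); recurring signatures are counted, candidates are
   ranked by count, and templates are admitted greedily subject to a
   minimal-mutual-correlation criterion — so the standard set spans the
   distinct spectral shapes actually present.
2. *Attribution*: every SP joins every standard class it correlates with
   at r >= 0.71 (many-to-many; 0.71 is the smallest two-decimal r whose
   square exceeds 0.5, i.e. accepted pairs share >50% of variance).
3. *Actualization*: per EEG channel, each class's members are averaged,
   adapting the template to that channel's spectral colouring while its
   dominant peaks stay put.
4. *Final classification*: each SP gets the single actual class with the
   maximum correlation among those >= 0.71; when none reaches 0.71 the
   unrestricted argmax is used and flagged — every window is labelled,
   there is no "undecided" category.

All correlations are Pearson on raw (non-log) power and take the maximum
over relative shifts of 0 and +-1 bin (+-0.5 Hz), absorbing the natural
day-to-day jitter of resonance frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .spectral import N_BINS, detect_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "SPClass",
    "SPClassSet",
    "LabelSequence",
    "Pool",
    "DegenerateInputError",
    "shifted_cc",
    "build_pool",
    "generate_standard_set",
    "attribute_to_classes",
    "actualize",
    "final_classify",
    "SpectralPatternClassifier",
]


class DegenerateInputError(ValueError):
    """Raised when no standard template can be formed from the pool."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the four-step classification.

    cc_accept : Pearson acceptance threshold (0.71; squared > 0.5).
    peak_threshold : fraction of the SP maximum a peak must exceed (0.60).
    shift_bins : half-width of the shift search in bins (1 = +-0.5 Hz).
    mutual_cc_max : admission to the standard set requires correlation
        with every admitted template strictly below this.
    min_count : a candidate signature must recur at least this often.
    """

    cc_accept: float = 0.71
    peak_threshold: float = 0.60
    shift_bins: int = 1
    mutual_cc_max: float = 0.71
    min_count: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.cc_accept < 1.0):
            raise ValueError("cc_accept must be in (0, 1)")
        if self.shift_bins < 0:
            raise ValueError("shift_bins must be >= 0")


@dataclass
class SPClass:
    """One template class: id, 59-bin template, dominant-peak bins."""

    class_id: int
    template: np.ndarray
    peaks: np.ndarray
    count: int = 0
    fallback: bool = False  # actual template borrowed from the standard


@dataclass
class SPClassSet:
    """Template set; study-wide when standard, per-channel when actual."""

    templates: list[SPClass]
    stage: str = "standard"  # "standard" | "actual"
    channel: str | None = None

    @property
    def class_ids(self) -> list[int]:
        return [t.class_id for t in self.templates]

    def template_matrix(self) -> np.ndarray:
        return np.vstack([t.template for t in self.templates])


@dataclass
class LabelSequence:
    """Final per-window labels for one channel of one epoch.

    Every window is labelled; low_confidence marks windows whose winning
    correlation fell below the acceptance threshold.
    """

    labels: np.ndarray
    confidence: np.ndarray
    low_confidence: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.labels) == len(self.confidence) == len(self.low_confidence)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Pool:
    """All SPs of a study with provenance, in pooled row order.

    spectra : (N, 59) array; meta : DataFrame with columns
    subject, condition, channel, epoch, window aligned row-wise.
    """

    spectra: np.ndarray
    meta: pd.DataFrame

    def __len__(self) -> int:
        return self.spectra.shape[0]


def _standardize(rows: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; zero-variance rows become 0."""
    rows = rows - rows.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(rows, axis=1, keepdims=True)
    norm[norm == 0] = np.inf
    return rows / norm


def _cc_matrix(X: np.ndarray, T: np.ndarray, shift_bins: int = 1) -> np.ndarray:
    """Max-over-shifts Pearson correlation of each row of X with each of T.

    Shifted comparisons use the overlapping region (59 - |shift| bins).
    Zero-variance inputs yield correlation 0.
    """
    X = np.atleast_2d(X)
    T = np.atleast_2d(T)
    best = _standardize(X) @ _standardize(T).T
    for s in range(1, shift_bins + 1):
        a = _standardize(X[:, s:]) @ _standardize(T[:, :-s]).T
        b = _standardize(X[:, :-s]) @ _standardize(T[:, s:]).T
        best = np.maximum(best, np.maximum(a, b))
    return np.clip(best, -1.0, 1.0)


def shifted_cc(a: np.ndarray, b: np.ndarray, cfg: ClassifierConfig | None = None) -> float:
    """Shift-corrected correlation of two 59-bin spectra.

    Maximum of the Pearson correlations at relative shifts of 0 and
    +-shift_bins bins; zero-variance overlap contributes 0.
    """
    cfg = cfg or ClassifierConfig()
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError("spectra must have equal length")
    return float(_cc_matrix(a[None, :], b[None, :], cfg.shift_bins)[0, 0])


def build_pool(entries: list[dict]) -> Pool:
    """Pool all SPs of a study with provenance.

    Each entry is a dict with keys ``subject``, ``condition``,
    ``channel``, ``epoch`` and ``spectra`` (an (n_windows, 59) array).
    Pool size is windows x channels x epochs x subjects; nothing is
    deduplicated at this step.
    """
    if not entries:
        raise ValueError("cannot build a pool from an empty dataset")
    mats, rows = [], []
    for e in entries:
        spec = np.atleast_2d(np.asarray(e["spectra"], float))
        mats.append(spec)
        for w in range(spec.shape[0]):
            rows.append({
                "subject": e["subject"], "condition": e["condition"],
                "channel": e["channel"], "epoch": e["epoch"], "window": w,
            })
    spectra = np.vstack(mats)
    if spectra.shape[1] != N_BINS:
        raise ValueError(f"expected {N_BINS}-bin spectra")
    return Pool(spectra, pd.DataFrame(rows))


def generate_standard_set(
    pool: Pool | np.ndarray, cfg: ClassifierConfig | None = None
) -> SPClassSet:
    """Form the study-wide standard template set from the pooled SPs.

    SPs are grouped by dominant-peak signature (the set of peak bins
    passing the 60% rule; "identical" SPs share a signature — exact
    floating equality would never recur). Signatures without peaks are
    excluded from candidacy. Per-signature average spectra, ranked by
    count, are admitted greedily: a candidate joins the set iff its count
    is >= min_count and its shift-corrected correlation with every
    already-admitted template stays below mutual_cc_max. Ties rank by
    first occurrence in pool order, making the result deterministic.
    """
    cfg = cfg or ClassifierConfig()
    X = pool.spectra if isinstance(pool, Pool) else np.atleast_2d(np.asarray(pool, float))
    if X.shape[0] == 0:
        raise ValueError("empty pool")
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(X):
        sig = tuple(detect_peaks(row, cfg.peak_threshold))
        if sig:
            groups.setdefault(sig, []).append(i)
    order = sorted(groups, key=lambda s: (-len(groups[s]), groups[s][0]))
    admitted: list[SPClass] = []
    for sig in order:
        idx = groups[sig]
        if len(idx) < cfg.min_count:
            continue
        cand = X[idx].mean(axis=0)
        if admitted:
            cc = _cc_matrix(cand[None, :], np.vstack([t.template for t in admitted]),
                            cfg.shift_bins)
            if cc.max() >= cfg.mutual_cc_max:
                continue
        admitted.append(SPClass(
            class_id=len(admitted) + 1, template=cand,
            peaks=detect_peaks(cand, cfg.peak_threshold), count=len(idx),
        ))
    if not admitted:
        raise DegenerateInputError(
            "no recurring peaked spectral pattern found; cannot form a "
            "standard set from this input"
        )
    return SPClassSet(admitted, stage="standard")


def attribute_to_classes(
    X: np.ndarray, standards: SPClassSet, cfg: ClassifierConfig | None = None
) -> np.ndarray:
    """Many-to-many membership: SP i belongs to class j iff cc >= 0.71.

    Returns a boolean (n_sps, n_classes) matrix; a row may have zero, one
    or several True entries at this stage.
    """
    cfg = cfg or ClassifierConfig()
    if not standards.templates:
        raise ValueError("empty standard set")
    cc = _cc_matrix(np.atleast_2d(X), standards.template_matrix(), cfg.shift_bins)
    return cc >= cfg.cc_accept


def actualize(
    X: np.ndarray,
    membership: np.ndarray,
    standards: SPClassSet,
    channel: str,
    cfg: ClassifierConfig | None = None,
) -> SPClassSet:
    """Average each class's member SPs of one channel into actual templates.

    Classes with no members on this channel keep the standard template
    (flagged). If a class's dominant peaks drift more than one bin from
    the standard's, a warning is logged — actualization is meant to
    reshape the spectrum around fixed main peaks, not move them.
    """
    cfg = cfg or ClassifierConfig()
    X = np.atleast_2d(X)
    actuals = []
    for j, std in enumerate(standards.templates):
        members = X[membership[:, j]]
        if members.shape[0] == 0:
            actuals.append(SPClass(std.class_id, std.template.copy(), std.peaks.copy(),
                                   count=0, fallback=True))
            continue
        tpl = members.mean(axis=0)
        peaks = detect_peaks(tpl, cfg.peak_threshold)
        matched = all(np.min(np.abs(peaks - p)) <= 1 for p in std.peaks) if peaks.size else False
        if not matched:
            logger.warning(
                "actual template of class %d on channel %s moved its dominant "
                "peaks by more than one bin", std.class_id, channel,
            )
        actuals.append(SPClass(std.class_id, tpl, peaks, count=int(members.shape[0])))
    return SPClassSet(actuals, stage="actual", channel=channel)


def final_classify(
    X: np.ndarray, actuals: SPClassSet, cfg: ClassifierConfig | None = None
) -> LabelSequence:
    """Label every SP with its best actual class.

    The label is the argmax correlation among classes reaching cc_accept;
    when no class reaches it, the unrestricted argmax is used with the
    low-confidence flag set (every window gets a label). Ties break to
    the lower class_id.
    """
    cfg = cfg or ClassifierConfig()
    X = np.atleast_2d(X)
    cc = _cc_matrix(X, actuals.template_matrix(), cfg.shift_bins)
    ids = np.asarray(actuals.class_ids)
    accepted = cc >= cfg.cc_accept
    any_ok = accepted.any(axis=1)
    masked = np.where(accepted, cc, -np.inf)
    choice = np.where(any_ok, masked.argmax(axis=1), cc.argmax(axis=1))
    conf = cc[np.arange(X.shape[0]), choice]
    return LabelSequence(ids[choice], conf, ~any_ok)


class SpectralPatternClassifier(BaseEstimator):
    """Unsupervised template classifier for short-term EEG spectra.

    Scikit-learn-style estimator over the four-step procedure: ``fit``
    pools the training spectra, extracts the standard set and actualizes
    it per channel; ``predict`` labels new (or the same) spectra with the
    per-channel actual templates. Channels unseen at fit time are labelled
    with the study-wide standard templates.

    Parameters mirror :class:`ClassifierConfig`.

    Attributes
    ----------
    standard_set_ : SPClassSet
        Study-wide standard templates.
    actual_sets_ : dict[str, SPClassSet]
        Per-channel actualized templates.
    classes_ : ndarray
        Sorted class ids.
    """

    def __init__(self, cc_accept: float = 0.71, peak_threshold: float = 0.60,
                 shift_bins: int = 1, mutual_cc_max: float = 0.71,
                 min_count: int = 2):
        self.cc_accept = cc_accept
        self.peak_threshold = peak_threshold
        self.shift_bins = shift_bins
        self.mutual_cc_max = mutual_cc_max
        self.min_count = min_count

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            cc_accept=self.cc_accept, peak_threshold=self.peak_threshold,
            shift_bins=self.shift_bins, mutual_cc_max=self.mutual_cc_max,
            min_count=self.min_count,
        )

    def fit(self, X: np.ndarray, y=None, *, channels=None) -> "SpectralPatternClassifier":
        """Learn standard and per-channel actual templates.

        X : (n_sps, 59) pooled spectra; channels : per-row channel labels
        (a single study-wide channel is assumed when omitted).
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != N_BINS:
            raise ValueError(f"X must have {N_BINS} columns")
        channels = (np.asarray(channels) if channels is not None
                    else np.full(X.shape[0], "all"))
        cfg = self._config()
        self.standard_set_ = generate_standard_set(X, cfg)
        self.actual_sets_ = {}
        for ch in pd.unique(channels):
            Xc = X[channels == ch]
            mem = attribute_to_classes(Xc, self.standard_set_, cfg)
            self.actual_sets_[ch] = actualize(Xc, mem, self.standard_set_, str(ch), cfg)
        self.classes_ = np.asarray(self.standard_set_.class_ids)
        self.n_classes_ = self.classes_.size
        return self

    def _actuals_for(self, ch) -> SPClassSet:
        return self.actual_sets_.get(ch, self.standard_set_)

    def label_sequence(self, X: np.ndarray, channel=None) -> LabelSequence:
        """Full labelling (labels, confidences, low-confidence flags)."""
        if not hasattr(self, "standard_set_"):
            raise ValueError("classifier is not fitted")
        ch = channel if channel is not None else "all"
        return final_classify(X, self._actuals_for(ch), self._config())

    def predict(self, X: np.ndarray, *, channels=None) -> np.ndarray:
        """Class id per SP, using each row's channel-specific templates."""
        X = np.atleast_2d(np.asarray(X, float))
        if channels is None:
            return self.label_sequence(X).labels
        channels = np.asarray(channels)
        out = np.empty(X.shape[0], dtype=int)
        for ch in pd.unique(channels):
            m = channels == ch
            out[m] = self.label_sequence(X[m], ch).labels
        return out

    def decision_function(self, X: np.ndarray, *, channels=None) -> np.ndarray:
        """Shift-corrected correlation of each SP with each class template."""
        X = np.atleast_2d(np.asarray(X, float))
        cfg = self._config()
        if channels is None:
            return _cc_matrix(X, self._actuals_for("all").template_matrix(),
                              cfg.shift_bins)
        channels = np.asarray(channels)
        out = np.empty((X.shape[0], self.n_classes_))
        for ch in pd.unique(channels):
            m = channels == ch
            out[m] = _cc_matrix(X[m], self._actuals_for(ch).template_matrix(),
                                cfg.shift_bins)
        return out
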