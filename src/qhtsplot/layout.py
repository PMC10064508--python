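"""Record ordering, curve-class assignment and color mapping.

The waterfall plot draws compounds in the order they are given: the
identity ordering is the contract, and every sort here is stable so
that ties fall back to file order.  Users typically pre-sort by
activity criteria -- e.g. by curve class and then by decreasing AC50
within each class -- and this module provides those sorts natively.

The curve-class labels are a deliberately simplified surrogate for the
multi-class qHTS curve-classification schemes used at screening
centers: four labels (complete, partial, low_efficacy, inactive)
assigned by explicit, documented threshold rules, not a re-derivation
of any center's criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import ConfigurationError, QHTSDataset, ResponseRecord, efficacy
from .curves import polarity

CURVE_CLASSES = ("complete", "partial", "low_efficacy", "inactive")
_CLASS_RANK = {c: i for i, c in enumerate(CURVE_CLASSES)}

_SORT_CRITERIA = {"file_order", "curve_class", "ac50", "efficacy", "readout", "comp_id"}


@dataclass
class OrderingSpec:
    """Ordered list of (criterion, direction) sort keys.

    Criteria: ``file_order``, ``curve_class``, ``ac50``, ``efficacy``,
    ``readout``, ``comp_id``, or ``annotation:<name>`` for any extra
    input column.  Directions: ``asc`` / ``desc``.  An empty key list
    is the identity (file order preserved).
    """

    keys: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def parse(cls, tokens: list[str]) -> "OrderingSpec":
        """Build from CLI-style ``key`` or ``key:dir`` tokens."""
        keys = []
        for tok in tokens:
            crit, _, direction = tok.partition(":")
            direction = direction or "asc"
            if direction not in ("asc", "desc"):
                raise ConfigurationError(f"sort direction must be asc or desc, got {direction!r}")
            keys.append((crit.strip(), direction))
        return cls(keys=keys)


@dataclass
class ClassThresholds:
    """Tunable parameters of the surrogate curve-class rules.

    min_efficacy: |s_inf - s0| below this (% activity) is inactive.
    low_efficacy_cap: |efficacy| in [min_efficacy, cap] with the curve
        midpoint outside the well-covered range is low_efficacy.
    plateau_margin: log units the AC50 must sit inside *both* grid
        extremes for the response to count as complete (both plateaus
        covered by the titration).
    """

    min_efficacy: float = 25.0
    low_efficacy_cap: float = 50.0
    plateau_margin: float = 1.0


def assign_curve_class(
    rec: ResponseRecord,
    grid: list[float],
    thresholds: Optional[ClassThresholds] = None,
) -> str:
    """Assign one of the four surrogate curve-class labels to a record.

    Rules, evaluated in order:

    1. no complete parameters, or |efficacy| < min_efficacy -> inactive
    2. AC50 at least ``plateau_margin`` log units inside both grid
       extremes (both asymptotes reached within the titration) -> complete
    3. AC50 inside the tested range but a plateau not reached -> partial
    4. |efficacy| <= low_efficacy_cap -> low_efficacy
    5. otherwise (strong response whose midpoint lies beyond the tested
       range) -> partial

    Deterministic and independent of the record's dataset position.
    """
    t = thresholds or ClassThresholds()
    if not rec.has_complete_params():
        return "inactive"
    eff = abs(efficacy(rec.params))
    if eff < t.min_efficacy:
        return "inactive"
    lo, hi = min(grid), max(grid)
    ac50 = rec.params.log_ac50_m
    if lo + t.plateau_margin <= ac50 <= hi - t.plateau_margin:
        return "complete"
    if lo <= ac50 <= hi:
        return "partial"
    if eff <= t.low_efficacy_cap:
        return "low_efficacy"
    return "partial"


def classify_dataset(
    ds: QHTSDataset, thresholds: Optional[ClassThresholds] = None
) -> list[str]:
    """Curve-class label per record, in dataset order."""
    return [assign_curve_class(r, ds.log_conc_m, thresholds) for r in ds.records]


def _sort_value(ds: QHTSDataset, classes, criterion: str, i: int):
    """(missing_flag, value) sort key for one record under one criterion."""
    rec = ds.records[i]
    if criterion == "file_order":
        return (0, i)
    if criterion == "curve_class":
        return (0, _CLASS_RANK[classes[i]])
    if criterion == "ac50":
        if not rec.has_complete_params():
            return (1, 0.0)
        return (0, rec.params.log_ac50_m)
    if criterion == "efficacy":
        if not rec.has_complete_params():
            return (1, 0.0)
        return (0, efficacy(rec.params))
    if criterion == "readout":
        return (0, rec.readout)
    if criterion == "comp_id":
        return (0, rec.comp_id)
    if criterion.startswith("annotation:"):
        name = criterion.split(":", 1)[1]
        if name not in rec.annotations:
            raise ConfigurationError(
                f"annotation column {name!r} is absent from record {i}"
            )
        return (0, rec.annotations[name])
    raise ConfigurationError(f"unknown ordering criterion {criterion!r}")


def order_records(
    ds: QHTSDataset,
    spec: Optional[OrderingSpec] = None,
    thresholds: Optional[ClassThresholds] = None,
) -> list[int]:
    """Permutation of record indices realizing the ordering spec.

    Stable: ties -- and the empty spec -- preserve file order.  ``ac50``
    and ``efficacy`` sort records lacking parameters last regardless of
    direction.  Successive keys are applied by repeated stable sorts,
    least-significant key first.
    """
    idx = list(range(ds.n_records))
    if spec is None or not spec.keys:
        return idx
    classes = None
    if any(c == "curve_class" for c, _ in spec.keys):
        classes = classify_dataset(ds, thresholds)
    for criterion, direction in reversed(spec.keys):
        if criterion not in _SORT_CRITERIA and not criterion.startswith("annotation:"):
            raise ConfigurationError(f"unknown ordering criterion {criterion!r}")
        reverse = direction == "desc"
        keys = {i: _sort_value(ds, classes, criterion, i) for i in idx}
        if reverse and all(isinstance(keys[i][1], (int, float)) for i in idx):
            # negate numerics so missing-params records stay last under desc
            idx.sort(key=lambda i: (keys[i][0], -keys[i][1]))
        else:
            idx.sort(key=lambda i: keys[i], reverse=reverse)
    return idx


# Fig-style defaults: fully efficacious sigmoids in red, partial in
# yellow, weak responses in green, inactives as gray dots; for
# polarity coloring, gain-of-signal blue and loss-of-signal red.
_DEFAULT_COLORS = {
    "complete": "#d62728",      # red
    "partial": "#e6b800",       # yellow
    "low_efficacy": "#2ca02c",  # green
    "inactive": "#9a9a9a",      # gray
    "gain": "#1f77b4",          # blue
    "loss": "#d62728",          # red
    "flat": "#9a9a9a",
}

# deterministic fallback cycle for user-defined group labels (readouts etc.)
_CYCLE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def default_palette(
    groups: list[str], overrides: Optional[dict[str, str]] = None
) -> dict[str, str]:
    """Deterministic label -> color map; user overrides win.

    Known labels (curve classes, gain/loss/flat) get their conventional
    colors; unknown labels are assigned from a fixed cycle in first-seen
    order, so the same label list always yields the same mapping.
    """
    overrides = overrides or {}
    palette: dict[str, str] = {}
    cycle_pos = 0
    for g in groups:
        if g in palette:
            continue
        if g in overrides:
            palette[g] = overrides[g]
        elif g in _DEFAULT_COLORS:
            palette[g] = _DEFAULT_COLORS[g]
        else:
            palette[g] = _CYCLE[cycle_pos % len(_CYCLE)]
            cycle_pos += 1
    return palette


def polarity_labels(ds: QHTSDataset) -> list[Optional[str]]:
    """gain/loss/flat label per record; None where parameters are absent."""
    return [
        polarity(r.params) if r.has_complete_params() else None for r in ds.records
    ]
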