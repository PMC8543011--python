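"""Event-level gating and reactivity profiling of TIL activation assays.

This module implements the flow-cytometry side of the tumor-reactivity
workflow: quantile-based gate thresholds derived from the unstimulated
("TILs alone") control, per-event marker positivity calls, the three
union reactivity definitions (CD137+, Antitumor Function+, Total Reactive),
background subtraction with the 0.01%/100% clamping conventions,
Boolean-combination (polyfunctionality) profiles over CD137/TNF/IFNγ,
marker-contribution decomposition, and protein-transport-inhibitor
modulation of surface vs intracellular CD137.

Events are carried as pandas DataFrames of transformed (arcsinh-scale)
intensities, one row per event.  CD137 is measured on two channels —
surface (S-CD137) and intracellular (IC-CD137) — and the derived total
CD137 call (T-CD137) is the Boolean OR of the two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Fluorescence channels on the panel (transformed scale).
S_CD137 = "S_CD137"
IC_CD137 = "IC_CD137"
TNF = "TNF"
IFNG = "IFNG"
CD107A = "CD107a"
CD4 = "CD4"
CD8 = "CD8"
VIABILITY = "viability"

ACTIVATION_CHANNELS: tuple[str, ...] = (S_CD137, IC_CD137, TNF, IFNG, CD107A)
SUBSET_CHANNELS: tuple[str, ...] = (CD4, CD8)
ALL_CHANNELS: tuple[str, ...] = ACTIVATION_CHANNELS + SUBSET_CHANNELS + (VIABILITY,)

# Derived marker: total CD137 = surface OR intracellular.
T_CD137 = "T_CD137"

# Marker panel in fixed order; this order is also the deterministic
# tie-break for the contribution decomposition.
MARKER_PANEL: tuple[str, ...] = (T_CD137, TNF, IFNG, CD107A)
COMBO_MARKERS: tuple[str, ...] = (T_CD137, TNF, IFNG)
ANTITUMOR_FUNCTION_MARKERS: tuple[str, ...] = (TNF, IFNG, CD107A)

CONDITIONS: tuple[str, ...] = ("autologous", "allogeneic", "alone")
INHIBITORS: tuple[str, ...] = ("none", "BFA", "MN", "BFA+MN")

PERCENT_FLOOR = 0.01
PERCENT_CAP = 100.0

_MARKER_DISPLAY = {T_CD137: "CD137", TNF: "TNF", IFNG: "IFNG", CD107A: "CD107a"}


class ChannelError(KeyError):
    """A required channel is missing from an event table."""


class ConfigurationError(ValueError):
    """An input value violates a documented precondition."""


@dataclass
class EventTable:
    """Flow-cytometry events for one sample under one condition.

    Parameters
    ----------
    data
        events × channels DataFrame of transformed intensities; must
        contain every channel in :data:`ALL_CHANNELS`.
    sample_id
        Identifier of the biological sample (patient TIL culture).
    condition
        One of ``autologous`` (stimulated with autologous tumor cells),
        ``allogeneic`` (irrelevant-tumor control) or ``alone``
        (unstimulated control).
    inhibitor
        Protein-transport inhibitor condition during the co-culture.
    """

    data: pd.DataFrame
    sample_id: str
    condition: str
    inhibitor: str = "none"

    def __post_init__(self) -> None:
        missing = [c for c in ALL_CHANNELS if c not in self.data.columns]
        if missing:
            raise ChannelError(f"event table is missing channels: {missing}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.inhibitor not in INHIBITORS:
            raise ConfigurationError(
                f"inhibitor {self.inhibitor!r} not in {INHIBITORS}"
            )
        values = self.data[list(ALL_CHANNELS)].to_numpy()
        if not np.isfinite(values).all():
            raise ConfigurationError("event intensities must be finite")

    @property
    def n_events(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GateThresholds:
    """Per-channel positivity cutoffs with their provenance.

    Thresholds are set from the unstimulated control: the stated
    quantile of each channel's control intensity distribution. An event
    is positive when its intensity is strictly greater than the cutoff.
    """

    cutoffs: Mapping[str, float]
    control_id: str
    quantile: float


@dataclass(frozen=True)
class ReactivityResult:
    """Per-sample, per-subset reactivity summary.

    ``markers``/``unions`` map marker or union-metric names to raw
    percent positive; ``subtracted`` holds the background-subtracted and
    clamped values (floor 0.01, cap 100).  Union metrics follow the
    three definitions: ``CD137`` (total CD137 positive), ``AF``
    (Antitumor Function: at least one of TNF/IFNγ/CD107a) and
    ``TotalReactive`` (at least one of all four markers).
    """

    sample_id: str
    subset: str
    n_live: int
    markers: Mapping[str, float]
    unions: Mapping[str, float]
    subtracted_markers: Mapping[str, float]
    subtracted_unions: Mapping[str, float]
    control_markers: Mapping[str, float]
    control_unions: Mapping[str, float]


@dataclass(frozen=True)
class CombinationProfile:
    """Polyfunctionality profile over the 7 reactive marker combinations.

    ``fractions`` maps the seven non-all-negative CD137/TNF/IFNγ
    combination labels (e.g. ``CD137+TNF-IFNG-``) to their share of the
    reactive population after per-combination background subtraction and
    renormalization.  ``grouping`` is the coarser three-way split
    {CD137+AF-, CD137-AF+, CD137+AF+} over cells positive for at least
    one panel marker (Antitumor Function includes CD107a when present).
    """

    subset: str
    fractions: Mapping[str, float]
    grouping: Mapping[str, float]
    n_reactive: int
    n_parent: int


@dataclass(frozen=True)
class ContributionDecomposition:
    """Incremental union gains per marker, in order of relevance.

    Markers are ordered by decreasing single-marker positive fraction;
    the k-th gain is the share of the total reactive union contributed
    by adding the k-th marker to the union of the first k−1.
    """

    order: tuple[str, ...]
    gains: Mapping[str, float]


@dataclass(frozen=True)
class ModulationResult:
    """Inhibitor modulation of CD137 relative to the no-inhibitor reference."""

    inhibitor: str
    cd137_form: str
    normalized: float
    percent_modulation: float


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def set_thresholds(
    control: EventTable,
    quantile: float = 0.999,
    channels: Sequence[str] = ACTIVATION_CHANNELS,
    viability_cutoff: float | None = None,
) -> GateThresholds:
    """Derive positivity cutoffs from the unstimulated control.

    The cutoff for each activation channel is the given quantile of the
    control ("TILs alone") intensity distribution, so at most
    ``1 - quantile`` of control events exceed it.  The viability dye is
    bimodal (dim live cells, bright dead cells) rather than
    tail-gated, so its cutoff defaults to the midpoint of the control
    range; pass ``viability_cutoff`` to place it explicitly.
    """
    if control.condition != "alone":
        raise ConfigurationError(
            "thresholds must be derived from the 'alone' control condition, "
            f"got {control.condition!r}"
        )
    if not 0.5 < quantile < 1.0:
        raise ConfigurationError(f"quantile must lie in (0.5, 1), got {quantile}")
    if control.n_events == 0:
        raise ConfigurationError("control event table is empty")
    cutoffs = {
        ch: float(control.data[ch].quantile(quantile)) for ch in channels
    }
    if viability_cutoff is None:
        col = control.data[VIABILITY]
        viability_cutoff = float(col.min() + col.max()) / 2.0
    cutoffs[VIABILITY] = viability_cutoff
    return GateThresholds(cutoffs=cutoffs, control_id=control.sample_id, quantile=quantile)


def gate_live(events: EventTable, thresholds: GateThresholds) -> pd.DataFrame:
    """Return the live-event subframe (viability dye below its cutoff)."""
    cut = thresholds.cutoffs.get(VIABILITY)
    if cut is None:
        return events.data
    return events.data.loc[events.data[VIABILITY] <= cut]


def split_subsets(
    events: EventTable, thresholds: GateThresholds | None = None,
    cd4_cutoff: float | None = None, cd8_cutoff: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Partition events into mutually exclusive CD8/CD4 subsets.

    Gates on the two lineage channels; double-positive and
    double-negative events are excluded.  Cutoffs may be given directly
    or taken from ``thresholds`` when it covers the lineage channels;
    otherwise the midpoint of each channel's range is used, which is
    adequate for well-separated lineage staining.
    """
    data = events.data
    if cd4_cutoff is None:
        if thresholds is not None and CD4 in thresholds.cutoffs:
            cd4_cutoff = thresholds.cutoffs[CD4]
        else:
            cd4_cutoff = float(data[CD4].min() + data[CD4].max()) / 2.0
    if cd8_cutoff is None:
        if thresholds is not None and CD8 in thresholds.cutoffs:
            cd8_cutoff = thresholds.cutoffs[CD8]
        else:
            cd8_cutoff = float(data[CD8].min() + data[CD8].max()) / 2.0
    cd4_pos = data[CD4] > cd4_cutoff
    cd8_pos = data[CD8] > cd8_cutoff
    return {
        "CD8": data.loc[cd8_pos & ~cd4_pos],
        "CD4": data.loc[cd4_pos & ~cd8_pos],
    }


def call_positivity(
    events: EventTable | pd.DataFrame, thresholds: GateThresholds
) -> pd.DataFrame:
    """Call per-event marker positivity against gate thresholds.

    Live events only (viability gate applied first when ``events`` is an
    :class:`EventTable`).  An event is positive on a channel when its
    intensity is strictly greater than the cutoff; the derived T-CD137
    column is the element-wise OR of the surface and intracellular
    CD137 calls.
    """
    if isinstance(events, EventTable):
        data = gate_live(events, thresholds)
    else:
        data = events
    missing = [ch for ch in ACTIVATION_CHANNELS if ch not in thresholds.cutoffs]
    if missing:
        raise ChannelError(f"thresholds missing for channels: {missing}")
    missing = [ch for ch in ACTIVATION_CHANNELS if ch not in data.columns]
    if missing:
        raise ChannelError(f"event table missing channels: {missing}")
    pos = pd.DataFrame(index=data.index)
    for ch in ACTIVATION_CHANNELS:
        pos[ch] = data[ch].to_numpy() > thresholds.cutoffs[ch]
    pos[T_CD137] = pos[S_CD137] | pos[IC_CD137]
    return pos


# ---------------------------------------------------------------------------
# background subtraction and clamping
# ---------------------------------------------------------------------------

def subtract_background(
    stimulated_pct: float, control_pct: float, floor: float = PERCENT_FLOOR
) -> float:
    """Subtract the unstimulated-control percentage, with a reporting floor.

    Negative differences are clamped to ``floor`` (0.01% by default),
    the value negative subtractions are converted to for statistical
    analysis and display.
    """
    for name, v in (("stimulated_pct", stimulated_pct), ("control_pct", control_pct)):
        if not 0.0 <= v <= 100.0:
            raise ConfigurationError(f"{name} must be in [0, 100], got {v}")
    return max(stimulated_pct - control_pct, floor)


def clamp_percent(
    value: float, floor: float = PERCENT_FLOOR, cap: float = PERCENT_CAP
) -> float:
    """Clamp a reported percentage to the [floor, cap] reporting scale.

    Values below the floor become 0.01% and values exceeding 100% after
    normalization become 100%.
    """
    return min(max(value, floor), cap)


# ---------------------------------------------------------------------------
# reactivity metrics
# ---------------------------------------------------------------------------

def _percent(mask: np.ndarray | pd.Series, n: int) -> float:
    return 100.0 * float(np.count_nonzero(mask)) / n


def _union_masks(pos: pd.DataFrame) -> dict[str, pd.Series]:
    af = pos[list(ANTITUMOR_FUNCTION_MARKERS)].any(axis=1)
    return {
        "CD137": pos[T_CD137],
        "AF": af,
        "TotalReactive": pos[T_CD137] | af,
    }


def reactivity_metrics(
    pos: pd.DataFrame,
    control_pos: pd.DataFrame,
    subset: str,
    sample_id: str = "",
) -> ReactivityResult:
    """Compute the three union reactivity definitions for one subset.

    TIL activation is reported as the percentage of live subset events
    positive for (1) total CD137, (2) at least one of TNF, IFNγ and
    CD107a ("Antitumor Function+"), and (3) at least one of all four
    markers ("Total Reactive"), each minus the matched unstimulated
    control and clamped to the [0.01, 100] reporting scale.
    """
    n = len(pos)
    if n == 0:
        raise ConfigurationError(f"no live events in subset {subset!r}")
    n_ctrl = len(control_pos)
    if n_ctrl == 0:
        raise ConfigurationError("no live events in control")

    marker_pct = {m: _percent(pos[m], n) for m in MARKER_PANEL}
    ctrl_marker_pct = {m: _percent(control_pos[m], n_ctrl) for m in MARKER_PANEL}
    union_pct = {k: _percent(v, n) for k, v in _union_masks(pos).items()}
    ctrl_union_pct = {k: _percent(v, n_ctrl) for k, v in _union_masks(control_pos).items()}

    sub_markers = {
        m: clamp_percent(subtract_background(marker_pct[m], ctrl_marker_pct[m]))
        for m in MARKER_PANEL
    }
    sub_unions = {
        k: clamp_percent(subtract_background(union_pct[k], ctrl_union_pct[k]))
        for k in union_pct
    }
    return ReactivityResult(
        sample_id=sample_id,
        subset=subset,
        n_live=n,
        markers=marker_pct,
        unions=union_pct,
        subtracted_markers=sub_markers,
        subtracted_unions=sub_unions,
        control_markers=ctrl_marker_pct,
        control_unions=ctrl_union_pct,
    )


# ---------------------------------------------------------------------------
# Boolean combination profiling
# ---------------------------------------------------------------------------

def combo_label(state: Sequence[bool], markers: Sequence[str] = COMBO_MARKERS) -> str:
    """Human-readable label for a positivity combination, e.g. CD137+TNF-IFNG-."""
    return "".join(
        f"{_MARKER_DISPLAY.get(m, m)}{'+' if s else '-'}"
        for m, s in zip(markers, state)
    )


def iter_combos(markers: Sequence[str] = COMBO_MARKERS, include_all_negative: bool = False):
    """Yield positivity-state tuples for a marker panel, most-positive first."""
    for state in itertools.product((True, False), repeat=len(markers)):
        if not include_all_negative and not any(state):
            continue
        yield state


def combination_counts(
    pos: pd.DataFrame, markers: Sequence[str] = COMBO_MARKERS
) -> pd.Series:
    """Count events in each of the 2^k positivity combinations.

    The counts over all combinations (including the all-negative one)
    partition the events exactly.
    """
    cols = [pos[m].to_numpy() for m in markers]
    code = np.zeros(len(pos), dtype=int)
    for i, col in enumerate(cols):
        code |= col.astype(int) << (len(markers) - 1 - i)
    counts = {}
    for state in iter_combos(markers, include_all_negative=True):
        bits = sum(int(s) << (len(markers) - 1 - i) for i, s in enumerate(state))
        counts[combo_label(state, markers)] = int(np.sum(code == bits))
    return pd.Series(counts)


def combination_profile(
    pos: pd.DataFrame,
    control_pos: pd.DataFrame,
    subset: str = "CD8",
    per_combination_subtraction: bool = True,
    include_cd107a_grouping: bool = True,
) -> CombinationProfile:
    """Profile the 7 reactive CD137/TNF/IFNγ combinations.

    Each combination's percentage of the parent (live subset) population
    is background-subtracted against the matched control combination
    (floored at 0 — the 0.01% reporting floor applies to reported
    percentages, not to these internal shares) and the seven reactive
    combinations are renormalized to sum to 1.  With
    ``per_combination_subtraction=False`` only the union is
    background-corrected and raw combination shares are used.

    The three-way grouping splits cells positive for at least one panel
    marker into CD137+AF-, CD137-AF+ and CD137+AF+, where Antitumor
    Function (AF) covers TNF/IFNγ and, when
    ``include_cd107a_grouping``, CD107a.
    """
    n_parent = len(pos)
    if n_parent == 0:
        raise ConfigurationError("no events to profile")
    n_ctrl = len(control_pos)

    counts = combination_counts(pos, COMBO_MARKERS)
    ctrl_counts = combination_counts(control_pos, COMBO_MARKERS)
    labels = [combo_label(s) for s in iter_combos(COMBO_MARKERS)]

    stim_pct = counts[labels] / n_parent * 100.0
    ctrl_pct = ctrl_counts[labels] / max(n_ctrl, 1) * 100.0
    if per_combination_subtraction:
        corrected = (stim_pct - ctrl_pct).clip(lower=0.0)
    else:
        corrected = stim_pct
    total = corrected.sum()
    if total <= 0:
        raise ConfigurationError("no reactive events after background subtraction")
    fractions = (corrected / total).to_dict()

    af_markers = list(ANTITUMOR_FUNCTION_MARKERS)
    if not include_cd107a_grouping:
        af_markers = [TNF, IFNG]
    af = pos[af_markers].any(axis=1)
    cd137 = pos[T_CD137]
    reactive = cd137 | af
    n_reactive = int(reactive.sum())
    if n_reactive == 0:
        raise ConfigurationError("no reactive events for grouping")
    grouping = {
        "CD137+AF-": float((cd137 & ~af).sum()) / n_reactive,
        "CD137-AF+": float((~cd137 & af).sum()) / n_reactive,
        "CD137+AF+": float((cd137 & af).sum()) / n_reactive,
    }
    return CombinationProfile(
        subset=subset,
        fractions=fractions,
        grouping=grouping,
        n_reactive=n_reactive,
        n_parent=n_parent,
    )


# ---------------------------------------------------------------------------
# contribution decomposition
# ---------------------------------------------------------------------------

def contribution_order(
    pos: pd.DataFrame, markers: Sequence[str] = MARKER_PANEL
) -> ContributionDecomposition:
    """Decompose the reactive union into ordered per-marker gains.

    Markers are sorted by decreasing single-marker positive fraction
    (ties broken by the fixed panel order CD137, TNF, IFNγ, CD107a);
    the k-th marker's gain is the number of events it newly adds to the
    union of the first k−1 markers, expressed as a percentage of the
    total reactive union.  Gains are non-negative and sum to 100%.
    """
    union_all = pos[list(markers)].any(axis=1)
    n_union = int(union_all.sum())
    if n_union == 0:
        raise ConfigurationError("no reactive events: union of markers is empty")
    singles = {m: float(pos[m].sum()) for m in markers}
    order = sorted(markers, key=lambda m: (-singles[m], markers.index(m)))
    gains: dict[str, float] = {}
    covered = np.zeros(len(pos), dtype=bool)
    for m in order:
        new = pos[m].to_numpy() & ~covered
        gains[m] = 100.0 * float(new.sum()) / n_union
        covered |= pos[m].to_numpy()
    return ContributionDecomposition(order=tuple(order), gains=gains)


# ---------------------------------------------------------------------------
# inhibitor modulation
# ---------------------------------------------------------------------------

def inhibitor_modulation(
    condition_pct: float,
    reference_pct: float,
    inhibitor: str = "none",
    cd137_form: str = "total",
) -> ModulationResult:
    """Normalize a CD137 percentage to its no-inhibitor reference.

    Returns the ratio and the percent modulation (ratio − 1) × 100, the
    convention used to report how transport inhibitors shift surface,
    intracellular and total CD137 detection.
    """
    if reference_pct <= 0:
        raise ConfigurationError(
            "modulation undefined: no-inhibitor reference percentage is zero"
        )
    normalized = condition_pct / reference_pct
    return ModulationResult(
        inhibitor=inhibitor,
        cd137_form=cd137_form,
        normalized=normalized,
        percent_modulation=(normalized - 1.0) * 100.0,
    )


# ---------------------------------------------------------------------------
# paired testing
# ---------------------------------------------------------------------------

def paired_marker_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for matched samples.

    Uses the exact null distribution when the sample is small and free
    of ties/zeros (scipy's default policy).  All-zero differences return
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired vectors must have equal length")
    if len(a) < 5:
        raise ConfigurationError("paired test needs at least 5 matched samples")
    if np.all(a == b):
        return 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue)
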