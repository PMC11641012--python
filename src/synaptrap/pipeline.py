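"""Force-extension-curve pipeline: preprocessing, cycle segmentation,
rupture detection, contour-length fingerprinting and pathway classification.

The pipeline turns a raw (time, force, extension) record of repeated
stretch-relax cycles into per-cycle interaction categories:

* ``i``    - initial hairpin-bound state without a synaptic complex;
  reports the protein unbinding force ``F_unbind``.
* ``ii``   - synaptic complex disassembling via one or more intermediate
  states (noncanonical pathway); reports the disassembly force ``F_diss``.
* ``iii``  - synaptic complex disassembling to the hairpin-bound state in
  a single step matching the 71-nm contour-length fingerprint (canonical
  pathway); reports ``F_diss``.
* ``none`` - no protein interaction identified (e.g. only free hairpin
  unfolding below the 6-pN threshold).

All steps are deterministic: repeated runs on the same trace produce
identical classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from synaptrap.polymer import (
    STATE_ORDER,
    ConstructState,
    SegmentFit,
    ThermalContext,
    fit_segment_contour,
    hybrid_extension,
)

__all__ = [
    "ForceExtensionTrace",
    "PullCycle",
    "RuptureEvent",
    "SegmentAssignment",
    "CycleClassification",
    "downsample",
    "correct_crosstalk",
    "segment_cycles",
    "detect_ruptures",
    "assign_states",
    "fit_segments",
    "measure_contour_change",
    "match_fingerprint",
    "classify_cycle",
    "extract_unbind_force",
    "dissipated_work",
    "analyze_cycle",
]


@dataclass
class ForceExtensionTrace:
    """Sampled (time, force, extension) record.

    time in s, force in pN, extension in nm, sampling_rate in Hz.
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        n = len(self.time)
        if len(self.force) != n or len(self.extension) != n:
            raise ValueError("time/force/extension must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.time)

    def slice(self, start: int, stop: int) -> "ForceExtensionTrace":
        return ForceExtensionTrace(self.time[start:stop],
                                   self.force[start:stop],
                                   self.extension[start:stop],
                                   self.sampling_rate)


@dataclass
class PullCycle:
    """One stretch(-relax) cycle; indices refer to the parent trace."""

    pull: ForceExtensionTrace
    relax: ForceExtensionTrace | None
    peak_force: float
    cycle_id: int = 0
    analyzable: bool = True   # False when the peak force missed the minimum


@dataclass
class RuptureEvent:
    """One detected force-drop transition on a pull trace."""

    index: int                 # sample position within the pull slice
    force: float               # pN, local maximum before the drop
    force_drop: float          # pN
    extension_jump: float = 0.0
    delta_L: float = float("nan")   # contour-length change across the event
    from_state: str = ""
    to_state: str = ""


@dataclass
class SegmentAssignment:
    """State label for one inter-event segment of a pull trace."""

    start: int
    stop: int
    label: str                 # state label or "unknown"
    rms_residual: float
    fit: SegmentFit | None = None

    @property
    def contour_coordinate(self) -> float | None:
        if self.fit is not None and self.fit.success:
            return self.fit.contour_coordinate
        return None


@dataclass
class CycleClassification:
    category: str              # "i", "ii", "iii" or "none"
    events: list[RuptureEvent] = field(default_factory=list)
    segment_labels: list[str] = field(default_factory=list)
    F_diss: float | None = None
    F_unbind: float | None = None
    cycle_id: int = 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def downsample(trace: ForceExtensionTrace, factor: int) -> ForceExtensionTrace:
    """Block-mean downsampling by an integer ``factor``.

    78 kHz data downsampled by 300 yields the 260-Hz analysis rate.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace
    n = len(trace) // factor
    if n == 0:
        raise ValueError("factor exceeds trace length")
    def block(a: np.ndarray) -> np.ndarray:
        return a[: n * factor].reshape(n, factor).mean(axis=1)
    return ForceExtensionTrace(block(trace.time), block(trace.force),
                               block(trace.extension),
                               trace.sampling_rate / factor)


def correct_crosstalk(trace: ForceExtensionTrace, coefficient: float,
                      reference: np.ndarray | None = None
                      ) -> ForceExtensionTrace:
    """Remove linear trap cross-talk from the force channel.

    The contamination model is ``force_measured = force_true +
    coefficient * reference``; the reference channel defaults to the
    extension (the moving-trap signal).  A zero coefficient is the
    identity, and applying ``-coefficient`` inverts the correction.
    """
    if not abs(coefficient) < 1:
        raise ValueError("crosstalk coefficient must satisfy |c| < 1")
    if coefficient == 0:
        return trace
    ref = trace.extension if reference is None else np.asarray(reference, float)
    return replace(trace, force=trace.force - coefficient * ref)


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(a) < window:
        return a.astype(float, copy=True)
    kernel = np.ones(window) / window
    out = np.convolve(a, kernel, mode="same")
    # repair edge shrinkage of the centred window
    half = window // 2
    for i in range(half):
        out[i] = a[: i + half + 1].mean()
        out[-(i + 1)] = a[-(i + half + 1):].mean()
    return out


# ---------------------------------------------------------------------------
# Cycle segmentation
# ---------------------------------------------------------------------------

def segment_cycles(trace: ForceExtensionTrace, min_peak_force: float = 30.0,
                   smooth_window: int = 5) -> list[PullCycle]:
    """Split a trace into pull/relax cycles at extension turning points.

    Cycles whose peak force is below ``min_peak_force`` (incomplete
    hairpin unfolding cannot be guaranteed) are retained but flagged
    ``analyzable=False`` and excluded from event statistics downstream.
    """
    n = len(trace)
    if n < 3:
        return []
    xs = _moving_average(trace.extension, smooth_window)
    d = np.diff(xs)
    sign = np.sign(d)
    sign[sign == 0] = 1  # treat flats as continuing upward
    flips = np.nonzero(np.diff(sign))[0] + 1
    maxima = [i for i in flips if sign[i - 1] > 0 > sign[i]]
    minima = [i for i in flips if sign[i - 1] < 0 < sign[i]]

    if not maxima:
        if sign[0] > 0:  # monotone single ramp: one pull, no relax
            peak = float(trace.force.max())
            return [PullCycle(trace.slice(0, n), None, peak, 0,
                              peak >= min_peak_force)]
        return []

    cycles: list[PullCycle] = []
    start = 0
    for cid, top in enumerate(maxima):
        stop = next((m for m in minima if m > top), n - 1)
        pull = trace.slice(start, top + 1)
        relax = trace.slice(top, stop + 1) if stop > top else None
        peak = float(trace.force[start:stop + 1].max())
        cycles.append(PullCycle(pull, relax, peak, cid,
                                peak >= min_peak_force))
        start = stop
    return cycles


# ---------------------------------------------------------------------------
# Rupture detection
# ---------------------------------------------------------------------------

def detect_ruptures(cycle: PullCycle | ForceExtensionTrace,
                    min_drop: float = 1.0, min_jump: float = 0.0,
                    window: int = 5, smooth_window: int = 5
                    ) -> list[RuptureEvent]:
    """Detect force-drop rupture events on the pull trace.

    With ``min_jump = 0`` candidates are samples where the smoothed
    force falls by at least ``min_drop`` pN within ``window`` samples;
    candidates closer than ``window`` samples are merged into a single
    event (drops in the same neighbourhood cannot be told apart).

    With ``min_jump > 0`` the extension channel corroborates and
    sharpens detection: each single-sample extension jump of at least
    ``min_jump`` nm that coincides with a raw force drop of at least
    ``min_drop`` pN is one event, so transitions on adjacent samples
    remain separable.

    The event force is read from the unsmoothed force as the mean of
    the last few samples preceding the drop, which suppresses the
    upward noise bias of a raw local maximum.
    """
    pull = cycle.pull if isinstance(cycle, PullCycle) else cycle
    f = pull.force
    x = pull.extension
    n = len(f)
    if n < window + 2:
        return []
    fs = _moving_average(f, smooth_window)

    if min_jump > 0:
        jump_at = np.diff(x)
        cand = np.nonzero(jump_at >= min_jump)[0]
        events: list[RuptureEvent] = []
        prev = -1
        for j in cand:
            post = min(j + 1 + window, n)
            drop = float(f[j] - f[j + 1: post].min())
            if drop < min_drop:
                continue
            lo = max(j - 2, prev + 1, 0)
            events.append(RuptureEvent(
                index=int(j), force=float(f[lo: j + 1].mean()),
                force_drop=drop, extension_jump=float(jump_at[j])))
            prev = j
        return events

    # forward rolling minimum over (i, i+window]
    drop = np.full(n, 0.0)
    from scipy.ndimage import minimum_filter1d
    fwd_min = minimum_filter1d(fs, size=window, origin=-(window // 2))
    # fwd_min[i] approximates min fs[i..i+window-1]; shift to exclude i
    drop[: n - 1] = fs[: n - 1] - fwd_min[1:]
    cand = np.nonzero(drop >= min_drop)[0]
    if len(cand) == 0:
        return []

    events = []
    group = [cand[0]]
    for i in cand[1:]:
        if i - group[-1] <= window:
            group.append(i)
        else:
            events.append(_event_from_group(group, f, fs, x, window))
            group = [i]
    events.append(_event_from_group(group, f, fs, x, window))
    return events


def _event_from_group(group: list[int], f: np.ndarray, fs: np.ndarray,
                      x: np.ndarray, window: int) -> RuptureEvent:
    lo = max(group[0] - window, 0)
    hi = min(group[-1] + window + 1, len(f))
    peak = lo + int(np.argmax(f[lo:hi]))
    post = min(peak + 2 * window + 1, len(f))
    force_drop = float(fs[min(peak, len(fs) - 1)] - fs[peak:post].min())
    jump = float(x[post - 1] - x[peak]) if post > peak else 0.0
    lo_avg = max(peak - 2, 0)
    force = float(f[lo_avg: peak + 1].mean())
    return RuptureEvent(index=peak, force=force, force_drop=force_drop,
                        extension_jump=jump)


# ---------------------------------------------------------------------------
# State assignment and contour-length measurement
# ---------------------------------------------------------------------------

def assign_states(cycle: PullCycle, states: dict[str, ConstructState],
                  events: list[RuptureEvent] | None = None,
                  th: ThermalContext = ThermalContext(),
                  min_force: float = 2.0,
                  residual_threshold: float = 15.0,
                  guard: int = 1,
                  min_points: int = 1,
                  order: tuple[str, ...] = STATE_ORDER
                  ) -> list[SegmentAssignment]:
    """Assign a candidate state to every inter-event segment of a pull.

    Segment ``k`` spans the samples after event ``k-1`` up to and
    including the peak sample of event ``k`` (the peak is the last
    sample of the old state).  Each segment is given the state whose
    hybrid WLC curve minimises the RMS extension residual over samples
    above ``min_force``; ties break deterministically toward the state
    earlier in the disassembly order, and segments whose best residual
    exceeds ``residual_threshold`` nm (or with fewer than ``min_points``
    usable samples) are labelled ``unknown``.  ``guard`` skips samples
    right after each event (1 = start at the first post-rupture sample).
    """
    if events is None:
        events = []
    pull = cycle.pull
    ordered = [name for name in order if name in states]
    ordered += [name for name in states if name not in ordered]

    out: list[SegmentAssignment] = []
    for k in range(len(events) + 1):
        start = events[k - 1].index + guard if k > 0 else 0
        stop = events[k].index + 1 if k < len(events) else len(pull)
        stop = max(stop, start)
        f = pull.force[start:stop]
        x = pull.extension[start:stop]
        mask = f >= min_force
        if mask.sum() < min_points:
            out.append(SegmentAssignment(start, stop, "unknown", float("inf")))
            continue
        fm, xm = f[mask], x[mask]
        best_label, best_rms = "unknown", float("inf")
        for name in ordered:
            pred = hybrid_extension(fm, states[name], th)
            rms = float(np.sqrt(np.mean((xm - pred) ** 2)))
            if rms < best_rms:
                best_label, best_rms = name, rms
        if best_rms > residual_threshold:
            best_label = "unknown"
        out.append(SegmentAssignment(start, stop, best_label, best_rms))
    return out


def _fit_segment(pull: ForceExtensionTrace, seg: SegmentAssignment,
                 states: dict[str, ConstructState], th: ThermalContext,
                 min_force: float) -> SegmentFit | None:
    """Free-ssDNA-contour fit of one segment; nominal fallback when the
    segment is too short to constrain a fit."""
    template = states.get(seg.label)
    if template is None:
        return None
    f = pull.force[seg.start:seg.stop]
    x = pull.extension[seg.start:seg.stop]
    mask = f >= min_force
    f, x = f[mask], x[mask]
    if len(f) >= 5 and np.ptp(f) >= 2.0:
        fit = fit_segment_contour(np.column_stack([x, f]), template,
                                  free=("ss",), th=th)
        if fit.success:
            return fit
    # short-lived segment: fall back to the assigned state's nominal contour
    return SegmentFit(template, float("nan"), True, "nominal")


def fit_segments(pull: ForceExtensionTrace,
                 assignments: list[SegmentAssignment],
                 states: dict[str, ConstructState],
                 th: ThermalContext = ThermalContext(),
                 min_force: float = 2.0) -> None:
    """Populate ``assignment.fit`` with a free-ssDNA-contour fit per segment."""
    for seg in assignments:
        seg.fit = _fit_segment(pull, seg, states, th, min_force)


def measure_contour_change(event_idx: int,
                           pull: ForceExtensionTrace,
                           assignments: list[SegmentAssignment],
                           states: dict[str, ConstructState],
                           th: ThermalContext = ThermalContext(),
                           min_force: float = 2.0) -> float | None:
    """Contour-length change (nm) across event ``event_idx``.

    The flanking segments are re-fitted with a free ssDNA contour length
    (rigid offsets fixed to the assigned state); the change is the
    difference of fitted ssDNA contour plus offsets.  Returns ``None``
    when either flank cannot be fitted (event excluded downstream).
    """
    if event_idx + 1 >= len(assignments):
        return None
    for k in (event_idx, event_idx + 1):
        if assignments[k].fit is None:
            assignments[k].fit = _fit_segment(pull, assignments[k], states,
                                              th, min_force)
    coord_a = assignments[event_idx].contour_coordinate
    coord_b = assignments[event_idx + 1].contour_coordinate
    if coord_a is None or coord_b is None:
        return None
    return coord_b - coord_a


def match_fingerprint(delta_L: float, expected: float = 71.0,
                      tol: float = 10.0) -> bool:
    """Does a contour-length change match the designed 71-nm disassembly
    fingerprint within ``tol`` nm?"""
    return abs(delta_L - expected) <= tol


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def extract_unbind_force(events: list[RuptureEvent],
                         threshold: float = 6.0) -> float | None:
    """Unbinding force of a hairpin-bound (category i) cycle.

    Ruptures below ``threshold`` pN are counted as free hairpin
    unfolding (literature value 5.7 pN) and excluded; the first rupture
    at or above the threshold is the protein unbinding event.
    """
    for ev in events:
        if ev.force >= threshold:
            return ev.force
    return None


def classify_cycle(cycle: PullCycle, events: list[RuptureEvent],
                   assignments: list[SegmentAssignment],
                   fingerprint: float = 71.0, tol: float = 10.0,
                   unbind_threshold: float = 6.0) -> CycleClassification:
    """Classify one pull cycle into interaction categories i/ii/iii/none.

    * iii: starts in the synapse state and reaches the hairpin-bound
      state in exactly one fingerprint-matched step;
    * ii:  starts in the synapse state and reaches the hairpin-bound
      state through >= 1 intermediate segment with a fingerprint-matched
      cumulative contour change;
    * i:   starts in the hairpin-bound state (no synaptic complex) with a
      protein unbinding rupture above the 6-pN free-unfolding threshold;
    * none otherwise.

    The cumulative contour change of the synapse -> hairpin-bound
    transition is measured between the fitted contours of the initial
    synapse segment and the first hairpin-bound segment, so short-lived
    intermediate segments that cannot be fitted do not block the
    fingerprint check.
    """
    labels = [a.label for a in assignments]
    cls = CycleClassification("none", events, labels, cycle_id=cycle.cycle_id)
    if not labels:
        return cls

    if labels[0] == "synapse" and events:
        try:
            j = labels.index("hairpin_bound")
        except ValueError:
            return cls
        coord_a = assignments[0].contour_coordinate
        coord_b = assignments[j].contour_coordinate
        if coord_a is None or coord_b is None:
            return cls
        cumulative = coord_b - coord_a
        if match_fingerprint(cumulative, fingerprint, tol):
            cls.category = "iii" if j == 1 else "ii"
            cls.F_diss = events[0].force
        return cls

    if labels[0] == "hairpin_bound":
        f_unbind = extract_unbind_force(events, unbind_threshold)
        if f_unbind is not None:
            cls.category = "i"
            cls.F_unbind = f_unbind
        return cls

    return cls


def dissipated_work(cycle: PullCycle, up_to: RuptureEvent | int) -> float:
    """Work (pN nm) dissipated along the pull up to an event sample:
    trapezoidal integral of force over extension."""
    idx = up_to.index if isinstance(up_to, RuptureEvent) else int(up_to)
    if idx < 0 or idx >= len(cycle.pull):
        raise ValueError("event index outside the pull trace")
    return float(np.trapezoid(cycle.pull.force[: idx + 1],
                              cycle.pull.extension[: idx + 1]))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_cycle(cycle: PullCycle, states: dict[str, ConstructState],
                  th: ThermalContext = ThermalContext(),
                  min_drop: float = 1.0, min_jump: float = 0.0,
                  window: int = 5, smooth_window: int = 5,
                  min_force: float = 2.0, residual_threshold: float = 15.0,
                  fingerprint: float = 71.0, fingerprint_tol: float = 10.0,
                  unbind_threshold: float = 6.0) -> CycleClassification:
    """Full per-cycle analysis: detect, assign, fingerprint, classify."""
    events = detect_ruptures(cycle, min_drop=min_drop, min_jump=min_jump,
                             window=window, smooth_window=smooth_window)
    assignments = assign_states(cycle, states, events, th,
                                min_force=min_force,
                                residual_threshold=residual_threshold)
    fit_segments(cycle.pull, assignments, states, th, min_force=min_force)
    for k, ev in enumerate(events):
        ev.from_state = assignments[k].label
        ev.to_state = assignments[k + 1].label
        dl = measure_contour_change(k, cycle.pull, assignments, states, th,
                                    min_force=min_force)
        ev.delta_L = float("nan") if dl is None else float(dl)
    return classify_cycle(cycle, events, assignments,
                          fingerprint=fingerprint, tol=fingerprint_tol,
                          unbind_threshold=unbind_threshold)
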