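"""Scan normalization, reference scaling and positive calling.

The analysis chain per array is:

1. net spot signal = max(signal median - background median, 0);
2. within each replicate subarray, express every net as a percentage of
   the mean net of the positive-control probes in that subarray;
3. aggregate the three replicate percentages into a per-probe mean and
   standard deviation;
4. scale each probe's mean by its *reference value* — the strongest
   normalized signal the probe can produce with a full-match target
   (measured during validation, or floored at 300% / 200% of controls
   for the AOA / AOB chemistry when unmeasured or weaker);
5. call a probe positive when its mean reaches at least 5% of its
   reference value.

Several probes show nonspecific background up to 3% of their maximum,
which the 5% cutoff sits safely above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .records import ArrayScan, CladeForest, ProbeRecord, RecordError

__all__ = [
    "CallParams",
    "NormalizedArray",
    "ReferenceValueSet",
    "CallColumn",
    "CallMatrix",
    "normalize_scan",
    "derive_reference_values",
    "call_positives",
    "assemble_call_matrix",
    "multiprobe_consistency",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CallParams:
    """Positive-calling parameters.

    call_fraction : fraction of a probe's reference value its signal
        must reach to be called positive (boundary inclusive).
    reference_floor : per-group fallback reference value, in % of the
        positive-control signal.
    nonspecific_max : nonspecific background ceiling as a fraction of a
        probe's maximum signal; used by the simulator, not by calling.
    """

    call_fraction: float = 0.05
    reference_floor: dict[str, float] = field(
        default_factory=lambda: {"AOA": 300.0, "AOB": 200.0}
    )
    nonspecific_max: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.call_fraction < 1:
            raise ValueError("call_fraction must be in (0, 1)")
        if any(v <= 0 for v in self.reference_floor.values()):
            raise ValueError("reference floors must be > 0")


@dataclass
class NormalizedArray:
    """Per-probe normalized signal for one array: mean and sd (over the
    three replicate subarrays) of the percentage of the positive-control
    average."""

    sample_id: str
    array_group: str
    mean_pct: dict[str, float]
    sd_pct: dict[str, float]


@dataclass
class ReferenceValueSet:
    """Per-probe reference values (% of positive-control signal) with a
    provenance flag: 'measured' from a full-match target, or 'floored'."""

    values: dict[str, float]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        for probe, flag in self.provenance.items():
            if flag not in {"measured", "floored"}:
                raise RecordError(f"probe {probe}: bad provenance {flag!r}")
            if flag == "measured" and self.values[probe] <= 0:
                raise RecordError(f"probe {probe}: measured reference must be > 0")


@dataclass
class CallColumn:
    """One sample's reference-scaled signals and boolean calls."""

    sample_id: str
    scaled_pct: dict[str, float]
    call: dict[str, bool]


@dataclass
class CallMatrix:
    """Probes x samples matrices of reference-scaled percentages
    (100 = maximum achievable signal for that probe; values above 100
    are permitted) and boolean positive calls."""

    scaled_pct: pd.DataFrame
    calls: pd.DataFrame


def normalize_scan(
    scan: ArrayScan,
    probes: list[ProbeRecord],
    ignore: tuple[str, ...] = ("hyaBp",),
) -> NormalizedArray:
    """Normalize one array's raw scan to the positive-control average.

    Control averaging happens within each replicate subarray (cancelling
    subarray-scale intensity differences) before replicate aggregation;
    probes spotted in multiple copies within a subarray are averaged
    first.  Negative nets clamp to 0.  The external spike control rows
    (*ignore*) are dropped.
    """
    by_name = {p.name: p for p in probes}
    controls = [p.name for p in probes if p.is_positive_control]
    if not controls:
        raise RecordError(f"scan {scan.sample_id}: probe set has no positive controls")

    # net per (replicate, probe), averaging multi-copy spots
    nets: dict[int, dict[str, list[float]]] = {}
    for row in scan.rows:
        if row.probe in ignore:
            continue
        net = max(row.signal_median - row.background_median, 0.0)
        nets.setdefault(row.replicate, {}).setdefault(row.probe, []).append(net)

    pcts: dict[str, list[float]] = {}
    for replicate in sorted(nets):
        probe_net = {name: sum(v) / len(v) for name, v in nets[replicate].items()}
        present_controls = [c for c in controls if c in probe_net]
        if not present_controls:
            raise RecordError(
                f"scan {scan.sample_id}: subarray {replicate} has no control spots"
            )
        control_mean = sum(probe_net[c] for c in present_controls) / len(
            present_controls
        )
        if control_mean <= 0:
            raise RecordError(
                f"scan {scan.sample_id}: subarray {replicate} control mean is 0"
            )
        for name, net in probe_net.items():
            pcts.setdefault(name, []).append(100.0 * net / control_mean)

    mean_pct: dict[str, float] = {}
    sd_pct: dict[str, float] = {}
    for name, values in pcts.items():
        mean = sum(values) / len(values)
        mean_pct[name] = mean
        if len(values) > 1:
            sd_pct[name] = math.sqrt(
                sum((v - mean) ** 2 for v in values) / (len(values) - 1)
            )
        else:
            sd_pct[name] = 0.0
    del by_name
    return NormalizedArray(scan.sample_id, scan.array_group, mean_pct, sd_pct)


def derive_reference_values(
    validation_results: list[tuple[NormalizedArray, set[str]]],
    probes: list[ProbeRecord],
    params: CallParams | None = None,
) -> ReferenceValueSet:
    """Derive per-probe reference values from validation hybridizations.

    *validation_results* pairs each validation array with the set of
    probe names that are full matches for the target hybridized on it.
    A probe's reference is the strongest mean_pct it reached on arrays
    where it is a full match; probes never full-matched, or weaker than
    the group floor, fall back to the floor (flag 'floored').
    """
    params = params or CallParams()
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for probe in probes:
        if probe.is_positive_control:
            continue
        best: float | None = None
        for arr, full_match in validation_results:
            if probe.name in full_match and probe.name in arr.mean_pct:
                v = arr.mean_pct[probe.name]
                best = v if best is None else max(best, v)
        floor = params.reference_floor[probe.array_group]
        if best is None or best < floor:
            values[probe.name] = floor
            provenance[probe.name] = "floored"
        else:
            values[probe.name] = best
            provenance[probe.name] = "measured"
    return ReferenceValueSet(values=values, provenance=provenance)


def call_positives(
    sample: NormalizedArray,
    refs: ReferenceValueSet,
    params: CallParams | None = None,
    probes: list[ProbeRecord] | None = None,
) -> CallColumn:
    """Scale one array's normalized signals by the reference values and
    call positives at the 5%-of-reference cutoff (boundary inclusive).

    Scaled values are not capped; calls use unrounded values.  Control
    probes are excluded from calling.
    """
    params = params or CallParams()
    controls = {p.name for p in probes if p.is_positive_control} if probes else set()
    scaled: dict[str, float] = {}
    call: dict[str, bool] = {}
    for name, mean in sample.mean_pct.items():
        if name in controls:
            continue
        if name not in refs.values:
            raise RecordError(f"probe {name}: no reference value")
        ref = refs.values[name]
        scaled[name] = 100.0 * mean / ref
        call[name] = mean + _EPS >= params.call_fraction * ref
    return CallColumn(sample.sample_id, scaled, call)


def assemble_call_matrix(
    columns: list[CallColumn], probe_order: list[str]
) -> CallMatrix:
    """Stack per-sample call columns into probes x samples matrices,
    rows in probe-set order."""
    probes = [p for p in probe_order if any(p in c.scaled_pct for c in columns)]
    scaled = pd.DataFrame(
        {c.sample_id: [c.scaled_pct.get(p, 0.0) for p in probes] for c in columns},
        index=probes,
    )
    calls = pd.DataFrame(
        {c.sample_id: [bool(c.call.get(p, False)) for p in probes] for c in columns},
        index=probes,
    )
    return CallMatrix(scaled_pct=scaled, calls=calls)


def multiprobe_consistency(
    calls: CallColumn,
    probes: list[ProbeRecord],
    clades: CladeForest,
) -> dict[str, str]:
    """Check positive calls against the multiple-probe hierarchy.

    For every positive probe, looks for probes targeting a proper
    ancestor of (any of) its clades: SUPPORTED if at least one such
    broader probe is also positive, UNSUPPORTED if broader probes exist
    but are all negative (the likely-false-positive pattern), and
    NO_BROADER_PROBE when the hierarchy offers none.
    """
    by_name = {p.name: p for p in probes}
    for probe in probes:
        for clade in probe.clades:
            clades.require(clade)
    flags: dict[str, str] = {}
    for name, positive in calls.call.items():
        if not positive:
            continue
        probe = by_name[name]
        if probe.is_positive_control or not probe.clades:
            continue
        ancestors = {a for c in probe.clades for a in clades.ancestors(c)}
        broader = [
            q
            for q in probes
            if q.name != name
            and not q.is_positive_control
            and any(qc in ancestors for qc in q.clades)
        ]
        if not broader:
            flags[name] = "NO_BROADER_PROBE"
        elif any(calls.call.get(q.name, False) for q in broader):
            flags[name] = "SUPPORTED"
        else:
            flags[name] = "UNSUPPORTED"
    return flags
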