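"""Validation bookkeeping: predicted vs observed hybridization.

Validation hybridizes the array against a panel of pure reference
targets, one clone per array, and compares observed calls with the
wMM-based expectations: pairs at wMM <= 1.5 are expected positive,
pairs above 2.5 expected negative, the band in between is *potentially*
positive and never counted as an error in either direction (such probes
were re-curated by hand rather than scored automatically).

The same machinery compares environmental array profiles against clone
libraries sequenced from the same sample: a positive probe is
*supported* when at least one clone falls within its specificity, and
the summary reports how many positives lack library support (the delta
statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .model import HybClass, PairScore, ScoringParams, batch_match
from .pipeline import CallMatrix
from .records import CladeForest, ProbeRecord, RecordError, TargetRecord

__all__ = [
    "ValidationPanel",
    "ValidationReport",
    "EnvironmentalComparison",
    "round_half_away",
    "predict_panel",
    "score_panel",
    "flag_false_positive_probes",
    "compare_environmental",
]

EXPECT_TRUE = "positive"
EXPECT_FALSE = "negative"
EXPECT_EITHER = "either"

_EXPECTATION = {
    HybClass.POSITIVE: EXPECT_TRUE,
    HybClass.POTENTIAL: EXPECT_EITHER,
    HybClass.NEGATIVE: EXPECT_FALSE,
    HybClass.NO_MATCH: EXPECT_FALSE,
}


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (1/16 -> 6.3%, not banker's 6.2)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass
class ValidationPanel:
    """A reference-target validation data set: the probe set, the pure
    targets hybridized one per array, and the observed boolean calls
    (probes x targets)."""

    probes: list[ProbeRecord]
    targets: list[TargetRecord]
    observed: pd.DataFrame
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        # positive controls hybridize by design; they are not scored
        self.probes = [p for p in self.probes if not p.is_positive_control]
        probe_names = [p.name for p in self.probes]
        missing = set(probe_names) - set(self.observed.index)
        if missing:
            raise RecordError(f"observed calls missing probe(s) {sorted(missing)[:5]}")
        missing_t = {t.name for t in self.targets} - set(self.observed.columns)
        if missing_t:
            raise RecordError(f"observed calls missing target(s) {sorted(missing_t)[:5]}")


@dataclass
class ValidationReport:
    """Panel-level bookkeeping of predicted vs observed reactions."""

    n_reactions: int
    n_correct: int
    pct_correct: float
    probes_validated_with_perfect_match: int
    probes_flagged_false_positive: list[str]
    probes_behaving_as_predicted_pct: float


@dataclass
class EnvironmentalComparison:
    """One environment's array-vs-clone-library summary row."""

    environment: str
    n_samples: int
    array_group: str
    clades_array: set[str]
    clades_library: set[str]
    delta_clades: int
    positive_probes: int
    supported_probes: int
    delta_probes: int
    delta_pct: float
    library_size: int


def predict_panel(
    probes: list[ProbeRecord],
    targets: list[TargetRecord],
    params: ScoringParams | None = None,
    scores: list[PairScore] | None = None,
) -> pd.DataFrame:
    """Expected-call matrix (probes x targets) with entries 'positive',
    'negative' or 'either' derived from the wMM prediction classes."""
    params = params or ScoringParams()
    if scores is None:
        scores = batch_match(probes, targets, params)
    frame = pd.DataFrame(
        index=[p.name for p in probes],
        columns=[t.name for t in targets],
        dtype=object,
    )
    for s in scores:
        frame.at[s.probe_name, s.target_name] = _EXPECTATION[s.predicted_class]
    return frame


def score_panel(
    panel: ValidationPanel, scores: list[PairScore] | None = None
) -> ValidationReport:
    """Count correct reactions and derive probe-level verdicts.

    A reaction is correct when the observed call matches the expected
    one; 'either' expectations are always correct.  A probe *behaves as
    predicted* when all its reactions are correct, and is *validated
    with a perfect match* when it hybridized (observed positive) to at
    least one full-match (wMM = 0) target.  The behaving-as-predicted
    percentage is reported over the validated probes, matching how
    probe-design success is quoted for such arrays.
    """
    if scores is None:
        scores = batch_match(panel.probes, panel.targets, panel.params)
    n_reactions = 0
    n_correct = 0
    probe_ok: dict[str, bool] = {p.name: True for p in panel.probes}
    validated: set[str] = set()
    flagged: set[str] = set()
    for s in scores:
        observed = bool(panel.observed.at[s.probe_name, s.target_name])
        expectation = _EXPECTATION[s.predicted_class]
        n_reactions += 1
        correct = (
            expectation == EXPECT_EITHER
            or (expectation == EXPECT_TRUE) == observed
        )
        if correct:
            n_correct += 1
        else:
            probe_ok[s.probe_name] = False
            if observed and expectation == EXPECT_FALSE:
                flagged.add(s.probe_name)
        if s.site is not None and not s.site.mismatches and observed:
            validated.add(s.probe_name)
    behaving = sum(1 for name in validated if probe_ok[name])
    return ValidationReport(
        n_reactions=n_reactions,
        n_correct=n_correct,
        pct_correct=round_half_away(100.0 * n_correct / n_reactions, 1)
        if n_reactions
        else 0.0,
        probes_validated_with_perfect_match=len(validated),
        probes_flagged_false_positive=sorted(flagged),
        probes_behaving_as_predicted_pct=(
            100.0 * behaving / len(validated) if validated else float("nan")
        ),
    )


def flag_false_positive_probes(
    panel: ValidationPanel, scores: list[PairScore] | None = None
) -> list[str]:
    """Probes observed positive on a target expected negative, sorted by
    name.  Removal from the probe set is a reported action for the
    maintainer, never a silent mutation."""
    return score_panel(panel, scores=scores).probes_flagged_false_positive


def combine_reports(reports: list[ValidationReport]) -> ValidationReport:
    """Pool per-group validation reports (e.g. AOA + AOB) into one."""
    n_reactions = sum(r.n_reactions for r in reports)
    n_correct = sum(r.n_correct for r in reports)
    validated = sum(r.probes_validated_with_perfect_match for r in reports)
    flagged = sorted(set().union(*(r.probes_flagged_false_positive for r in reports)))
    behaving = sum(
        r.probes_behaving_as_predicted_pct
        / 100.0
        * r.probes_validated_with_perfect_match
        for r in reports
        if r.probes_validated_with_perfect_match
    )
    return ValidationReport(
        n_reactions=n_reactions,
        n_correct=n_correct,
        pct_correct=round_half_away(100.0 * n_correct / n_reactions, 1)
        if n_reactions
        else 0.0,
        probes_validated_with_perfect_match=validated,
        probes_flagged_false_positive=flagged,
        probes_behaving_as_predicted_pct=(
            100.0 * behaving / validated if validated else float("nan")
        ),
    )


def compare_environmental(
    calls: CallMatrix,
    probes: list[ProbeRecord],
    clades: CladeForest,
    library: list[str],
    environment: str,
    n_samples: int,
) -> EnvironmentalComparison:
    """Compare array calls for one environment against its clone library.

    A probe is *positive* when called in at least one of the
    environment's samples, and *supported* when at least one library
    clone's clade lies within the probe's specificity (the probe's clade
    or a descendant of it).  Clade sets on both sides are aggregated to
    the forest's high-level clades; delta counts array-detected
    high-level clades absent from the library.
    """
    if not library:
        raise RecordError("clone library is empty")
    if calls.calls.shape[1] < 1:
        raise RecordError("call matrix has no samples")
    for clade in library:
        clades.require(clade)
    by_name = {p.name: p for p in probes}
    positive = [
        name
        for name in calls.calls.index
        if calls.calls.loc[name].any()
        and name in by_name
        and not by_name[name].is_positive_control
    ]
    supported = []
    for name in positive:
        specificity = by_name[name].clades
        for c in specificity:
            clades.require(c)
        if any(clades.is_within(lc, pc) for lc in set(library) for pc in specificity):
            supported.append(name)
    clades_array = {
        clades.resolve_high(c) for name in positive for c in by_name[name].clades
    }
    clades_library = {clades.resolve_high(c) for c in set(library)}
    n_pos = len(positive)
    n_sup = len(supported)
    delta = n_pos - n_sup
    return EnvironmentalComparison(
        environment=environment,
        n_samples=n_samples,
        array_group=calls_group(probes, positive),
        clades_array=clades_array,
        clades_library=clades_library,
        delta_clades=len(clades_array - clades_library),
        positive_probes=n_pos,
        supported_probes=n_sup,
        delta_probes=delta,
        delta_pct=round_half_away(100.0 * delta / n_pos, 1) if n_pos else 0.0,
        library_size=len(library),
    )


def calls_group(probes: list[ProbeRecord], positive: list[str]) -> str:
    groups = {p.array_group for p in probes}
    return groups.pop() if len(groups) == 1 else "mixed"


def write_environmental_table(rows: list[EnvironmentalComparison], path) -> None:
    """Tabular export mirroring the environmental-summary layout."""
    with open(path, "w", newline="") as handle:
        handle.write(
            "environment\tn_samples\tgroup\tclades_array\tclades_library"
            "\tdelta_clades\tpositive_probes\tsupported_probes\tdelta_probes"
            "\tdelta_pct\tlibrary_size\n"
        )
        for r in rows:
            handle.write(
                f"{r.environment}\t{r.n_samples}\t{r.array_group}"
                f"\t{len(r.clades_array)}\t{len(r.clades_library)}"
                f"\t{r.delta_clades}\t{r.positive_probes}\t{r.supported_probes}"
                f"\t{r.delta_probes}\t{r.delta_pct:.1f}%\t{r.library_size}\n"
            )
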