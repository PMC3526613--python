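"""Synthetic probe/target panels and simulated array scans.

The generator builds random probes and, for each probe, engineered
targets whose best binding window carries a known mismatch load, so the
panel spans all four prediction classes with analytically known ground
truth.  The scan simulator turns wMM scores into raw spot intensities
through a simple response model

    relative_signal(wMM) = clamp(1 - wMM / 2.5, 0, 1)

anchored at the two ends the hybridization model fixes — full signal at
wMM 0, none above 2.5 — with the linear interpolation in between being
a modelling convenience isolated in one function.  Probes additionally
receive a uniform nonspecific background of up to 3% of their reference
value (strictly below the 5% call cutoff), and spot intensities are
jittered with multiplicative lognormal noise so they stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    RNA_COMPLEMENT,
    HybClass,
    MatchSite,
    PairScore,
    ScoringParams,
    best_match,
)
from .pipeline import CallParams, ReferenceValueSet
from .records import ArrayScan, ProbeRecord, ScanRow, TargetRecord

__all__ = ["SimulationParams", "relative_signal", "generate_panel", "simulate_scan"]

_DNA = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    seed : one global seed governing all draws.
    n_probes : number of non-control probes per panel.
    probe_length_range : inclusive probe length bounds, nt.
    control_net : raw net intensity of a positive-control spot.
    background_level : constant raw background median added to spots.
    noise_cv : coefficient of variation of the per-spot multiplicative
        lognormal jitter (0 disables noise).
    nonspecific_max : nonspecific background ceiling, as a fraction of a
        probe's reference value; must stay below the call fraction.
    """

    seed: int = 0
    n_probes: int = 8
    probe_length_range: tuple[int, int] = (18, 28)
    control_net: float = 10000.0
    background_level: float = 100.0
    noise_cv: float = 0.1
    nonspecific_max: float = 0.03
    n_replicates: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.probe_length_range
        if not 6 <= lo <= hi:
            raise ValueError("infeasible probe length range")
        if not 0 <= self.nonspecific_max < CallParams().call_fraction:
            raise ValueError("nonspecific_max must sit below the call fraction")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def relative_signal(wmm: float, negative_threshold: float = 2.5) -> float:
    """Relative hybridization signal (0-1) of a site with score *wmm*."""
    if np.isnan(wmm):
        return 0.0
    return float(np.clip(1.0 - wmm / negative_threshold, 0.0, 1.0))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_DNA), size=length))


# engineered variants: (suffix, number of internal default-weight
# mismatches, or None for an unrelated no-match target)
_VARIANTS: list[tuple[str, int | None]] = [
    ("full", 0),
    ("mm1", 1),
    ("mm2", 2),
    ("mm3", 3),
    ("nomatch", None),
]


def generate_panel(
    params: SimulationParams,
    group: str = "AOA",
    scoring: ScoringParams | None = None,
) -> tuple[list[ProbeRecord], list[TargetRecord], list[PairScore]]:
    """Generate a probe set, engineered targets, and ground truth.

    Each probe gets five targets: an exact full-match embedding (wMM 0,
    POSITIVE), embeddings with 1/2/3 internal default-weight mismatches
    (wMM 1.2 POSITIVE, 2.4 POTENTIAL, 3.6 NEGATIVE) and one unrelated
    sequence with no window inside the mismatch budget (NO_MATCH).
    Ground-truth scores come from the analytic construction and every
    engineered site is verified (and its flanks redrawn on collision)
    against the window scan, so the truth is constructive, not assumed.
    Two positive-control probes are appended to the probe set.
    """
    scoring = scoring or ScoringParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.probe_length_range
    probes: list[ProbeRecord] = []
    targets: list[TargetRecord] = []
    truth: list[PairScore] = []
    internal_w = scoring.internal_weight * scoring.default_mismatch_weight
    for i in range(params.n_probes):
        length = int(rng.integers(lo, hi + 1))
        probe = ProbeRecord(
            name=f"P{i:03d}",
            sequence=_random_seq(rng, length),
            clades=(f"clade{i:03d}",),
            array_group=group,
        )
        probes.append(probe)
        for suffix, n_mm in _VARIANTS:
            tname = f"T{i:03d}_{suffix}"
            if n_mm is None:
                for _ in range(100):
                    seq = _random_seq(rng, max(60, length + 20))
                    candidate = TargetRecord(tname, seq, array_group=group)
                    if (
                        best_match(probe, candidate, scoring).predicted_class
                        is HybClass.NO_MATCH
                    ):
                        break
                else:  # pragma: no cover - vanishingly unlikely
                    raise RuntimeError("could not draw a no-match target")
                targets.append(candidate)
                truth.append(
                    PairScore(probe.name, tname, float("nan"), None, HybClass.NO_MATCH)
                )
                continue
            # internal positions (weight 1.2); complement substitution
            # always forms a default-weight (1.0) mismatch pair
            positions = sorted(
                rng.choice(np.arange(4, length - 2), size=n_mm, replace=False)
            )
            site_seq = list(probe.sequence)
            mismatches = []
            for pos in positions:
                sense = _COMPLEMENT[probe.sequence[pos - 1]]
                site_seq[pos - 1] = sense
                mismatches.append((int(pos), probe.sequence[pos - 1], RNA_COMPLEMENT[sense]))
            wmm = n_mm * internal_w
            for _ in range(100):
                flank5 = _random_seq(rng, 20)
                flank3 = _random_seq(rng, 20)
                seq = flank5 + "".join(site_seq) + flank3
                candidate = TargetRecord(
                    tname,
                    seq,
                    clade=probe.clades[0] if suffix == "full" else None,
                    array_group=group,
                )
                got = best_match(probe, candidate, scoring)
                if (
                    got.site is not None
                    and got.site.offset == 21
                    and abs(got.wmm - wmm) < 1e-9
                ):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not isolate the engineered site")
            targets.append(candidate)
            truth.append(
                PairScore(
                    probe.name,
                    tname,
                    wmm,
                    MatchSite(tname, 21, tuple(mismatches)),
                    scoring.classify(wmm),
                )
            )
    for j, tail in enumerate(("F", "R")):
        probes.append(
            ProbeRecord(
                name=f"CTRL-{tail}",
                sequence=_random_seq(rng, 20),
                is_positive_control=True,
                array_group=group,
            )
        )
    return probes, targets, truth


def simulate_scan(
    probes: list[ProbeRecord],
    scores: list[PairScore],
    refs: ReferenceValueSet,
    params: SimulationParams,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> ArrayScan:
    """Simulate one array hybridized with a pool of targets.

    *scores* are the wMM scores of the probes against the pooled
    targets; each probe responds to its best (lowest-wMM) site.  Raw
    nets are scaled so a 100%-of-reference response of a probe with
    reference 100 equals ``control_net``; positive-control spots sit at
    ``control_net`` exactly (before noise).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    group = {p.array_group for p in probes}.pop()
    best_rel: dict[str, float] = {}
    for s in scores:
        if s.site is None:
            continue
        rel = relative_signal(s.wmm)
        best_rel[s.probe_name] = max(best_rel.get(s.probe_name, 0.0), rel)
    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
    scan = ArrayScan(sample_id=sample_id, array_group=group)
    for probe in probes:
        if probe.is_positive_control:
            expected_pct = None
        else:
            ref = refs.values[probe.name]
            pct = ref * best_rel.get(probe.name, 0.0)
            pct += rng.uniform(0.0, params.nonspecific_max * ref)
            expected_pct = pct
        for replicate in range(1, params.n_replicates + 1):
            net = (
                params.control_net
                if expected_pct is None
                else expected_pct / 100.0 * params.control_net
            )
            if params.noise_cv > 0:
                net *= rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma)
            scan.rows.append(
                ScanRow(
                    probe=probe.name,
                    replicate=replicate,
                    signal_median=net + params.background_level,
                    background_median=params.background_level,
                )
            )
    return scan
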