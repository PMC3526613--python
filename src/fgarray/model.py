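"""Weighted-mismatch (wMM) hybridization scoring and probe thermodynamics.

The array's probes are immobilized DNA oligos written on the sense strand
of the marker gene; the labelled target is single-stranded *antisense*
RNA (run-off transcription from a T7-tagged reverse primer).  A probe
position therefore matches when the probe base equals the target's sense
base — the RNA base it actually pairs with is the RNA complement of that
sense base.  Mismatches are weighted by where they sit on the probe
(terminal mismatches destabilize less) and by which DNA/RNA base
opposition they form (G·U and T·G wobbles destabilize least):

    wMM = sum over mismatches of position_weight x basepair_weight

Probe-target pairs with wMM <= 1.5 are expected to hybridize above the
call cutoff, pairs with wMM > 2.5 to stay below it, and the band in
between is only potentially positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .records import ProbeRecord, TargetRecord

__all__ = [
    "ScoringParams",
    "TmParams",
    "HybClass",
    "MatchSite",
    "PairScore",
    "pair_bases",
    "compute_wmm",
    "best_match",
    "batch_match",
    "compute_tm",
    "gc_content",
]

# RNA complement of a sense-strand base: the base the probe pairs with.
RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "T": "A"}

# Watson-Crick probe(DNA):target(RNA) pairs.
_WC_PAIRS = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}

# comparisons against the class thresholds tolerate float summation error;
# the smallest real wMM increment is 0.3 * 0.4 = 0.12, vastly larger.
_EPS = 1e-9


class HybClass(str, enum.Enum):
    """Predicted hybridization outcome of a probe-target pair."""

    POSITIVE = "POSITIVE"
    POTENTIAL = "POTENTIAL"
    NEGATIVE = "NEGATIVE"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class ScoringParams:
    """Mismatch weighting scheme and prediction thresholds.

    ``position_weights_5p``/``position_weights_3p`` weight the first
    three positions counted from either probe end; every other position
    weighs ``internal_weight``.  ``basepair_weights`` is keyed by
    (probe DNA base, target RNA base); any mismatch pair not listed
    weighs ``default_mismatch_weight``.  Windows with more than
    ``max_mismatches`` mismatches are not considered match sites at all.
    """

    position_weights_5p: tuple[float, float, float] = (0.3, 0.6, 1.0)
    position_weights_3p: tuple[float, float, float] = (0.3, 0.8, 1.1)
    internal_weight: float = 1.2
    basepair_weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("A", "C"): 1.2,  # dA·rC
            ("T", "C"): 1.2,  # dT·rC
            ("G", "U"): 0.7,  # dG·rU wobble
            ("T", "G"): 0.4,  # dT·rG wobble
        }
    )
    default_mismatch_weight: float = 1.0
    positive_threshold: float = 1.5
    negative_threshold: float = 2.5
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        weights = (
            *self.position_weights_5p,
            *self.position_weights_3p,
            self.internal_weight,
            self.default_mismatch_weight,
            *self.basepair_weights.values(),
        )
        if any(w <= 0 for w in weights):
            raise ValueError("all weights must be > 0")
        if not self.positive_threshold < self.negative_threshold:
            raise ValueError("positive_threshold must be < negative_threshold")

    def position_weight(self, position: int, length: int) -> float:
        """Weight of 1-based probe *position* on a probe of *length* nt."""
        if not 1 <= position <= length:
            raise ValueError(f"position {position} outside [1, {length}]")
        if length < 6:
            raise ValueError("position weighting requires probe length >= 6")
        if position <= 3:
            return self.position_weights_5p[position - 1]
        from_3p = length - position  # 0 for the 3' terminal base
        if from_3p <= 2:
            return self.position_weights_3p[from_3p]
        return self.internal_weight

    def basepair_weight(self, probe_base: str, target_rna_base: str) -> float:
        return self.basepair_weights.get(
            (probe_base, target_rna_base), self.default_mismatch_weight
        )

    def classify(self, wmm: float) -> HybClass:
        if wmm <= self.positive_threshold + _EPS:
            return HybClass.POSITIVE
        if wmm <= self.negative_threshold + _EPS:
            return HybClass.POTENTIAL
        return HybClass.NEGATIVE


@dataclass(frozen=True)
class TmParams:
    """Nearest-neighbour melting-temperature settings.

    Duplex Tm is approximated with the unified DNA/DNA nearest-neighbour
    table at a total oligo concentration ``oligo_nM`` (the CT/4 term for
    non-self-complementary duplexes) with a monovalent-salt correction
    to ``sodium_mM``.
    """

    oligo_nM: float = 250.0
    sodium_mM: float = 50.0
    nn_table: str = "DNA_NN3"  # unified Allawi & SantaLucia parameters
    salt_correction: int = 5  # entropy correction, 0.368 N ln[Na+]

    def __post_init__(self) -> None:
        if self.oligo_nM <= 0 or self.sodium_mM <= 0:
            raise ValueError("concentrations must be > 0")


@dataclass(frozen=True)
class MatchSite:
    """Best ungapped binding site of a probe on a target.

    ``offset`` is the 1-based start of the probe-length window on the
    target sense strand; ``mismatches`` lists
    (probe position 1-based from the probe 5' end, probe base,
    target RNA base).
    """

    target_name: str
    offset: int
    mismatches: tuple[tuple[int, str, str], ...] = ()


@dataclass(frozen=True)
class PairScore:
    """Outcome of scoring one probe against one target."""

    probe_name: str
    target_name: str
    wmm: float
    site: MatchSite | None
    predicted_class: HybClass


def pair_bases(probe_base: str, target_sense_base: str) -> tuple[bool, str]:
    """Resolve the DNA/RNA base opposition at one aligned position.

    Returns ``(is_match, target_rna_base)`` where the RNA base is the
    complement of the target's sense base (the target is antisense RNA).
    """
    if probe_base not in RNA_COMPLEMENT or target_sense_base not in RNA_COMPLEMENT:
        raise ValueError(
            f"ambiguous base in pair ({probe_base!r}, {target_sense_base!r})"
        )
    rna = RNA_COMPLEMENT[target_sense_base]
    return (probe_base, rna) in _WC_PAIRS, rna


def compute_wmm(probe: ProbeRecord, site: MatchSite, params: ScoringParams | None = None) -> float:
    """Weighted-mismatch score of a probe at a given match site."""
    params = params or ScoringParams()
    length = len(probe.sequence)
    if length < 6:
        raise ValueError("wMM scoring requires probe length >= 6")
    total = 0.0
    for pos, probe_base, rna_base in site.mismatches:
        total += params.position_weight(pos, length) * params.basepair_weight(
            probe_base, rna_base
        )
    return total


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SENSE_BY_INDEX = "ACGTN"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode("latin-1"),
        dtype=np.uint8,
    )


def _contrib_table(probe: str, params: ScoringParams) -> np.ndarray:
    """(L, 5) table: weighted contribution of sense base s at probe
    position i; 0 where the sense base matches the probe base.

    An N in the target always counts as a default-weight mismatch."""
    length = len(probe)
    table = np.empty((length, 5))
    for i, pb in enumerate(probe):
        posw = params.position_weight(i + 1, length)
        for s_idx, sb in enumerate(_SENSE_BY_INDEX):
            if sb == pb:
                table[i, s_idx] = 0.0
            elif sb == "N":
                table[i, s_idx] = posw * params.default_mismatch_weight
            else:
                _, rna = pair_bases(pb, sb)
                table[i, s_idx] = posw * params.basepair_weight(pb, rna)
    return table


def best_match(
    probe: ProbeRecord, target: TargetRecord, params: ScoringParams | None = None
) -> PairScore:
    """Score every ungapped probe-length window on the target sense
    strand and return the lowest-wMM site within the mismatch budget.

    Ties are broken by the smallest offset.  If no window carries at
    most ``max_mismatches`` mismatches the pair is classed NO_MATCH.
    """
    params = params or ScoringParams()
    length = len(probe.sequence)
    if length > len(target.sequence):
        raise ValueError(
            f"probe {probe.name} ({length} nt) longer than target "
            f"{target.name} ({len(target.sequence)} nt)"
        )
    probe_idx = _encode(probe.sequence)
    target_idx = _encode(target.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(target_idx, length)
    # mismatch mask: sense base differs from probe base, or is N
    mism = (windows != probe_idx[None, :]) | (windows == 4)
    counts = mism.sum(axis=1)
    ok = counts <= params.max_mismatches
    if not ok.any():
        return PairScore(probe.name, target.name, float("nan"), None, HybClass.NO_MATCH)
    table = _contrib_table(probe.sequence, params)
    wmms = table[np.arange(length)[None, :], windows].sum(axis=1)
    wmms[~ok] = np.inf
    best = int(np.argmin(wmms))  # first minimum -> smallest offset
    mismatches = []
    for i in map(int, np.flatnonzero(mism[best])):
        pb = probe.sequence[i]
        sb = target.sequence[best + i]
        rna = "N" if sb == "N" else RNA_COMPLEMENT[sb]
        mismatches.append((i + 1, pb, rna))
    site = MatchSite(target.name, best + 1, tuple(mismatches))
    wmm = float(wmms[best])
    return PairScore(probe.name, target.name, wmm, site, params.classify(wmm))


def batch_match(
    probes: list[ProbeRecord],
    targets: list[TargetRecord],
    params: ScoringParams | None = None,
) -> list[PairScore]:
    """Score every probe against every target (probe-major order).

    All probes and targets must belong to the same array group; cross
    hybridization between the AOA and AOB chemistries is not modelled.
    """
    params = params or ScoringParams()
    groups = {p.array_group for p in probes} | {t.array_group for t in targets}
    if len(groups) > 1:
        raise ValueError(f"probes and targets span array groups {sorted(groups)}")
    return [best_match(p, t, params) for p in probes for t in targets]


def compute_tm(sequence: str, params: TmParams | None = None) -> float:
    """Nearest-neighbour duplex melting temperature in deg C."""
    params = params or TmParams()
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("Tm requires length >= 2")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous base in {sequence!r}")
    # dnac1 = dnac2 = CT/2 makes Biopython's ln-term argument CT/4
    half = params.oligo_nM / 2.0
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=getattr(_mt, params.nn_table),
            dnac1=half,
            dnac2=half,
            Na=params.sodium_mM,
            saltcorr=params.salt_correction,
        )
    )


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases, in [0, 1]."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)
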