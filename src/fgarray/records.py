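"""Domain records shared across the toolkit.

All sequences are stored as DNA on the sense strand of the marker gene,
5'->3'.  Strand/complement logic lives in :mod:`fgarray.model`, never in
the records or the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_BASES = frozenset("ACGT")
TARGET_BASES = frozenset("ACGTN")
ARRAY_GROUPS = ("AOA", "AOB")

#: length bounds for non-control oligonucleotide probes (nt)
PROBE_LENGTH_RANGE = (18, 28)


class RecordError(ValueError):
    """A record violating a domain invariant."""


def _check_group(group: str) -> str:
    if group not in ARRAY_GROUPS:
        raise RecordError(f"array_group must be one of {ARRAY_GROUPS}, got {group!r}")
    return group


@dataclass(frozen=True)
class ProbeRecord:
    """A short oligonucleotide probe spotted on the array.

    Parameters
    ----------
    name : unique identifier within a probe set.
    sequence : probe sequence as the sense strand of the target gene
        region, 5'->3', unambiguous bases only.
    clades : clade identifiers the probe is specific for (empty for
        controls).
    is_positive_control : positive-control probes (complementary to the
        PCR primer sites) define 100% signal during normalization and are
        exempt from the 18-28 nt length rule.
    array_group : "AOA" or "AOB"; the two organism groups have separate
        probe sets, controls and reference floors.
    reference_value : optional per-probe maximum normalized signal
        (% of positive-control signal) measured with a full-match target.
    """

    name: str
    sequence: str
    clades: tuple[str, ...] = ()
    is_positive_control: bool = False
    array_group: str = "AOA"
    reference_value: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise RecordError("probe name must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "clades", tuple(self.clades))
        bad = set(seq) - DNA_BASES
        if bad:
            raise RecordError(
                f"probe {self.name}: non-ACGT base(s) {sorted(bad)} in sequence"
            )
        lo, hi = PROBE_LENGTH_RANGE
        if not self.is_positive_control and not lo <= len(seq) <= hi:
            raise RecordError(
                f"probe {self.name}: length {len(seq)} outside [{lo}, {hi}] "
                "(rule applies to non-control probes)"
            )
        _check_group(self.array_group)
        if self.reference_value is not None and self.reference_value < 0:
            raise RecordError(f"probe {self.name}: negative reference_value")


@dataclass(frozen=True)
class TargetRecord:
    """A target sequence (sense strand) a probe may hybridize to."""

    name: str
    sequence: str
    clade: str | None = None
    array_group: str = "AOA"

    def __post_init__(self) -> None:
        if not self.name:
            raise RecordError("target name must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise RecordError(f"target {self.name}: empty sequence")
        bad = set(seq) - TARGET_BASES
        if bad:
            raise RecordError(
                f"target {self.name}: non-IUPAC base(s) {sorted(bad)} in sequence"
            )
        _check_group(self.array_group)


def check_unique_names(records) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.name in seen:
            raise RecordError(f"duplicate record name {rec.name!r}")
        seen.add(rec.name)


@dataclass(frozen=True)
class ScanRow:
    """One spot measurement: raw medians exactly as quantified."""

    probe: str
    replicate: int
    signal_median: float
    background_median: float

    def __post_init__(self) -> None:
        if self.signal_median < 0 or self.background_median < 0:
            raise RecordError(
                f"spot {self.probe} rep {self.replicate}: negative raw value"
            )


@dataclass
class ArrayScan:
    """Raw per-spot measurements for one hybridized array.

    Each array carries three replicate subarrays; ``replicate`` indexes
    the subarray (1-3).  Non-control probes appear once per subarray;
    control probes may be spotted in multiple copies per subarray.
    """

    sample_id: str
    array_group: str
    rows: list[ScanRow] = field(default_factory=list)

    N_REPLICATES = 3

    def validate(self, probes: list[ProbeRecord], ignore: tuple[str, ...] = ("hyaBp",)) -> None:
        """Check the scan against its companion probe set.

        Rows for probe names in *ignore* (external spike controls) are
        tolerated without a probe-set entry.
        """
        _check_group(self.array_group)
        by_name = {p.name: p for p in probes}
        per_probe: dict[str, list[int]] = {}
        for row in self.rows:
            if row.probe in ignore:
                continue
            if row.probe not in by_name:
                raise RecordError(
                    f"scan {self.sample_id}: unknown probe {row.probe!r}"
                )
            per_probe.setdefault(row.probe, []).append(row.replicate)
        want = set(range(1, self.N_REPLICATES + 1))
        for name, reps in per_probe.items():
            if set(reps) != want:
                raise RecordError(
                    f"scan {self.sample_id}: probe {name} has replicates "
                    f"{sorted(reps)}, expected {sorted(want)}"
                )
            if not by_name[name].is_positive_control and len(reps) != self.N_REPLICATES:
                raise RecordError(
                    f"scan {self.sample_id}: non-control probe {name} has "
                    f"{len(reps)} spots, expected exactly {self.N_REPLICATES}"
                )


class CladeForest:
    """The clade hierarchy probes and clones are assigned to.

    A forest of named clades (child -> parent mapping, roots have parent
    ``None``).  A subset of clades may be marked *high-level*; these are
    the named lineages community summaries aggregate to.  When no clade
    is marked, the roots serve as the high-level set.
    """

    def __init__(self, parent: dict[str, str | None], high_level: set[str] | None = None):
        self.parent = dict(parent)
        # parents must themselves be nodes
        for child, par in list(self.parent.items()):
            if par is not None and par not in self.parent:
                self.parent[par] = None
        self._check_acyclic()
        if high_level:
            unknown = set(high_level) - set(self.parent)
            if unknown:
                raise RecordError(f"unknown high-level clade(s): {sorted(unknown)}")
            self.high_level = set(high_level)
        else:
            self.high_level = {c for c, p in self.parent.items() if p is None}

    def _check_acyclic(self) -> None:
        for start in self.parent:
            seen = {start}
            node = self.parent[start]
            while node is not None:
                if node in seen:
                    raise RecordError(f"clade forest contains a cycle through {node!r}")
                seen.add(node)
                node = self.parent[node]

    def __contains__(self, clade: str) -> bool:
        return clade in self.parent

    def require(self, clade: str) -> None:
        if clade not in self.parent:
            raise RecordError(f"unknown clade {clade!r}")

    def ancestors(self, clade: str) -> list[str]:
        """Proper ancestors of *clade*, nearest first."""
        self.require(clade)
        out = []
        node = self.parent[clade]
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    def is_within(self, clade: str, ancestor: str) -> bool:
        """True if *clade* equals *ancestor* or descends from it."""
        self.require(ancestor)
        return clade == ancestor or ancestor in self.ancestors(clade)

    def resolve_high(self, clade: str) -> str:
        """Nearest high-level clade on the path from *clade* to its root
        (including *clade* itself); falls back to the root."""
        self.require(clade)
        node: str | None = clade
        root = clade
        while node is not None:
            if node in self.high_level:
                return node
            root = node
            node = self.parent[node]
        return root
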