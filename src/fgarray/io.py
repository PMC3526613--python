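"""Readers and writers for the toolkit's external artifacts.

All tabular formats are tab-delimited text with a header row; lines
starting with ``#`` are metadata comments and are skipped on input.
Readers validate and reject — they never silently repair a record.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .records import (
    ArrayScan,
    CladeForest,
    ProbeRecord,
    RecordError,
    ScanRow,
    TargetRecord,
    check_unique_names,
)

PROBE_COLUMNS = ["name", "sequence", "clades", "control", "group", "reference_value"]
SCAN_COLUMNS = ["probe", "replicate", "signal_median", "background_median"]


def _header_lines(params_note: str = "") -> list[str]:
    lines = [f"# fgarray v{__version__}"]
    if params_note:
        lines.append(f"# params: {params_note}")
    return lines


def _open_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a TSV, returning (header, [(line_no, fields), ...])."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append((line_no, fields))
    if header is None:
        raise RecordError(f"{path}: empty file")
    return header, rows


def read_fasta(path, default_group: str = "AOA") -> list[TargetRecord]:
    """Read target sequences from FASTA.

    Sequences are uppercased and RNA U is mapped to T.  The description
    line may carry ``clade=<id>`` and ``group=<AOA|AOB>`` tokens.
    Errors are reported with the record name and its header line number.
    """
    path = Path(path)
    # header line numbers, in record order, for error reporting
    line_nos = [
        no
        for no, line in enumerate(path.read_text().splitlines(), start=1)
        if line.startswith(">")
    ]
    records: list[TargetRecord] = []
    seen: set[str] = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise RecordError(f"{path}: no FASTA records")
    for idx, rec in enumerate(parsed):
        line_no = line_nos[idx] if idx < len(line_nos) else -1
        clade = None
        group = default_group
        for token in rec.description.split()[1:]:
            if token.startswith("clade="):
                clade = token[len("clade=") :]
            elif token.startswith("group="):
                group = token[len("group=") :]
        if rec.id in seen:
            raise RecordError(f"{path}:{line_no}: duplicate target name {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(
                TargetRecord(rec.id, str(rec.seq), clade=clade, array_group=group)
            )
        except RecordError as err:
            raise RecordError(f"{path}:{line_no}: {err}") from err
    return records


def write_fasta(targets: list[TargetRecord], path) -> None:
    with open(path, "w") as handle:
        for t in targets:
            desc = ""
            if t.clade:
                desc += f" clade={t.clade}"
            desc += f" group={t.array_group}"
            handle.write(f">{t.name}{desc}\n{t.sequence}\n")


def read_probe_table(path) -> list[ProbeRecord]:
    """Read a probe set from TSV (columns: name, sequence, clades,
    control, group[, reference_value]); clades are semicolon-separated."""
    header, rows = _open_rows(path)
    required = PROBE_COLUMNS[:5]
    missing = [c for c in required if c not in header]
    if missing:
        raise RecordError(f"{path}: missing column(s) {missing}")
    col = {name: header.index(name) for name in header}
    probes: list[ProbeRecord] = []
    for line_no, fields in rows:
        try:
            clades = tuple(c for c in fields[col["clades"]].split(";") if c)
            ref_raw = (
                fields[col["reference_value"]]
                if "reference_value" in col and col["reference_value"] < len(fields)
                else ""
            )
            probes.append(
                ProbeRecord(
                    name=fields[col["name"]],
                    sequence=fields[col["sequence"]],
                    clades=clades,
                    is_positive_control=_parse_bool(fields[col["control"]]),
                    array_group=fields[col["group"]],
                    reference_value=float(ref_raw) if ref_raw else None,
                )
            )
        except (RecordError, ValueError, IndexError) as err:
            raise RecordError(f"{path}:{line_no}: {err}") from err
    check_unique_names(probes)
    return probes


def _parse_bool(text: str) -> bool:
    if text in {"1", "true", "True", "yes"}:
        return True
    if text in {"0", "false", "False", "no", ""}:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def write_probe_table(probes: list[ProbeRecord], path, params_note: str = "") -> None:
    with open(path, "w", newline="") as handle:
        for line in _header_lines(params_note):
            handle.write(line + "\n")
        handle.write("\t".join(PROBE_COLUMNS) + "\n")
        for p in probes:
            ref = "" if p.reference_value is None else f"{p.reference_value:g}"
            handle.write(
                "\t".join(
                    [
                        p.name,
                        p.sequence,
                        ";".join(p.clades),
                        "1" if p.is_positive_control else "0",
                        p.array_group,
                        ref,
                    ]
                )
                + "\n"
            )


def read_scan_table(
    path, sample_id: str, group: str, probes: list[ProbeRecord] | None = None
) -> ArrayScan:
    """Read one array's scan table (probe, replicate, signal_median,
    background_median).  Raw medians are stored verbatim; if *probes* is
    given the scan is validated against that probe set."""
    header, rows = _open_rows(path)
    missing = [c for c in SCAN_COLUMNS if c not in header]
    if missing:
        raise RecordError(f"{path}: missing column(s) {missing}")
    col = {name: header.index(name) for name in header}
    scan = ArrayScan(sample_id=sample_id, array_group=group)
    for line_no, fields in rows:
        try:
            scan.rows.append(
                ScanRow(
                    probe=fields[col["probe"]],
                    replicate=int(fields[col["replicate"]]),
                    signal_median=float(fields[col["signal_median"]]),
                    background_median=float(fields[col["background_median"]]),
                )
            )
        except (RecordError, ValueError, IndexError) as err:
            raise RecordError(f"{path}:{line_no}: {err}") from err
    if probes is not None:
        scan.validate(probes)
    return scan


def write_scan_table(scan: ArrayScan, path, params_note: str = "") -> None:
    with open(path, "w", newline="") as handle:
        for line in _header_lines(params_note):
            handle.write(line + "\n")
        handle.write("\t".join(SCAN_COLUMNS) + "\n")
        for row in scan.rows:
            handle.write(
                f"{row.probe}\t{row.replicate}\t{row.signal_median:g}"
                f"\t{row.background_median:g}\n"
            )


def read_gpr_subset(
    path, sample_id: str, group: str, probes: list[ProbeRecord] | None = None
) -> ArrayScan:
    """Thin adapter for a GenePix-results-like dialect: columns "Name",
    "Block", "F532 Median", "B532 Median".  The block index is taken as
    the replicate subarray index."""
    with open(path, newline="") as handle:
        lines = [ln for ln in handle if ln.strip() and not ln.startswith(('"', "#"))]
    reader = csv.DictReader(_io.StringIO("".join(lines)), delimiter="\t")
    scan = ArrayScan(sample_id=sample_id, array_group=group)
    for rec in reader:
        try:
            scan.rows.append(
                ScanRow(
                    probe=rec["Name"],
                    replicate=int(rec["Block"]),
                    signal_median=float(rec["F532 Median"]),
                    background_median=float(rec["B532 Median"]),
                )
            )
        except (KeyError, ValueError, RecordError) as err:
            raise RecordError(f"{path}: bad GPR row {rec!r}: {err}") from err
    if probes is not None:
        scan.validate(probes)
    return scan


def read_clade_forest(path) -> CladeForest:
    """Read a clade forest from TSV (child, parent[, high_level]);
    an empty or '-' parent marks a root."""
    header, rows = _open_rows(path)
    if header[:2] != ["child", "parent"]:
        raise RecordError(f"{path}: expected columns child, parent[, high_level]")
    parent: dict[str, str | None] = {}
    high: set[str] = set()
    for line_no, fields in rows:
        child = fields[0]
        par = fields[1] if len(fields) > 1 and fields[1] not in {"", "-"} else None
        if child in parent:
            raise RecordError(f"{path}:{line_no}: duplicate clade {child!r}")
        parent[child] = par
        if len(fields) > 2 and _parse_bool(fields[2]):
            high.add(child)
    return CladeForest(parent, high or None)


def write_clade_forest(forest: CladeForest, path) -> None:
    with open(path, "w", newline="") as handle:
        handle.write("child\tparent\thigh_level\n")
        for child in sorted(forest.parent):
            par = forest.parent[child] or "-"
            handle.write(f"{child}\t{par}\t{int(child in forest.high_level)}\n")


def write_pair_scores(scores, path, params_note: str = "") -> None:
    """Write a score report: probe, target, offset, n_mismatches, wMM, class."""
    with open(path, "w", newline="") as handle:
        for line in _header_lines(params_note):
            handle.write(line + "\n")
        handle.write("probe\ttarget\toffset\tn_mismatches\twMM\tclass\n")
        for s in scores:
            if s.site is None:
                handle.write(f"{s.probe_name}\t{s.target_name}\t-\t-\t-\tNO_MATCH\n")
            else:
                handle.write(
                    f"{s.probe_name}\t{s.target_name}\t{s.site.offset}"
                    f"\t{len(s.site.mismatches)}\t{s.wmm:.2f}\t{s.predicted_class.value}\n"
                )


def write_call_matrix(matrix, path, params_note: str = "") -> None:
    """Write a call matrix: normalized-percentage table (one decimal,
    heatmap-ready) at *path* and the parallel boolean call table next to
    it with a ``.calls.tsv`` suffix.  Output is byte-deterministic."""
    if matrix.scaled_pct.empty:
        raise RecordError("call matrix is empty")
    path = Path(path)
    samples = list(matrix.scaled_pct.columns)

    def _write(frame, out, fmt) -> None:
        with open(out, "w", newline="") as handle:
            for line in _header_lines(params_note):
                handle.write(line + "\n")
            handle.write("probe\t" + "\t".join(samples) + "\n")
            for probe in frame.index:
                cells = [fmt(frame.at[probe, s]) for s in samples]
                handle.write(probe + "\t" + "\t".join(cells) + "\n")

    _write(matrix.scaled_pct, path, lambda v: f"{v:.1f}")
    calls_path = path.with_suffix("").as_posix() + ".calls.tsv"
    _write(matrix.calls, calls_path, lambda v: "1" if v else "0")


def write_reference_values(refs, path, params_note: str = "") -> None:
    with open(path, "w", newline="") as handle:
        for line in _header_lines(params_note):
            handle.write(line + "\n")
        handle.write("probe\treference_value\tprovenance\n")
        for probe in refs.values:
            handle.write(
                f"{probe}\t{refs.values[probe]:.1f}\t{refs.provenance[probe]}\n"
            )


def read_reference_values(path):
    from .pipeline import ReferenceValueSet

    header, rows = _open_rows(path)
    if header[:3] != ["probe", "reference_value", "provenance"]:
        raise RecordError(f"{path}: expected columns probe, reference_value, provenance")
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for line_no, fields in rows:
        if fields[0] in values:
            raise RecordError(f"{path}:{line_no}: duplicate probe {fields[0]!r}")
        values[fields[0]] = float(fields[1])
        provenance[fields[0]] = fields[2]
    return ReferenceValueSet(values=values, provenance=provenance)
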