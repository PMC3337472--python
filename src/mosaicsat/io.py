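"""TSV dialects, packaged fixture data, and report writing.

All tables are UTF-8, tab-separated, with a required header row; lines
starting with ``#`` are comments. Parsing is strict: unknown columns are
warned about, malformed rows raise :class:`ValidationError` with the
``file:line`` location. Writers emit byte-stable output for fixed inputs.

Dialects
--------
Allele spectrum (wide)   ``locus_id  n_alleles``
Allele spectrum (long)   ``mutation_id  locus_id`` (auto-aggregated)
Complementation matrix   ``mutation_a  mutation_b  result [channel]``
Deficiency tests         ``mutation  deficiency_id  result``
"""

from __future__ import annotations

import csv
import json
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .complementation import ComplementationMatrix
from .errors import ValidationError
from .saturation import AlleleSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_matrix",
    "write_matrix",
    "read_deficiencies",
    "load_screen_spectrum",
    "write_report",
    "report_to_markdown",
]


def _rows(path: str | Path):
    """Yield (line_number, fields) for non-comment, non-blank lines."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if fields[0].lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in fields]


def _header(path: str | Path, rows, expected: dict[tuple[str, ...], str]) -> tuple[str, list[str]]:
    try:
        lineno, fields = next(rows)
    except StopIteration:
        raise ValidationError(f"{path}: empty file (header row required)") from None
    for cols, dialect in expected.items():
        if fields[: len(cols)] == list(cols):
            extra = fields[len(cols):]
            if extra:
                warnings.warn(f"{path}:{lineno}: ignoring unknown columns {extra}", stacklevel=3)
            return dialect, fields
    raise ValidationError(
        f"{path}:{lineno}: unrecognized header {fields!r}; expected one of "
        f"{[list(c) for c in expected]}"
    )


def read_spectrum(path: str | Path) -> AlleleSpectrum:
    """Read an allele spectrum TSV (wide or long dialect)."""
    rows = _rows(path)
    dialect, _ = _header(
        path, rows, {("locus_id", "n_alleles"): "wide", ("mutation_id", "locus_id"): "long"}
    )
    if dialect == "wide":
        counts: dict[str, int] = {}
        for lineno, fields in rows:
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            locus, raw = fields[0], fields[1]
            try:
                n = int(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: n_alleles must be an integer, got {raw!r}"
                ) from None
            if n < 1:
                raise ValidationError(f"{path}:{lineno}: n_alleles must be >= 1, got {n}")
            if locus in counts:
                raise ValidationError(f"{path}:{lineno}: duplicate locus_id {locus!r}")
            counts[locus] = n
        if not counts:
            raise ValidationError(f"{path}: no data rows")
        return AlleleSpectrum.from_counts(counts)
    pairs = []
    for lineno, fields in rows:
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValidationError(f"{path}: no data rows")
    try:
        return AlleleSpectrum.from_assignments(pairs)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_spectrum(spectrum: AlleleSpectrum, path: str | Path) -> Path:
    """Write the wide-dialect spectrum TSV (byte-stable for fixed input)."""
    path = Path(path)
    lines = ["locus_id\tn_alleles"]
    lines += [f"{locus}\t{n}" for locus, n in zip(spectrum.locus_ids, spectrum.alleles_per_locus)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_matrix(
    path: str | Path, deficiencies_path: str | Path | None = None
) -> ComplementationMatrix:
    """Read a long-format pairwise complementation TSV.

    Both orientations of a pair may appear but must agree; a contradiction
    is reported with the offending pair. An optional deficiency-test table
    (``mutation  deficiency_id  result``) is merged in.
    """
    rows = _rows(path)
    _, _ = _header(
        path,
        rows,
        {
            ("mutation_a", "mutation_b", "result", "channel"): "long",
            ("mutation_a", "mutation_b", "result"): "long",
        },
    )
    records = []
    for lineno, fields in rows:
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
        channel = fields[3] if len(fields) > 3 and fields[3] else None
        records.append((fields[0], fields[1], fields[2], channel, lineno))
    deficiency_records = []
    if deficiencies_path is not None:
        deficiency_records = list(read_deficiencies(deficiencies_path))
    try:
        return ComplementationMatrix.from_records(
            [(a, b, res, ch) for a, b, res, ch, _ in records],
            deficiency_records=deficiency_records,
        )
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def read_deficiencies(path: str | Path) -> list[tuple[str, str, str]]:
    rows = _rows(path)
    _header(path, rows, {("mutation", "deficiency_id", "result"): "long"})
    records = []
    for lineno, fields in rows:
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        records.append((fields[0], fields[1], fields[2]))
    return records


def write_matrix(matrix: ComplementationMatrix, path: str | Path) -> Path:
    path = Path(path)
    lines = ["mutation_a\tmutation_b\tresult\tchannel"]
    for (a, b), res in sorted(matrix.results.items()):
        channel = matrix.channels.get((a, b), "")
        lines.append(f"{a}\t{b}\t{res}\t{channel}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_screen_spectrum() -> AlleleSpectrum:
    """The packaged allele spectrum of the Drosophila miRNA-pathway screen.

    45 retained mutations over 24 complementation groups: the nine
    molecularly identified genes with their allele counts, plus 15
    unidentified single-allele groups (the identified alleles sum to 30, so
    the remaining 15 mutations over 15 groups are necessarily singletons).
    """
    ref = resources.files("mosaicsat.data") / "mirna_screen_spectrum.tsv"
    with resources.as_file(ref) as path:
        return read_spectrum(path)


def report_to_markdown(report: dict, title: str = "Report") -> str:
    """A flat key/value markdown table rendering of a JSON report."""

    def _flatten(prefix: str, obj) -> list[tuple[str, str]]:
        if isinstance(obj, dict):
            out = []
            for key, value in obj.items():
                out.extend(_flatten(f"{prefix}.{key}" if prefix else str(key), value))
            return out
        if isinstance(obj, (list, tuple)):
            return [(prefix, json.dumps(obj))]
        return [(prefix, json.dumps(obj))]

    lines = [f"# {title}", "", "| key | value |", "| --- | --- |"]
    lines += [f"| {k} | {v} |" for k, v in _flatten("", report)]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path, name: str) -> tuple[Path, Path]:
    """Write ``<name>.json`` and ``<name>.md`` into ``out_dir``.

    JSON is sorted-key / indent-2 so output is byte-stable and diffable;
    warnings raised during computation belong inside ``report`` (they are
    scientific output, not log noise).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{name}.json"
    md_path = out_dir / f"{name}.md"
    json_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    md_path.write_text(report_to_markdown(report, title=name), encoding="utf-8")
    return json_path, md_path
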