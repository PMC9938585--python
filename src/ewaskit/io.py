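"""Readers and writers for the pipeline's table formats.

Matrices travel as TSV with a header row of sample ids and feature ids in
the first column; sample sheets as CSV; annotation and result tables as
TSV; blocklists as one id per line.  Every writer prepends ``#`` comment
lines recording the tool version and the parameters (seed included) that
produced the file, and every reader skips them.  Readers validate what
the type demands -- range for beta/detection-p, integrality for counts
and bead counts -- and name the offending cell in error messages.
Missing values are encoded as ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "read_matrix", "write_matrix", "read_sample_sheet", "write_sample_sheet",
    "read_table", "write_table", "read_blocklist", "write_blocklist",
    "write_probe_bed", "write_report",
]

MATRIX_KINDS = ("beta", "counts", "detection_p", "beads")


class ParseError(ValueError):
    """A table violated its format contract."""


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# ewaskit {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key} = {value}")
    return lines


def write_matrix(df: pd.DataFrame, path, kind: str, meta: dict | None = None) -> None:
    """Write a feature x sample matrix as TSV with a comment header."""
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    body = df.to_csv(sep="\t", index_label="feature_id", na_rep="NA",
                     float_format="%.10g", lineterminator="\n")
    path.write_text("\n".join(_header_lines(meta)) + "\n" + body)


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read and validate a feature x sample TSV matrix.

    beta / detection_p values must lie in [0, 1]; counts and bead counts
    must be non-negative integers.  Ragged rows, duplicated ids and
    out-of-range cells raise :class:`ParseError` naming the first
    offending cell.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: ragged or malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path.name}: duplicated feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path.name}: duplicated sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.where(~df.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy())
        r, c = bad[0][0], bad[1][0]
        raise ParseError(f"{path.name}: non-numeric value at ({df.index[r]}, {df.columns[c]})")
    finite = np.isfinite(values.astype(float))
    if kind in ("beta", "detection_p"):
        bad = finite & ((values < 0) | (values > 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(
                f"{path.name}: {kind} value {values[r, c]} outside [0, 1] "
                f"at ({df.index[r]}, {df.columns[c]})"
            )
    else:
        bad = finite & ((values < 0) | (values != np.floor(values)))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(
                f"{path.name}: {kind} value {values[r, c]} is not a non-negative "
                f"integer at ({df.index[r]}, {df.columns[c]})"
            )
    return df


def write_sample_sheet(sheet: pd.DataFrame, path, meta: dict | None = None) -> None:
    body = sheet.to_csv(index=False, na_rep="NA", lineterminator="\n")
    Path(path).write_text("\n".join(_header_lines(meta)) + "\n" + body)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#", na_values=["NA"])
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ParseError(f"{Path(path).name}: sample sheet needs sample_id and group columns")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{Path(path).name}: duplicated sample id {dup!r}")
    return sheet


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Generic TSV writer for annotation and result tables."""
    body = df.to_csv(sep="\t", index=False, na_rep="NA",
                     float_format="%.10g", lineterminator="\n")
    Path(path).write_text("\n".join(_header_lines(meta)) + "\n" + body)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_blocklist(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_blocklist(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")}


def write_probe_bed(probes: pd.DataFrame, path) -> None:
    """Probe positions as BED (0-based, half-open)."""
    bed = pd.DataFrame({
        "chrom": probes["chrom"],
        "start": probes["pos"].astype(int) - 1,
        "end": probes["pos"].astype(int),
        "name": probes["probe_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def write_report(entries: dict, path, meta: dict | None = None) -> None:
    """Key-value run/QC report."""
    lines = _header_lines(meta)
    lines += [f"{key}\t{value}" for key, value in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
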