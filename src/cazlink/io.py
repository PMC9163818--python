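"""Schema-validated TSV readers/writers and cross-file input validation.

All tabular I/O is UTF-8 TSV with a header row; lines starting with ``#``
are comments.  Readers raise :class:`SchemaError` naming the offending
file and column/row, so a malformed input aborts a run with a usable
message instead of propagating a pandas error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .ontology import TargetMapping, load_mapping

__all__ = [
    "SchemaError",
    "read_bin_table",
    "read_abundance_matrix",
    "read_annotations",
    "read_metadata",
    "read_mapping",
    "write_tsv",
    "ValidationReport",
    "validate_inputs",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """An input table does not match its expected schema."""


def _read(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise SchemaError(f"{path}: cannot be parsed as TSV ({exc})") from exc


def _require(df: pd.DataFrame, path: PathLike, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, path: PathLike, column: str) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based, after header
        raise SchemaError(f"{path}: non-numeric value in column {column!r}, "
                          f"row {row}")
    return values


def read_bin_table(path: PathLike) -> pd.DataFrame:
    """`bin_id  taxonomy  completeness  contamination` table."""
    df = _read(path)
    _require(df, path, ("bin_id", "taxonomy", "completeness", "contamination"))
    if df["bin_id"].duplicated().any():
        dup = df.loc[df["bin_id"].duplicated(), "bin_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate bin_id {dup!r}")
    df["completeness"] = _numeric(df, path, "completeness")
    df["contamination"] = _numeric(df, path, "contamination")
    if ((df["completeness"] < 0) | (df["completeness"] > 100)).any():
        raise SchemaError(f"{path}: completeness outside [0, 100]")
    if (df["contamination"] < 0).any():
        raise SchemaError(f"{path}: negative contamination")
    return df


def read_abundance_matrix(path: PathLike) -> pd.DataFrame:
    """Bin-by-sample relative-abundance matrix (% of total DNA)."""
    df = _read(path)
    first = df.columns[0]
    if df[first].duplicated().any():
        dup = df.loc[df[first].duplicated(), first].iloc[0]
        raise SchemaError(f"{path}: duplicate bin id {dup!r}")
    if len(set(df.columns[1:])) != len(df.columns) - 1:
        raise SchemaError(f"{path}: duplicate sample columns")
    out = df.set_index(first)
    out.index.name = "bin_id"
    for col in out.columns:
        out[col] = _numeric(out.reset_index(), path, col).to_numpy()
    if (out.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative abundance")
    return out


def read_annotations(path: PathLike) -> pd.DataFrame:
    """`protein_id  bin_id  family  [cupp_group]` CAZyme domain table."""
    df = _read(path)
    _require(df, path, ("protein_id", "bin_id", "family"))
    if "cupp_group" not in df.columns:
        df["cupp_group"] = ""
    df["cupp_group"] = df["cupp_group"].fillna("")
    blank = df["family"].isna() | (df["family"].str.strip() == "")
    if blank.any():
        row = int(df.index[blank][0]) + 2
        raise SchemaError(f"{path}: blank family in row {row}")
    return df


def read_metadata(
    path: PathLike, phenotype_column: str = "ch4_l_per_kg_dmi"
) -> pd.DataFrame:
    """`sample_id  animal  group  <phenotype>` sample metadata table."""
    df = _read(path)
    _require(df, path, ("sample_id", "group", phenotype_column))
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    df[phenotype_column] = _numeric(df, path, phenotype_column)
    return df


def read_mapping(path: PathLike) -> TargetMapping:
    """Linkage-target mapping TSV (delegates to the ontology loader)."""
    return load_mapping(path)


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = True,
              comment: Optional[str] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


@dataclass
class ValidationReport:
    """Per-file and cross-file validation outcome."""

    file_results: dict[str, tuple[bool, str]] = field(default_factory=dict)
    cross_failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(ok for ok, _ in self.file_results.values()) and \
            not self.cross_failures

    def summary(self) -> str:
        lines = []
        for name, (ok, message) in self.file_results.items():
            lines.append(f"{'PASS' if ok else 'FAIL'}  {name}: {message}")
        for failure in self.cross_failures:
            lines.append(f"FAIL  cross-check: {failure}")
        if self.ok:
            lines.append("all inputs consistent")
        return "\n".join(lines)


def validate_inputs(
    bins: PathLike,
    abundance: PathLike,
    annotations: PathLike,
    metadata: PathLike,
    mapping: Optional[PathLike] = None,
    phenotype_column: str = "ch4_l_per_kg_dmi",
) -> ValidationReport:
    """Validate every input file and their referential consistency.

    Never raises: all failures are carried in the report.
    """
    report = ValidationReport()
    loaded: dict[str, object] = {}
    readers = {
        "bins": (bins, read_bin_table),
        "abundance": (abundance, read_abundance_matrix),
        "annotations": (annotations, read_annotations),
        "metadata": (metadata, lambda p: read_metadata(p, phenotype_column)),
    }
    if mapping is not None:
        readers["mapping"] = (mapping, read_mapping)
    for name, (path, reader) in readers.items():
        try:
            loaded[name] = reader(path)
            size = len(loaded[name]) if hasattr(loaded[name], "__len__") else "-"
            report.file_results[name] = (True, f"{path} ({size} rows)")
        except (SchemaError, ValueError) as exc:
            report.file_results[name] = (False, str(exc))

    if {"bins", "abundance"} <= loaded.keys():
        known = set(loaded["bins"]["bin_id"])
        orphans = [b for b in loaded["abundance"].index if b not in known]
        if orphans:
            report.cross_failures.append(
                f"abundance matrix bins missing from the bin table: {orphans[:5]}"
            )
    if {"bins", "annotations"} <= loaded.keys():
        known = set(loaded["bins"]["bin_id"])
        bad = loaded["annotations"][~loaded["annotations"]["bin_id"].isin(known)]
        if not bad.empty:
            first = bad.iloc[0]
            report.cross_failures.append(
                f"annotation protein {first['protein_id']!r} references unknown "
                f"bin {first['bin_id']!r} ({len(bad)} such rows)"
            )
    if {"abundance", "metadata"} <= loaded.keys():
        samples = set(loaded["metadata"]["sample_id"])
        missing = [s for s in loaded["abundance"].columns if s not in samples]
        if missing:
            report.cross_failures.append(
                f"abundance sample(s) missing from metadata: {missing}"
            )
        extra = [s for s in samples if s not in set(loaded["abundance"].columns)]
        if extra:
            report.cross_failures.append(
                f"metadata sample(s) missing from the abundance matrix: {extra}"
            )
    return report
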