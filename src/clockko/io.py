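"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with optional ``#``-prefixed metadata header lines;
bioluminescence traces are CSV (time_h, signal) or wide CSV (time_h + one
column per well); gene-set libraries use standard GMT (term, description,
tab-separated member genes).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .diffexpr import GENOTYPES, ExpressionStudy
from .enrich import GeneSetLibrary

__all__ = [
    "read_expression",
    "write_expression",
    "read_truth",
    "write_table",
    "read_table",
    "read_gmt",
    "write_gmt",
    "read_timeseries",
    "read_qpcr",
]


def _split_comments(path: str | Path) -> tuple[int, str]:
    """Return (number of leading '#' lines, remaining text)."""
    text = Path(path).read_text()
    lines = text.splitlines(keepends=True)
    n = 0
    while n < len(lines) and lines[n].startswith("#"):
        n += 1
    return n, "".join(lines[n:])


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None, index: bool = False
) -> None:
    """Write a TSV with '#'-prefixed metadata lines above the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    _, body = _split_comments(path)
    return pd.read_csv(
        _io.StringIO(body), sep="\t", index_col=index_col, float_precision="round_trip"
    )


def write_expression(
    study: ExpressionStudy,
    matrix_path: str | Path,
    design_path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the TPM matrix (first column 'gene') and the design table."""
    write_table(study.tpm.rename_axis("gene"), matrix_path, metadata, index=True)
    write_table(study.design.reset_index(), design_path, metadata)


def read_expression(matrix_path: str | Path, design_path: str | Path) -> ExpressionStudy:
    """Read a TPM matrix + design pair, validating structure.

    Rejects duplicate gene ids (with the offending line number), design
    samples absent from the matrix (and vice versa), and unknown genotypes.
    """
    n_comment, body = _split_comments(matrix_path)
    tpm = pd.read_csv(
        _io.StringIO(body), sep="\t", index_col=0, float_precision="round_trip"
    )
    if tpm.index.name != "gene":
        raise ValueError(
            f"{matrix_path}: first column must be named 'gene', got {tpm.index.name!r}"
        )
    dup = tpm.index.duplicated(keep="first")
    if dup.any():
        pos = int(dup.argmax())  # 0-based row of first duplicate
        line = n_comment + 2 + pos  # + comments + header, 1-based
        raise ValueError(
            f"{matrix_path}: duplicate gene id {tpm.index[pos]!r} on line {line}"
        )

    design = read_table(design_path)
    required = {"sample", "genotype", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"{design_path}: missing columns {sorted(missing)}")
    design = design.set_index("sample")
    for sample in design.index:
        if sample not in tpm.columns:
            raise ValueError(
                f"{design_path}: sample {sample!r} not present in the matrix"
            )
    for sample in tpm.columns:
        if sample not in design.index:
            raise ValueError(f"{matrix_path}: sample {sample!r} missing from design")
    bad = sorted(set(design["genotype"]) - set(GENOTYPES))
    if bad:
        raise ValueError(
            f"{design_path}: unknown genotypes {bad}; expected one of {GENOTYPES}"
        )
    return ExpressionStudy(tpm, design)


def read_truth(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col="gene")


def read_gmt(path: str | Path, name: str | None = None, uppercase: bool = False) -> GeneSetLibrary:
    """Parse a GMT gene-set library (term TAB description TAB genes...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i}: expected term, description, genes")
        term = fields[0]
        if term in sets:
            raise ValueError(f"{path}: line {i}: duplicate term {term!r}")
        genes = [g.strip() for g in fields[2:] if g.strip()]
        if uppercase:
            genes = [g.upper() for g in genes]
        if not genes:
            raise ValueError(f"{path}: line {i}: term {term!r} has no genes")
        sets[term] = frozenset(genes)
    return GeneSetLibrary(name=name or path.stem, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term, genes in library.sets.items():
            fh.write("\t".join([term, "", *sorted(genes)]) + "\n")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a bioluminescence CSV: (time_h, signal) or time_h + well columns."""
    n_comment, body = _split_comments(path)
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: first column must be 'time_h'")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least one signal column")
    return df


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
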